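"""Population arterial input function (AIF).

The pharmacokinetic model needs the arterial plasma concentration Cp(t). In
the absence of a patient-specific AIF the standard population curve is the
Parker functional form: two Gaussians (first pass and recirculation) plus an
exponential washout modulated by a sigmoid,

    Cp(t) = sum_n A_n / (sigma_n sqrt(2 pi)) exp(-(t - T_n)^2 / (2 sigma_n^2))
            + alpha exp(-beta t) / (1 + exp(-s (t - tau)))

with t in minutes. The published population constants are the defaults here.
A bolus-arrival delay shifts the curve so that Cp is identically zero before
injection (and hence Cp(0) = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AIFModel:
    """Parker-form population AIF with a bolus-arrival delay.

    Amplitudes A1/A2 in mmol*min, centers/widths in minutes, alpha in mmol,
    beta and s in 1/min, tau in minutes. ``t_onset_s`` is the bolus arrival
    time in seconds; ``hematocrit`` converts between plasma and whole-blood
    concentrations (Cb = Cp * (1 - Hct)).
    """

    a1: float = 0.809
    a2: float = 0.330
    t1: float = 0.17046
    t2: float = 0.365
    sigma1: float = 0.0563
    sigma2: float = 0.132
    alpha: float = 1.050
    beta: float = 0.1685
    s: float = 38.078
    tau: float = 0.483
    t_onset_s: float = 10.0
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        if not (0.0 <= self.hematocrit < 1.0):
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.t_onset_s < 0:
            raise ValueError("bolus onset must be >= 0 s")

    def plasma_concentration(self, t_s: np.ndarray) -> np.ndarray:
        """Cp(t) in mmol/L at times ``t_s`` (seconds); zero before onset."""
        return parker_aif(t_s, self)

    def blood_concentration(self, t_s: np.ndarray) -> np.ndarray:
        """Whole-blood concentration Cb = Cp * (1 - Hct)."""
        return self.plasma_concentration(t_s) * (1.0 - self.hematocrit)


def parker_aif(t_s: np.ndarray, model: AIFModel | None = None) -> np.ndarray:
    """Evaluate the Parker population AIF at times given in seconds."""
    if model is None:
        model = AIFModel()
    t_s = np.asarray(t_s, dtype=float)
    tm = (t_s - model.t_onset_s) / 60.0  # minutes since bolus arrival
    cp = np.zeros_like(tm)
    on = tm > 0
    x = tm[on]
    for a, c, sig in ((model.a1, model.t1, model.sigma1), (model.a2, model.t2, model.sigma2)):
        cp[on] += a / (sig * np.sqrt(2.0 * np.pi)) * np.exp(-((x - c) ** 2) / (2.0 * sig**2))
    cp[on] += model.alpha * np.exp(-model.beta * x) / (1.0 + np.exp(-model.s * (x - model.tau)))
    return np.clip(cp, 0.0, None)
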