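"""Acquisition protocol metadata.

A single :class:`AcquisitionProtocol` record carries the sequence parameters
the quantitative models need: the diffusion b-value ladder and direction
count, the variable-flip-angle (VFA) set used for T1 quantification, the
spoiled-gradient-echo timing, the dynamic frame spacing, and the contrast
agent dose/rate/relaxivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence and contrast-agent parameters of a combined DWI + DCE exam.

    Attributes
    ----------
    b_values : diffusion weightings in s/mm^2, strictly increasing from 0.
    n_directions_per_b : diffusion-encoding directions acquired per non-zero b.
    flip_angles_deg : pre-contrast VFA excitation angles for T1 mapping.
    dynamic_flip_angle_deg : excitation angle of the dynamic series.
    tr_ms, te_ms : repetition/echo time of the spoiled gradient echo, ms.
    dynamic_dt_s : dynamic frame spacing, s.
    n_frames : number of dynamic frames.
    dose_mmol_per_kg : contrast dose.
    injection_rate_ml_s : injection rate.
    relaxivity_l_mmol_s : longitudinal relaxivity r1 of the agent at field.
    """

    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0, 1500.0, 2000.0, 2500.0)
    n_directions_per_b: int = 6
    flip_angles_deg: tuple[float, ...] = (6.0, 9.0, 15.0)
    dynamic_flip_angle_deg: float = 15.0
    tr_ms: float = 4.0
    te_ms: float = 1.8
    dynamic_dt_s: float = 5.0
    n_frames: int = 60
    dose_mmol_per_kg: float = 0.1
    injection_rate_ml_s: float = 4.0
    relaxivity_l_mmol_s: float = 6.3

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b_values)
        if len(b) < 1 or b[0] != 0.0:
            raise ValueError("b_values must start at 0")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b_values must be strictly increasing")
        angles = tuple(self.flip_angles_deg) + (self.dynamic_flip_angle_deg,)
        if any(not (0.0 < a < 90.0) for a in angles):
            raise ValueError("flip angles must lie in (0, 90) degrees")
        if self.dynamic_dt_s <= 0:
            raise ValueError("dynamic_dt_s must be positive")
        if self.relaxivity_l_mmol_s <= 0:
            raise ValueError("relaxivity must be positive")
        if self.n_directions_per_b < 1:
            raise ValueError("n_directions_per_b must be >= 1")
        if self.tr_ms <= 0 or self.te_ms <= 0:
            raise ValueError("TR and TE must be positive")

    @property
    def frame_times_s(self) -> tuple[float, ...]:
        """Acquisition time stamps of the dynamic frames (first frame at 0)."""
        return tuple(i * self.dynamic_dt_s for i in range(self.n_frames))


def default_protocol() -> AcquisitionProtocol:
    """Protocol defaults of the standardized 3T exam this pipeline targets.

    Six b-values 0-2500 s/mm^2 with 6 directions each; VFA angles 6/9/15
    degrees at TR 4 ms / TE 1.8 ms; a 15-degree dynamic series at 5 s spacing
    for 60 frames; gadobenate 0.1 mmol/kg at 4 mL/s with r1 = 6.3 L/(mmol*s).
    """
    return AcquisitionProtocol()
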