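"""Diffusion-kurtosis fitting.

The signal model is the direction-averaged kurtosis representation

    ln(S/S0) = -b * ADC + (b * ADC)^2 * K / 6,

quadratic in b in log-signal space, so with S0 fixed by the b = 0 mean the
fit is an ordinary least-squares solve for (c1, c2) in
ln(S/S0) = c1*b + c2*b^2, giving ADC = -c1 and K = 6*c2/ADC^2. ADC here is
the kurtosis-model diffusivity, not a separate monoexponential fit. Signals
are geometrically averaged over gradient directions first (arithmetically
for b = 0), which is the natural average for a model linear in log-signal
and improves SNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .images import ImageSeries, ParameterMaps, VolumeTag

logger = logging.getLogger(__name__)

ADC_CEIL = 4.0e-3  # mm^2/s, physiological ceiling
MK_CEIL = 3.0
ADC_FLOOR_VALID = 1.0e-5  # below this the quadratic term is unidentifiable
_GUARD = 0.10  # +-10% guard band outside [0, ceiling] clears validity


@dataclass
class DKIVoxelFit:
    """Single-voxel kurtosis fit: ADC (mm^2/s), MK, fitted S0, residual SS."""

    adc: float
    mk: float
    s0: float
    rss: float
    valid: bool


def direction_average(series: ImageSeries) -> ImageSeries:
    """Collapse a multi-direction DWI series to one volume per b-value.

    b > 0 volumes are combined by the per-voxel geometric mean across
    directions; b = 0 volumes are arithmetically averaged. Output tags are
    the unique b-values in ascending order. Voxels with any non-positive
    signal at a given b get 0 there (flagged invalid downstream).
    """
    b = series.b_values()
    unique_b = np.unique(b)
    if 0.0 not in unique_b:
        raise ValueError("series has no b = 0 volume")
    counts = {bv: int(np.sum(b == bv)) for bv in unique_b if bv > 0}
    if len(set(counts.values())) > 1:
        raise ValueError(f"unequal direction counts per b-value: {counts}")

    out = np.empty(series.shape3d + (len(unique_b),), dtype=float)
    for i, bv in enumerate(unique_b):
        sub = series.voxels[..., b == bv]
        if bv == 0:
            out[..., i] = sub.mean(axis=-1)
        else:
            pos = np.all(sub > 0, axis=-1)
            gm = np.zeros(series.shape3d)
            if np.any(pos):
                gm[pos] = np.exp(np.log(sub[pos]).mean(axis=-1))
            out[..., i] = gm
    tags = [VolumeTag(b_value=float(bv)) for bv in unique_b]
    return ImageSeries(out, tags, affine=series.affine.copy(), space_label=series.space_label)


def _fit_quadratic(y: np.ndarray, b_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of y = c1*b + c2*b^2 for stacked voxels; returns c1, c2, rss."""
    A = np.column_stack([b_pos, b_pos**2])
    coef, _, _, _ = np.linalg.lstsq(A, y.T, rcond=None)
    resid = y.T - A @ coef
    return coef[0], coef[1], np.sum(resid**2, axis=0)


def fit_dki_voxel(signals: np.ndarray, b_values: np.ndarray) -> DKIVoxelFit:
    """Fit ADC and MK for one voxel from per-b mean signals.

    ``signals`` holds the direction-averaged signal at each entry of
    ``b_values`` (which must include 0 and at least two non-zero values).
    Raw estimates outside the guard bands, or non-positive input signals,
    clear the validity flag; reported values are clipped to
    [0, ADC_CEIL] x [0, MK_CEIL].
    """
    signals = np.asarray(signals, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if len(np.unique(b_values)) < 3 or 0.0 not in b_values:
        raise ValueError("need >= 3 distinct b-values including 0")
    fits = fit_dki_stack(signals[None, :], b_values)
    return DKIVoxelFit(
        adc=float(fits["adc"][0]),
        mk=float(fits["mk"][0]),
        s0=float(fits["s0"][0]),
        rss=float(fits["rss"][0]),
        valid=bool(fits["valid"][0]),
    )


def fit_dki_stack(signals: np.ndarray, b_values: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized kurtosis fit over a (n_voxels, n_b) signal stack."""
    b_values = np.asarray(b_values, dtype=float)
    signals = np.asarray(signals, dtype=float)
    is_b0 = b_values == 0.0
    s0 = signals[:, is_b0].mean(axis=1)
    b_pos = b_values[~is_b0]
    s_pos = signals[:, ~is_b0]

    ok = (s0 > 0) & np.all(s_pos > 0, axis=1)
    n = signals.shape[0]
    adc = np.zeros(n)
    mk = np.zeros(n)
    rss = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    if np.any(ok):
        y = np.log(s_pos[ok] / s0[ok, None])
        c1, c2, r = _fit_quadratic(y, b_pos)
        adc_raw = -c1
        with np.errstate(divide="ignore", invalid="ignore"):
            mk_raw = np.where(adc_raw != 0, 6.0 * c2 / adc_raw**2, np.inf)
        good = (
            (adc_raw > ADC_FLOOR_VALID)
            & (adc_raw >= -_GUARD * ADC_CEIL)
            & (adc_raw <= (1 + _GUARD) * ADC_CEIL)
            & (mk_raw >= -_GUARD * MK_CEIL)
            & (mk_raw <= (1 + _GUARD) * MK_CEIL)
        )
        adc[ok] = np.clip(adc_raw, 0.0, ADC_CEIL)
        mk[ok] = np.clip(np.where(np.isfinite(mk_raw), mk_raw, 0.0), 0.0, MK_CEIL)
        rss[ok] = r
        valid[ok] = good
    return {"adc": adc, "mk": mk, "s0": s0, "rss": rss, "valid": valid}


def fit_dki_volume(series: ImageSeries, mask: np.ndarray | None = None) -> ParameterMaps:
    """Direction-average a DWI series and fit ADC/MK on every masked voxel."""
    if mask is None:
        mask = np.ones(series.shape3d, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape3d:
        raise ValueError("mask shape differs from image grid")
    if not mask.any():
        raise ValueError("mask selects no voxels")

    avg = direction_average(series)
    b = avg.b_values()
    stack = avg.voxels[mask]  # (n_vox, n_b)
    fits = fit_dki_stack(stack, b)

    shape = series.shape3d
    adc_map = np.zeros(shape)
    mk_map = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    adc_map[mask] = fits["adc"]
    mk_map[mask] = fits["mk"]
    valid[mask] = fits["valid"]

    n_mask = int(mask.sum())
    n_bad = n_mask - int(valid.sum())
    logger.info("DKI fit: %d voxels, %d invalid (%.1f%%)", n_mask, n_bad, 100.0 * n_bad / n_mask)
    return ParameterMaps(
        maps={"ADC": adc_map, "MK": mk_map},
        units={},
        valid=valid,
        affine=series.affine.copy(),
        space_label=series.space_label,
    )


def dki_signal(b: np.ndarray, s0: float, adc: float, k: float) -> np.ndarray:
    """Forward kurtosis signal S = S0 exp(-b*ADC + (b*ADC)^2 K / 6)."""
    b = np.asarray(b, dtype=float)
    return s0 * np.exp(-b * adc + (b * adc) ** 2 * k / 6.0)
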