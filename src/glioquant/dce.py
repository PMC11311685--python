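"""DCE-MRI quantification.

Chain: variable-flip-angle (VFA) T1 mapping via the linearized spoiled
gradient echo (SPGR) equation; inversion of the dynamic SPGR signal to
contrast-agent concentration C(t) = (R1(t) - R10) / r1; extended-Tofts
pharmacokinetic fitting

    Ct(t) = vp * Cp(t) + Ktrans * int_0^t Cp(u) exp(-kep (t - u)) du,

with ve = Ktrans / kep; and the semi-quantitative curve descriptors (CBV,
TTP, peak, AUC, wash-in, wash-out) computed on relative-enhancement curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aif import AIFModel
from .images import ImageSeries, ParameterMaps
from .protocol import AcquisitionProtocol

logger = logging.getLogger(__name__)

T1_MIN_MS = 100.0
T1_MAX_MS = 10000.0
KTRANS_MAX = 5.0  # 1/min
KEP_MAX = 10.0  # 1/min


@dataclass
class T1Fit:
    t1_ms: float
    m0: float
    valid: bool


@dataclass
class ToftsVoxelFit:
    """Extended-Tofts estimate: Ktrans, kep in 1/min; ve, vp fractions."""

    ktrans: float
    kep: float
    ve: float
    vp: float
    rss: float
    valid: bool


@dataclass
class CurveMetrics:
    """Semi-quantitative enhancement-curve descriptors.

    Units follow the input curve (percent relative enhancement by default):
    peak in %, TTP in s, auc in %*s, wash_in and wash_out in %/s, cbv in %.
    """

    ttp: float
    peak: float
    auc: float
    wash_in: float
    wash_out: float
    valid: bool


def spgr_signal(t1_ms: np.ndarray, m0: np.ndarray, flip_deg: float, tr_ms: float) -> np.ndarray:
    """Spoiled gradient-echo signal S = M0 sin(a) (1 - E1) / (1 - E1 cos(a))."""
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    return np.asarray(m0, dtype=float) * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def fit_t1_vfa(signals: np.ndarray, angles_deg: np.ndarray, tr_ms: float) -> T1Fit:
    """DESPOT1-style linearized VFA fit for one voxel.

    Regresses S/sin(a) on S/tan(a): the slope is E1 = exp(-TR/T1) and the
    intercept M0 (1 - E1). Validity is cleared when E1 falls outside (0, 1)
    or T1 outside [100, 10000] ms.
    """
    out = fit_t1_vfa_stack(np.asarray(signals, dtype=float)[None, :], angles_deg, tr_ms)
    return T1Fit(t1_ms=float(out["t1_ms"][0]), m0=float(out["m0"][0]), valid=bool(out["valid"][0]))


def fit_t1_vfa_stack(signals: np.ndarray, angles_deg: np.ndarray, tr_ms: float) -> dict[str, np.ndarray]:
    """Vectorized VFA fit over a (n_voxels, n_angles) stack."""
    angles = np.asarray(angles_deg, dtype=float)
    if len(np.unique(angles)) < 2:
        raise ValueError("need >= 2 distinct flip angles")
    signals = np.asarray(signals, dtype=float)
    a = np.deg2rad(angles)
    y = signals / np.sin(a)  # (n_vox, n_ang)
    x = signals / np.tan(a)

    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=1)
    sxy = np.sum((x - xm) * (y - ym), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(sxx > 0, sxy / sxx, np.nan)
    intercept = ym[:, 0] - e1 * xm[:, 0]

    ok = np.isfinite(e1) & (e1 > 0) & (e1 < 1) & np.all(signals > 0, axis=1)
    t1 = np.full(signals.shape[0], np.nan)
    m0 = np.full(signals.shape[0], np.nan)
    t1[ok] = -tr_ms / np.log(e1[ok])
    m0[ok] = intercept[ok] / (1.0 - e1[ok])
    ok &= (t1 >= T1_MIN_MS) & (t1 <= T1_MAX_MS) & (m0 > 0)
    return {"t1_ms": t1, "m0": m0, "valid": ok}


def signal_to_concentration(
    s_t: np.ndarray,
    s_baseline: float | np.ndarray,
    t10_ms: float | np.ndarray,
    tr_ms: float,
    flip_deg: float,
    relaxivity: float,
) -> np.ndarray:
    """Invert the dynamic SPGR signal to concentration (mmol/L).

    The equilibrium magnetization is implied by (s_baseline, T10); each frame
    is then solved for E1(t), giving R1(t) and C(t) = (R1(t) - R10)/r1,
    clipped below at 0. Frames whose signal implies E1 <= 0 (out of the SPGR
    range) come back as NaN. Works on a trailing time axis.
    """
    s_t = np.asarray(s_t, dtype=float)
    s_baseline = np.asarray(s_baseline, dtype=float)
    t10_ms = np.asarray(t10_ms, dtype=float)
    if np.any(s_baseline <= 0):
        raise ValueError("baseline signal must be positive")
    a = np.deg2rad(flip_deg)
    e10 = np.exp(-tr_ms / t10_ms)
    # M0 sin(a) implied by the baseline signal and T10
    m0sin = s_baseline * (1.0 - e10 * np.cos(a)) / (1.0 - e10)

    num = m0sin[..., None] - s_t
    den = m0sin[..., None] - s_t * np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = num / den
    bad = ~np.isfinite(e1) | (e1 <= 0) | (e1 >= 1)
    e1 = np.where(bad, np.nan, e1)
    r1 = -np.log(e1) / (tr_ms / 1000.0)  # 1/s
    r10 = (1000.0 / t10_ms)[..., None]
    c = (r1 - r10) / relaxivity
    return np.where(np.isnan(c), np.nan, np.clip(c, 0.0, None))


def tofts_forward(
    t_s: np.ndarray, cp: np.ndarray, ktrans_per_min: float, kep_per_min: float, vp: float
) -> np.ndarray:
    """Extended-Tofts tissue curve by trapezoidal discrete convolution."""
    t_min = np.asarray(t_s, dtype=float) / 60.0
    cp = np.asarray(cp, dtype=float)
    n = len(t_min)
    conv = np.zeros(n)
    # int_0^t cp(u) exp(-kep (t-u)) du on the frame grid
    for i in range(1, n):
        u = t_min[: i + 1]
        kern = cp[: i + 1] * np.exp(-kep_per_min * (t_min[i] - u))
        conv[i] = np.trapezoid(kern, u)
    return vp * cp + ktrans_per_min * conv


def _tofts_forward_fast(t_min: np.ndarray, cp: np.ndarray, ktrans: float, kep: float, vp: float) -> np.ndarray:
    """Recursive trapezoid evaluation of the Tofts convolution, O(n)."""
    n = len(t_min)
    conv = np.zeros(n)
    for i in range(1, n):
        dt = t_min[i] - t_min[i - 1]
        ek = np.exp(-kep * dt)
        conv[i] = conv[i - 1] * ek + 0.5 * dt * (cp[i] + cp[i - 1] * ek)
    return vp * cp + ktrans * conv


def fit_extended_tofts(ct: np.ndarray, cp: np.ndarray, t_s: np.ndarray) -> ToftsVoxelFit:
    """Nonlinear least-squares extended-Tofts fit of one tissue curve.

    Multi-start trust-region fit over (Ktrans, kep, vp) with bounds
    [0, 5] x [1e-6, 10] x [0, 1]; the best residual wins. ve = Ktrans/kep.
    A fit landing on the parameter bounds or failing to converge is invalid.
    """
    ct = np.asarray(ct, dtype=float)
    cp = np.asarray(cp, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if len(t_s) < 5:
        raise ValueError("need >= 5 frames")
    if not np.any(cp > 0):
        raise ValueError("AIF is identically zero")
    finite = np.isfinite(ct)
    if finite.sum() < 5:
        return ToftsVoxelFit(0.0, 0.0, 0.0, 0.0, np.inf, False)

    t_min = t_s / 60.0
    if np.allclose(ct[finite], 0.0, atol=1e-12):
        return ToftsVoxelFit(0.0, 0.0, 0.0, 0.0, 0.0, True)

    def resid(p):
        model = _tofts_forward_fast(t_min, cp, p[0], p[1], p[2])
        return model[finite] - ct[finite]

    lb = np.array([0.0, 1e-6, 0.0])
    ub = np.array([KTRANS_MAX, KEP_MAX, 1.0])
    starts = [
        (0.05, 0.3, 0.02),
        (0.3, 1.0, 0.05),
        (0.02, 0.1, 0.01),
        (1.0, 3.0, 0.1),
    ]
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0=np.array(x0), bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # numerical failure on this start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return ToftsVoxelFit(0.0, 0.0, 0.0, 0.0, np.inf, False)

    ktrans, kep, vp = best.x
    rss = 2.0 * best.cost
    ve = ktrans / kep if ktrans > 0 else 0.0
    valid = bool(best.success) and ve <= 1.0 and ktrans < 0.999 * KTRANS_MAX and kep < 0.999 * KEP_MAX
    if ktrans < 1e-8:
        ktrans, ve = 0.0, 0.0
        kep = 0.0
    return ToftsVoxelFit(float(ktrans), float(kep), float(ve), float(vp), float(rss), valid)


def compute_curve_metrics(curve: np.ndarray, t_s: np.ndarray, window_s: float = 60.0) -> CurveMetrics:
    """Semi-quantitative descriptors of one enhancement curve.

    Bolus arrival is the first frame exceeding 10% of the curve maximum;
    peak is the curve maximum; TTP = t(peak) - t(arrival); AUC is the
    trapezoidal integral over [arrival, arrival + window_s] (end point
    linearly interpolated); wash-in the steepest forward-difference slope on
    [arrival, peak]; wash-out the sign-flipped least-squares slope from peak
    to the last frame (positive for decaying curves).
    """
    curve = np.asarray(curve, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if len(curve) < 5:
        raise ValueError("need >= 5 frames")
    cmax = np.nanmax(curve)
    cmin = np.nanmin(curve)
    if not np.isfinite(cmax) or cmax == cmin:
        return CurveMetrics(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    thresh = 0.1 * cmax
    above = np.where(curve > thresh)[0]
    i_arr = int(above[0]) if len(above) else 0
    i_peak = int(np.nanargmax(curve))
    ttp = float(t_s[i_peak] - t_s[i_arr])
    peak = float(cmax)

    t_end = min(t_s[i_arr] + window_s, t_s[-1])
    grid = np.concatenate([t_s[(t_s >= t_s[i_arr]) & (t_s <= t_end)], [t_end]])
    grid = np.unique(grid)
    vals = np.interp(grid, t_s, curve)
    auc = float(np.trapezoid(vals, grid))

    if i_peak > i_arr:
        slopes = np.diff(curve[i_arr : i_peak + 1]) / np.diff(t_s[i_arr : i_peak + 1])
        wash_in = float(np.max(slopes))
    else:
        wash_in = 0.0

    if i_peak < len(curve) - 1:
        tt = t_s[i_peak:]
        cc = curve[i_peak:]
        slope = np.polyfit(tt, cc, 1)[0]
        wash_out = float(-slope)
    else:
        wash_out = 0.0
    return CurveMetrics(ttp=ttp, peak=peak, auc=auc, wash_in=wash_in, wash_out=wash_out, valid=True)


def compute_cbv(ct: np.ndarray, cp: np.ndarray, t_s: np.ndarray, hematocrit: float = 0.45) -> float:
    """Cerebral blood volume as the tissue-to-blood AUC ratio, in percent.

    cbv = 100 * int ct dt / int cb dt with the whole-blood curve
    cb = cp * (1 - Hct), integrated trapezoidally over the full window.
    """
    ct = np.asarray(ct, dtype=float)
    cb = np.asarray(cp, dtype=float) * (1.0 - hematocrit)
    t_s = np.asarray(t_s, dtype=float)
    denom = np.trapezoid(cb, t_s)
    if denom <= 0:
        raise ValueError("blood-curve integral must be positive")
    return float(100.0 * np.trapezoid(ct, t_s) / denom)


def fit_dce_volume(
    vfa: ImageSeries,
    dynamic: ImageSeries,
    protocol: AcquisitionProtocol,
    aif: AIFModel | None = None,
    mask: np.ndarray | None = None,
    n_baseline_frames: int | None = None,
    auc_window_s: float = 60.0,
) -> ParameterMaps:
    """Full DCE chain on a volume: T1 map -> concentration -> Tofts + curve metrics.

    Returns the 10 DCE parameter maps (Ktrans, Kep, vp, ve, CBV, TTP, peak,
    AUC_DCE, wash_in, wash_out). Semi-quantitative metrics are computed on
    percent relative enhancement (S - S0)/S0 * 100; CBV on concentration.
    Baseline frames are those before bolus onset (from the AIF model) unless
    given explicitly.
    """
    if aif is None:
        aif = AIFModel()
    if vfa.shape3d != dynamic.shape3d:
        raise ValueError("VFA and dynamic series must share a grid")
    if mask is None:
        mask = np.ones(vfa.shape3d, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    t = dynamic.times()
    if n_baseline_frames is None:
        n_baseline_frames = max(1, int(np.sum(t < aif.t_onset_s)))
    cp = aif.plasma_concentration(t)

    angles = vfa.flip_angles()
    t1fits = fit_t1_vfa_stack(vfa.voxels[mask], angles, protocol.tr_ms)

    dyn = dynamic.voxels[mask]  # (n_vox, n_frames)
    s_base = dyn[:, :n_baseline_frames].mean(axis=1)

    shape = vfa.shape3d
    names = ("Ktrans", "Kep", "vp", "ve", "CBV", "TTP", "peak", "AUC_DCE", "wash_in", "wash_out")
    maps = {k: np.zeros(shape) for k in names}
    valid = np.zeros(shape, dtype=bool)

    idx = np.argwhere(mask)
    n_bad = 0
    for row, (vi, vj, vk) in enumerate(idx):
        if not t1fits["valid"][row] or s_base[row] <= 0:
            n_bad += 1
            continue
        conc = signal_to_concentration(
            dyn[row], s_base[row], t1fits["t1_ms"][row], protocol.tr_ms,
            protocol.dynamic_flip_angle_deg, protocol.relaxivity_l_mmol_s,
        )
        tk = fit_extended_tofts(conc, cp, t)
        enh = (dyn[row] - s_base[row]) / s_base[row] * 100.0
        cm = compute_curve_metrics(enh, t, window_s=auc_window_s) if np.ptp(enh) > 0 else CurveMetrics(
            0.0, 0.0, 0.0, 0.0, 0.0, False
        )
        ok = tk.valid and cm.valid and np.all(np.isfinite(conc))
        if not ok:
            n_bad += 1
            continue
        cbv = compute_cbv(np.nan_to_num(conc), cp, t, aif.hematocrit)
        v = (vi, vj, vk)
        maps["Ktrans"][v] = tk.ktrans
        maps["Kep"][v] = tk.kep
        maps["vp"][v] = tk.vp
        maps["ve"][v] = tk.ve
        maps["CBV"][v] = cbv
        maps["TTP"][v] = cm.ttp
        maps["peak"][v] = cm.peak
        maps["AUC_DCE"][v] = cm.auc
        maps["wash_in"][v] = cm.wash_in
        maps["wash_out"][v] = cm.wash_out
        valid[v] = True

    n_mask = len(idx)
    logger.info("DCE fit: %d voxels, %d invalid (%.1f%%)", n_mask, n_bad, 100.0 * n_bad / max(n_mask, 1))
    return ParameterMaps(maps=maps, units={}, valid=valid, affine=vfa.affine.copy(), space_label=vfa.space_label)
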