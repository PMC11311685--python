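"""Synthetic phantoms and cohorts with known ground truth.

The patient data behind this pipeline are not publicly deposited, so the
package ships generators for everything the analysis chain consumes:

* DWI phantoms following the kurtosis signal model (isotropic — the pipeline
  only evaluates direction-averaged scalars), with Rician noise;
* VFA + dynamic DCE phantoms driven by the SPGR signal equation, an
  extended-Tofts tissue response and the Parker population AIF;
* ROI-level cohorts: per-patient 12-parameter biopsy vectors drawn from
  group-specific multivariate normals plus exchangeable NAWM control
  vectors, with WHO grade / IDH1/2 / 1p/19q labels attached.

Rician noise is applied on the complex signal (two independent Gaussian
channels, magnitude taken), which is the correct noise floor for magnitude
MRI at high b-value or low enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aif import AIFModel
from .dce import spgr_signal, tofts_forward
from .dki import dki_signal
from .images import PARAMETER_NAMES, ImageSeries, ParameterMaps, VolumeTag
from .protocol import AcquisitionProtocol

# six non-collinear unit gradient directions (icosahedral-style scheme)
_DIRECTIONS = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
    ]
)
_DIRECTIONS = _DIRECTIONS / np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)


@dataclass(frozen=True)
class Region:
    """Ground-truth tissue values for one phantom compartment."""

    name: str
    t1_ms: float = 1000.0
    adc: float = 0.8e-3  # mm^2/s
    k: float = 0.9
    ktrans: float = 0.0  # 1/min
    ve: float = 0.1
    vp: float = 0.01

    def __post_init__(self) -> None:
        if not (200.0 <= self.t1_ms <= 5000.0):
            raise ValueError(f"region {self.name}: T1 outside [200, 5000] ms")
        if not (0.1e-3 <= self.adc <= 3.5e-3):
            raise ValueError(f"region {self.name}: ADC outside [0.1e-3, 3.5e-3]")
        if not (0.0 <= self.k <= 3.0):
            raise ValueError(f"region {self.name}: K outside [0, 3]")
        if not (0.0 <= self.ve <= 1.0 and 0.0 <= self.vp <= 1.0):
            raise ValueError(f"region {self.name}: ve/vp outside [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid layout and acquisition noise of a block phantom.

    Regions occupy contiguous blocks along the x axis (equal split). The
    noise scale is Rician, relative to the b0 / pre-contrast signal.
    """

    shape: tuple[int, int, int] = (10, 10, 5)
    regions: tuple[Region, ...] = (
        Region("nawm", t1_ms=900.0, adc=0.75e-3, k=0.95, ktrans=0.004, ve=0.04, vp=0.01),
        Region("lgg", t1_ms=1400.0, adc=1.3e-3, k=0.55, ktrans=0.03, ve=0.15, vp=0.02),
        Region("hgg", t1_ms=1600.0, adc=1.0e-3, k=0.85, ktrans=0.15, ve=0.3, vp=0.05),
    )
    noise_sigma: float = 0.0
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.regions) < 1:
            raise ValueError("at least one region required")

    def region_index(self) -> np.ndarray:
        """Voxel-to-region assignment (blocks along x)."""
        nx = self.shape[0]
        edges = np.linspace(0, nx, len(self.regions) + 1).astype(int)
        idx = np.zeros(self.shape, dtype=int)
        for i in range(len(self.regions)):
            idx[edges[i] : edges[i + 1]] = i
        return idx

    def truth_map(self, attr: str) -> np.ndarray:
        vals = np.array([getattr(r, attr) for r in self.regions])
        return vals[self.region_index()]


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (S + n1) + i*n2 with n1, n2 ~ N(0, sigma)."""
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_dwi(spec: PhantomSpec, protocol: AcquisitionProtocol) -> tuple[ImageSeries, ParameterMaps]:
    """Forward-simulate a multi-b, multi-direction DWI series.

    The phantom is isotropic: the noiseless signal is identical across
    directions at each b. Returns the noisy series and the ground-truth
    ADC/MK maps.
    """
    if len(protocol.b_values) < 3:
        raise ValueError("protocol must list >= 3 b-values")
    rng = np.random.default_rng(spec.seed)
    adc = spec.truth_map("adc")
    k = spec.truth_map("k")

    vols = []
    tags = []
    for b in protocol.b_values:
        clean = dki_signal(b, spec.s0, adc, k)
        if b == 0:
            vols.append(clean)
            tags.append(VolumeTag(b_value=0.0))
        else:
            for d in range(protocol.n_directions_per_b):
                vols.append(clean.copy())
                tags.append(VolumeTag(b_value=float(b), direction=tuple(_DIRECTIONS[d % len(_DIRECTIONS)])))
    signal = np.stack(vols, axis=-1)
    noisy = add_rician_noise(signal, spec.noise_sigma * spec.s0, rng)
    series = ImageSeries(noisy, tags, space_label="dwi")
    truth = ParameterMaps(
        maps={"ADC": adc, "MK": k}, units={}, valid=np.ones(spec.shape, dtype=bool), space_label="dwi"
    )
    return series, truth


def simulate_dce(
    spec: PhantomSpec, protocol: AcquisitionProtocol, aif: AIFModel | None = None
) -> tuple[ImageSeries, ImageSeries, ParameterMaps]:
    """Forward-simulate VFA and dynamic series from Tofts ground truth.

    VFA volumes follow the SPGR equation at each listed angle from
    (T1, M0 = s0); dynamic frames follow the same equation with R1(t)
    shortened by the tissue concentration from the extended-Tofts forward
    model under the population AIF. Rician noise applies to both series.
    Returns (vfa, dynamic, ground-truth maps with Ktrans/Kep/vp/ve).
    """
    if len(protocol.flip_angles_deg) < 2:
        raise ValueError("protocol must list >= 2 flip angles")
    if protocol.n_frames < 5:
        raise ValueError("need >= 5 dynamic frames")
    if aif is None:
        aif = AIFModel()
    rng = np.random.default_rng(spec.seed)

    t1 = spec.truth_map("t1_ms")
    ktrans = spec.truth_map("ktrans")
    ve = spec.truth_map("ve")
    vp = spec.truth_map("vp")
    m0 = np.full(spec.shape, spec.s0)
    sigma = spec.noise_sigma * spec.s0

    vfa_vols = [spgr_signal(t1, m0, a, protocol.tr_ms) for a in protocol.flip_angles_deg]
    vfa = ImageSeries(
        add_rician_noise(np.stack(vfa_vols, axis=-1), sigma, rng),
        [VolumeTag(flip_angle_deg=float(a)) for a in protocol.flip_angles_deg],
        space_label="dce",
    )

    t = np.asarray(protocol.frame_times_s)
    cp = aif.plasma_concentration(t)
    # one tissue curve per region, broadcast to voxels
    ridx = spec.region_index()
    curves = []
    for r in spec.regions:
        kep = r.ktrans / r.ve if r.ve > 0 else 0.0
        curves.append(tofts_forward(t, cp, r.ktrans, kep, r.vp))
    curves = np.array(curves)  # (n_regions, n_frames)
    conc = curves[ridx]  # (..., n_frames)

    r1 = 1000.0 / t1[..., None] + protocol.relaxivity_l_mmol_s * conc  # 1/s
    t1_t = 1000.0 / r1  # ms
    dyn_clean = spgr_signal(t1_t, m0[..., None], protocol.dynamic_flip_angle_deg, protocol.tr_ms)
    dynamic = ImageSeries(
        add_rician_noise(dyn_clean, sigma, rng),
        [VolumeTag(time_s=float(ti)) for ti in t],
        space_label="dce",
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        kep_map = np.where(ve > 0, ktrans / ve, 0.0)
    truth = ParameterMaps(
        maps={"Ktrans": ktrans, "Kep": kep_map, "ve": ve, "vp": vp},
        units={},
        valid=np.ones(spec.shape, dtype=bool),
        space_label="dce",
    )
    return vfa, dynamic, truth


# ---------------------------------------------------------------------------
# ROI-level cohorts

HISTOLOGIES = (
    "astrocytoma_g2",
    "astrocytoma_g3",
    "oligodendroglioma_g2",
    "oligodendroglioma_g3",
    "glioblastoma",
)

_WHO_GRADE = {
    "astrocytoma_g2": 2,
    "astrocytoma_g3": 3,
    "oligodendroglioma_g2": 2,
    "oligodendroglioma_g3": 3,
    "glioblastoma": 4,
}

# effect group of each histology for mean assignment
_EFFECT_GROUP = {
    "astrocytoma_g2": "lgg",
    "oligodendroglioma_g2": "lgg",
    "astrocytoma_g3": "hgg_astro",
    "glioblastoma": "hgg_astro",
    "oligodendroglioma_g3": "oligo_hg",
}

#: Default group mean vectors over the 12 parameters (reporting order).
#: Chosen as plausible tissue values: higher perfusion/permeability and
#: kurtosis with lower ADC in high-grade astrocytic tumors; oligodendroglial
#: grade-3 tumors intermediate.
DEFAULT_GROUP_MEANS: dict[str, np.ndarray] = {
    "lgg": np.array([1.30e-3, 0.60, 0.04, 0.35, 0.025, 0.12, 2.5, 70.0, 30.0, 1500.0, 2.0, 0.12]),
    "hgg_astro": np.array([0.95e-3, 0.90, 0.09, 0.60, 0.045, 0.20, 4.8, 50.0, 60.0, 2800.0, 4.5, 0.30]),
    "oligo_hg": np.array([1.10e-3, 0.75, 0.065, 0.48, 0.035, 0.16, 3.6, 60.0, 45.0, 2100.0, 3.2, 0.20]),
}

#: Shared NAWM (control) distribution: no group effect by construction.
DEFAULT_NAWM_MEAN = np.array([0.78e-3, 0.95, 0.004, 0.08, 0.01, 0.045, 1.5, 80.0, 10.0, 500.0, 0.5, 0.05])

#: Relative dispersion (SD / mean) of each parameter across patients.
#: A 30% coefficient of variation yields single-parameter AUCs in the
#: 0.75-0.9 range typical of clinical glioma biomarkers.
DEFAULT_CV = 0.30

#: Physical clipping ranges per parameter.
_CLIP = {
    "ADC": (0.1e-3, 3.5e-3),
    "MK": (0.0, 3.0),
    "Ktrans": (0.0, 5.0),
    "Kep": (0.0, 10.0),
    "vp": (0.0, 1.0),
    "ve": (0.0, 1.0),
    "CBV": (0.0, None),
    "TTP": (0.0, None),
    "peak": (0.0, None),
    "AUC_DCE": (0.0, None),
    "wash_in": (0.0, None),
    "wash_out": (None, None),
}

_DCE_IDX = [i for i, p in enumerate(PARAMETER_NAMES) if p not in ("ADC", "MK")]


@dataclass(frozen=True)
class CohortSpec:
    """Composition and effect structure of a synthetic patient cohort.

    ``group_sizes`` maps histology names to patient counts (defaults mirror
    a 81-patient glioma case mix: 12/7/3/12/47). ``idh_counts`` fixes the
    marginal IDH1/2 wildtype/mutated/missing totals; oligodendrogliomas are
    always mutated + 1p/19q-codeleted, remaining mutated and missing labels
    fill the astrocytic strata (glioblastoma last). Group mean vectors are
    over the 12 parameters in reporting order; covariance is built from a
    per-parameter coefficient of variation with exchangeable correlation
    ``dce_corr`` among the 10 DCE parameters.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "astrocytoma_g2": 12,
            "astrocytoma_g3": 7,
            "oligodendroglioma_g2": 3,
            "oligodendroglioma_g3": 12,
            "glioblastoma": 47,
        }
    )
    idh_counts: tuple[int, int, int] | None = (32, 42, 7)  # (wildtype, mutated, missing)
    group_means: dict[str, np.ndarray] = field(default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    nawm_mean: np.ndarray = field(default_factory=lambda: DEFAULT_NAWM_MEAN.copy())
    cv: float = DEFAULT_CV
    dce_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.group_sizes) - set(HISTOLOGIES)
        if unknown:
            raise ValueError(f"unknown histologies: {sorted(unknown)}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.idh_counts is not None and sum(self.idh_counts) != self.n_patients:
            raise ValueError(
                f"idh_counts sum {sum(self.idh_counts)} != cohort size {self.n_patients}"
            )
        if not (-1.0 / 11.0 < self.dce_corr < 1.0):
            raise ValueError("dce_corr outside the positive-semidefinite range")

    @property
    def n_patients(self) -> int:
        return sum(self.group_sizes.values())

    def covariance(self, mean: np.ndarray) -> np.ndarray:
        """Covariance: CV-scaled SDs, exchangeable corr among DCE params."""
        sd = np.abs(mean) * self.cv
        sd = np.where(sd == 0, 1e-6, sd)
        corr = np.eye(len(mean))
        for i in _DCE_IDX:
            for j in _DCE_IDX:
                if i != j:
                    corr[i, j] = self.dce_corr
        cov = np.outer(sd, sd) * corr
        # guard: exchangeable blocks are PSD by construction, but verify
        eigmin = float(np.linalg.eigvalsh(cov).min())
        if eigmin < -1e-12:
            raise ValueError("covariance is not positive semidefinite")
        return cov


def _assign_idh(histology: list[str], idh_counts: tuple[int, int, int] | None) -> list[str]:
    n = len(histology)
    if idh_counts is None:
        # canonical assignment: glioblastoma wildtype, everything else mutated
        return ["wildtype" if h == "glioblastoma" else "mutated" for h in histology]
    n_wt, n_mut, n_miss = idh_counts
    idh = [""] * n
    # oligodendrogliomas are mutated by definition
    mut_left = n_mut
    for i, h in enumerate(histology):
        if h.startswith("oligodendroglioma"):
            if mut_left <= 0:
                raise ValueError("idh_counts: not enough mutated labels for oligodendrogliomas")
            idh[i] = "mutated"
            mut_left -= 1
    # astrocytomas take mutated labels next, then glioblastomas take
    # wildtype, with leftovers (mutated/missing) absorbed by glioblastoma
    astro = [i for i, h in enumerate(histology) if h.startswith("astrocytoma")]
    gbm = [i for i, h in enumerate(histology) if h == "glioblastoma"]
    for i in astro:
        if mut_left > 0:
            idh[i] = "mutated"
            mut_left -= 1
    wt_left, miss_left = n_wt, n_miss
    for i in gbm + [i for i in astro if idh[i] == ""]:
        if wt_left > 0:
            idh[i] = "wildtype"
            wt_left -= 1
        elif mut_left > 0:
            idh[i] = "mutated"
            mut_left -= 1
        elif miss_left > 0:
            idh[i] = "missing"
            miss_left -= 1
    if any(x == "" for x in idh) or wt_left or mut_left or miss_left:
        raise ValueError("idh_counts could not be assigned consistently")
    return idh


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw an ROI-level cohort table.

    One row per patient with labels (histology, who_grade, idh,
    codeletion_1p19q) and ``biopsy_<param>`` / ``nawm_<param>`` columns for
    the 12 parameters. Biopsy vectors come from the histology's effect-group
    multivariate normal; NAWM vectors from the shared control distribution
    (exchangeable across groups — the built-in negative control).
    """
    rng = np.random.default_rng(spec.seed)
    histology: list[str] = []
    for h in HISTOLOGIES:
        histology.extend([h] * spec.group_sizes.get(h, 0))
    idh = _assign_idh(histology, spec.idh_counts)

    rows = []
    nawm_cov = spec.covariance(spec.nawm_mean)
    for i, h in enumerate(histology):
        mean = spec.group_means[_EFFECT_GROUP[h]]
        vec = rng.multivariate_normal(mean, spec.covariance(mean))
        nawm = rng.multivariate_normal(spec.nawm_mean, nawm_cov)
        row: dict[str, object] = {
            "patient_id": f"P{i + 1:03d}",
            "histology": h,
            "who_grade": _WHO_GRADE[h],
            "idh": idh[i],
            "codeletion_1p19q": "yes" if h.startswith("oligodendroglioma") else ("no" if idh[i] != "missing" else "missing"),
        }
        for j, p in enumerate(PARAMETER_NAMES):
            lo, hi = _CLIP[p]
            row[f"biopsy_{p}"] = float(np.clip(vec[j], lo if lo is not None else -np.inf, hi if hi is not None else np.inf))
            row[f"nawm_{p}"] = float(np.clip(nawm[j], lo if lo is not None else -np.inf, hi if hi is not None else np.inf))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(cohort: pd.DataFrame) -> dict[str, float]:
    """Case-mix bookkeeping: counts and percentages of the cohort table.

    Percentages are over all included patients, rounded to one decimal.
    """
    n = len(cohort)
    out: dict[str, float] = {"n_included": float(n)}

    def pct(k: int) -> float:
        return round(100.0 * k / n, 1)

    for h in HISTOLOGIES:
        k = int((cohort["histology"] == h).sum())
        out[f"n_{h}"] = float(k)
        out[f"pct_{h}"] = pct(k)
    for g in (2, 3, 4):
        k = int((cohort["who_grade"] == g).sum())
        out[f"n_who{g}"] = float(k)
        out[f"pct_who{g}"] = pct(k)
    k_hgg = int((cohort["who_grade"] >= 3).sum())
    out["n_hgg"] = float(k_hgg)
    out["pct_hgg"] = pct(k_hgg)
    out["n_lgg"] = float(n - k_hgg)
    out["pct_lgg"] = pct(n - k_hgg)
    for status in ("wildtype", "mutated", "missing"):
        k = int((cohort["idh"] == status).sum())
        out[f"n_idh_{status}"] = float(k)
        out[f"pct_idh_{status}"] = pct(k)
    return out
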