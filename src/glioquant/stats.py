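"""Two-group testing over the 12 parameters.

The decision tree per parameter: Shapiro-Wilk normality in each group
(alpha 0.05), Levene's test for variance homogeneity (mean-centered, alpha
0.05), then

* both groups normal + homogeneous variance  -> unpaired t-test
* both groups normal + inhomogeneous         -> Welch test
* any group non-normal                       -> Mann-Whitney U

All p-values are two-sided. With 12 a-priori parameter hypotheses per
contrast, significance is declared at the Bonferroni-adjusted level
alpha = 0.05 / 12 (0.004). The same battery run on the NAWM control ROIs
serves as a negative control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .images import PARAMETER_NAMES

CONTRASTS = ("lgg_vs_hgg", "idh_wt_vs_mut", "oligo_vs_astro_hg")

#: Combined sample size up to which the Mann-Whitney p is computed exactly.
_MW_EXACT_MAX_N = 20


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = len(PARAMETER_NAMES), digits: int = 3) -> float:
    """Per-test threshold alpha / m, rounded to the reported precision."""
    return round(family_alpha / n_tests, digits)


@dataclass
class GroupTestResult:
    parameter: str
    contrast: str
    roi_role: str
    n_a: int
    n_b: int
    shapiro_p_a: float
    shapiro_p_b: float
    levene_p: float
    chosen_test: str  # {"t", "welch", "mann_whitney"}
    statistic: float
    p_value: float
    significant: bool
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    sd_a: float
    sd_b: float


def select_test(normal_a: bool, normal_b: bool, homogeneous: bool) -> str:
    """Dispatch rule of the decision tree (total over all 8 flag settings).

    The homogeneous-but-non-normal cell goes to Mann-Whitney: rank tests
    keep their level under non-normality where the t-test may not.
    """
    if normal_a and normal_b:
        return "t" if homogeneous else "welch"
    return "mann_whitney"


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n_tot = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n_tot
    method = "exact" if (n_tot <= _MW_EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    adjusted_alpha: float = 0.05 / 12,
    parameter: str = "",
    contrast: str = "",
    roi_role: str = "biopsy",
    force_test: str | None = None,
) -> GroupTestResult:
    """Run the full decision tree on two samples.

    ``force_test`` bypasses the dispatch (used for oracle checks); normally
    the test is chosen from the Shapiro-Wilk and Levene pre-tests.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    for name, arr in (("a", a), ("b", b)):
        if len(arr) < 3:
            raise ValueError(f"group {name} has n = {len(arr)} < 3")

    sw_a = float(sps.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0
    sw_b = float(sps.shapiro(b).pvalue) if np.ptp(b) > 0 else 0.0
    lev = float(sps.levene(a, b, center="mean").pvalue) if np.ptp(np.concatenate([a, b])) > 0 else 1.0

    chosen = force_test or select_test(sw_a >= 0.05, sw_b >= 0.05, lev >= 0.05)
    if chosen == "t":
        res = sps.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    elif chosen == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif chosen == "mann_whitney":
        stat, p = _mann_whitney(a, b)
    else:
        raise ValueError(f"unknown test {chosen!r}")

    return GroupTestResult(
        parameter=parameter,
        contrast=contrast,
        roi_role=roi_role,
        n_a=len(a),
        n_b=len(b),
        shapiro_p_a=sw_a,
        shapiro_p_b=sw_b,
        levene_p=lev,
        chosen_test=chosen,
        statistic=stat,
        p_value=p,
        significant=bool(p < adjusted_alpha),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
    )


def contrast_groups(cohort: pd.DataFrame, contrast: str) -> tuple[pd.Series, pd.Series, str, str]:
    """Boolean membership masks (a, b) for a named contrast.

    lgg_vs_hgg: WHO grade 2 vs grades 3-4. idh_wt_vs_mut: wildtype vs
    mutated (missing excluded). oligo_vs_astro_hg: grade-3 oligodendroglioma
    vs high-grade astrocytic tumors (astrocytoma grades 3-4 + glioblastoma);
    grade-2 patients are excluded.
    """
    if contrast == "lgg_vs_hgg":
        a = cohort["who_grade"] == 2
        b = cohort["who_grade"].isin([3, 4])
        return a, b, "lgg", "hgg"
    if contrast == "idh_wt_vs_mut":
        a = cohort["idh"] == "wildtype"
        b = cohort["idh"] == "mutated"
        return a, b, "idh_wildtype", "idh_mutated"
    if contrast == "oligo_vs_astro_hg":
        high = cohort["who_grade"] >= 3
        a = high & cohort["histology"].str.startswith("oligodendroglioma")
        b = high & ~cohort["histology"].str.startswith("oligodendroglioma")
        return a, b, "oligo_hg", "astro_hg"
    raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")


def run_contrast_battery(
    cohort: pd.DataFrame,
    contrast: str,
    adjusted_alpha: float = 0.05 / 12,
    roles: tuple[str, ...] = ("biopsy", "nawm"),
) -> list[GroupTestResult]:
    """12 parameters x {biopsy, nawm} comparisons for one contrast."""
    mask_a, mask_b, name_a, name_b = contrast_groups(cohort, contrast)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(f"contrast {contrast}: a group is empty after label filtering")
    results = []
    for role in roles:
        for p in PARAMETER_NAMES:
            col = f"{role}_{p}"
            results.append(
                compare_groups(
                    cohort.loc[mask_a, col].to_numpy(),
                    cohort.loc[mask_b, col].to_numpy(),
                    adjusted_alpha=adjusted_alpha,
                    parameter=p,
                    contrast=contrast,
                    roi_role=role,
                )
            )
    return results


def results_table(results: list[GroupTestResult]) -> pd.DataFrame:
    """Flatten battery results to a report table (one row per test)."""
    df = pd.DataFrame([vars(r) for r in results])
    df["stars"] = np.where(df["significant"], "*", "")
    return df
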