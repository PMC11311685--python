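"""Logistic regression, forward selection with AIC, and ROC/Youden analysis.

Per contrast: a univariate binary logistic model per parameter (its AIC is
reported next to a ROC analysis on the raw measurement), then a forward
stepwise logistic model over all 12 parameters (candidates enter on a
likelihood-ratio test at alpha = 0.05) whose ROC is computed on the
predicted probability. AUC is the pairwise concordance statistic (ties
count 1/2); its 95% CI uses DeLong's variance; the operating point is the
cut-off maximizing Youden's J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .images import PARAMETER_NAMES

logger = logging.getLogger(__name__)

FORWARD_ENTRY_ALPHA = 0.05


@dataclass
class LogisticModel:
    predictors: list[str]
    coefficients: dict[str, float]
    intercept: float
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    error: str | None = None
    aic_path: list[tuple[str, float]] = field(default_factory=list)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.intercept)
        for name in self.predictors:
            eta = eta + self.coefficients[name] * X[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff_value: float
    cutoff_scale: str  # {"raw_parameter", "model_probability"}
    sensitivity: float
    specificity: float
    youden_j: float
    p_value: float  # AUC vs 0.5, DeLong normal approximation
    direction: str  # "greater": higher score predicts the positive class
    degenerate: bool = False


def fit_logistic(X: pd.DataFrame | np.ndarray, y: np.ndarray, names: list[str] | None = None) -> LogisticModel:
    """Maximum-likelihood binary logistic fit (Newton IRLS, tol 1e-8).

    Perfect separation (or any numerical failure) returns a model flagged
    non-converged with a named error state instead of raising; such models
    are reported but excluded from selection.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if Xa.shape[0] == 1 and len(np.asarray(y)) > 1:
            Xa = Xa.T
        names = names or [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError(f"need n >= 10 observations, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if not np.all(np.isfinite(Xa)):
        raise ValueError("predictors must be finite")

    design = sm.add_constant(Xa, has_constant="add")
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, method="newton", tol=1e-8, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        error = None
        # under (quasi-)separation Newton drives every fitted probability
        # onto its observed label and the likelihood to 0
        fitted = res.predict(design)
        if np.max(np.abs(y - fitted)) < 1e-3:
            converged, error = False, "perfect_separation"
    except Exception as exc:  # PerfectSeparationError and numerical failures
        logger.info("logistic fit failed (%s): %s", type(exc).__name__, exc)
        k = len(names) + 1
        return LogisticModel(names, {n: np.nan for n in names}, np.nan, np.nan, np.nan, len(y), False,
                             error="perfect_separation")
    coefs = {n: float(c) for n, c in zip(names, res.params[1:])}
    return LogisticModel(
        predictors=names,
        coefficients=coefs,
        intercept=float(res.params[0]),
        log_likelihood=float(res.llf),
        aic=float(2 * (len(names) + 1) - 2 * res.llf),
        n_obs=len(y),
        converged=converged,
        error=error,
    )


def _null_model(y: np.ndarray) -> LogisticModel:
    y = np.asarray(y, dtype=float)
    p = y.mean()
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return LogisticModel([], {}, float(np.log(p / (1 - p))), ll, 2 - 2 * ll, len(y), True)


def forward_select(X: pd.DataFrame, y: np.ndarray, entry_alpha: float = FORWARD_ENTRY_ALPHA) -> LogisticModel:
    """Forward stepwise logistic regression with likelihood-ratio entry.

    Starting from the intercept-only model, at each step the candidate with
    the smallest LR-test p-value enters if p < ``entry_alpha``; ties break
    by larger likelihood improvement, then by column-name order. The
    selected model carries its AIC path; if nothing enters, the
    intercept-only model is returned flagged.
    """
    y = np.asarray(y, dtype=float)
    candidates = sorted(X.columns)
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate predictors")
    current = _null_model(y)
    selected: list[str] = []
    path = [("(intercept)", current.aic)]

    while True:
        best: tuple[float, float, str, LogisticModel] | None = None
        for name in candidates:
            if name in selected:
                continue
            trial = fit_logistic(X[selected + [name]], y)
            if not trial.converged:
                continue
            lr = 2.0 * (trial.log_likelihood - current.log_likelihood)
            p = float(sps.chi2.sf(max(lr, 0.0), df=1))
            key = (p, -trial.log_likelihood, name)
            if best is None or key < (best[0], -best[3].log_likelihood, best[2]):
                best = (p, lr, name, trial)
        if best is None or best[0] >= entry_alpha:
            break
        selected.append(best[2])
        current = best[3]
        path.append((best[2], current.aic))

    if not selected:
        current.error = "no_candidate_entered"
    current.aic_path = path
    return current


# ---------------------------------------------------------------------------
# ROC


def auc_concordance(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the rank (Mann-Whitney) concordance statistic, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the AUC estimate via midrank components."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n  # P(score_neg < score_pos | this positive)
    v01 = 1.0 - (tz[m:] - ty) / m
    if m > 1 and n > 1:
        return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return float("nan")


def roc_analysis(scores: np.ndarray, y: np.ndarray, cutoff_scale: str = "raw_parameter") -> ROCResult:
    """AUC with DeLong 95% CI and the Youden-optimal operating point.

    Orientation is chosen internally so AUC >= 0.5 (``direction`` records
    whether high scores indicate the positive class); the cut-off scan runs
    over the observed score values with the decision rule score >= cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")

    if np.ptp(scores) == 0:
        return ROCResult(0.5, 0.5, 0.5, float(scores[0]), cutoff_scale, 1.0, 0.0, 0.0, 1.0, "greater", True)

    auc_raw = auc_concordance(scores, y)
    direction = "greater"
    s = scores
    if auc_raw < 0.5:
        direction = "less"
        s = -scores
    auc = auc_concordance(s, y)

    var = _delong_variance(s, y)
    se = np.sqrt(var) if np.isfinite(var) else np.nan
    z = sps.norm.ppf(0.975)
    ci_low = float(max(0.0, auc - z * se)) if np.isfinite(se) else 0.0
    ci_high = float(min(1.0, auc + z * se)) if np.isfinite(se) else 1.0
    if np.isfinite(se) and se > 0:
        p_value = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p_value = 1.0 if auc == 0.5 else 0.0

    best = None
    for thr in np.unique(s):
        pred = s >= thr
        sens = float(np.mean(pred[y == 1]))
        spec = float(np.mean(~pred[y == 0]))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    j, thr, sens, spec = best
    cutoff = float(-thr) if direction == "less" else float(thr)
    return ROCResult(
        auc=float(auc),
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff_value=cutoff,
        cutoff_scale=cutoff_scale,
        sensitivity=sens,
        specificity=spec,
        youden_j=float(j),
        p_value=p_value,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Report assembly


def build_report(cohort: pd.DataFrame, contrast: str, role: str = "biopsy") -> tuple[pd.DataFrame, dict]:
    """Per-contrast classification report: 12 univariate rows + 1 combined.

    Each single-parameter row carries the univariate logistic AIC and a ROC
    analysis on the raw measurement (cut-offs on the raw-data scale); the
    final row is the forward-selected multivariable model, with its ROC on
    the predicted probability and coefficients reported as weights. The
    second return value holds the selected model's details and AIC path.
    """
    from .stats import contrast_groups  # local import to avoid cycle

    mask_a, mask_b, name_a, name_b = contrast_groups(cohort, contrast)
    sub = cohort[mask_a | mask_b]
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(f"contrast {contrast}: empty class")
    # the second-listed group (higher grade / wildtype ordering per contrast
    # definition) is the positive class
    y = mask_b[mask_a | mask_b].to_numpy().astype(int)

    cols = [f"{role}_{p}" for p in PARAMETER_NAMES]
    X = sub[cols].copy()
    X.columns = list(PARAMETER_NAMES)
    keep = X.notna().all(axis=1).to_numpy()
    X, y = X[keep], y[keep]

    rows = []
    for p in PARAMETER_NAMES:
        uni = fit_logistic(X[[p]], y)
        roc = roc_analysis(X[p].to_numpy(), y, cutoff_scale="raw_parameter")
        rows.append(
            {
                "model": p,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "p_value": roc.p_value,
                "cutoff_value": roc.cutoff_value,
                "cutoff_scale": roc.cutoff_scale,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "aic": uni.aic,
                "weights": "",
                "converged": uni.converged,
            }
        )

    model = forward_select(X, y)
    proba = model.predict_proba(X)
    roc = roc_analysis(proba, y, cutoff_scale="model_probability")
    weights = "; ".join(f"{k} ({model.coefficients[k]:.4g})" for k in model.predictors)
    rows.append(
        {
            "model": " + ".join(model.predictors) if model.predictors else "(intercept)",
            "auc": roc.auc,
            "ci_low": roc.ci_low,
            "ci_high": roc.ci_high,
            "p_value": roc.p_value,
            "cutoff_value": roc.cutoff_value,
            "cutoff_scale": roc.cutoff_scale,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "aic": model.aic,
            "weights": weights,
            "converged": model.converged,
        }
    )
    df = pd.DataFrame(rows)
    conv = df[df["converged"]]
    df["lowest_aic"] = False
    if len(conv):
        df.loc[conv["aic"].idxmin(), "lowest_aic"] = True
    details = {
        "contrast": contrast,
        "positive_class": name_b,
        "selected_predictors": model.predictors,
        "coefficients": model.coefficients,
        "intercept": model.intercept,
        "aic_path": model.aic_path,
        "n_obs": int(model.n_obs),
    }
    return df, details
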