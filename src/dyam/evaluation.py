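"""Biomarker evaluation protocol.

Classifier performance is always assessed on merged out-of-fold predictions:
patients are randomly sorted into ten folds, the model (including any
feature selection and rescaling, which estimators perform inside ``fit``) is
refit on each training fold, and the held-out scores are merged so every
patient is scored exactly once.  The merged AUC carries a DeLong confidence
interval; significance against meaningless labels comes from permutation
testing with the DeLong variance and the null s.e.m. propagated in
quadrature; sensitivity to the training sample comes from repeated 90/10
subsampling.  Survival readouts (Kaplan-Meier, log-rank, score-quartile
progression ratios, proportional-hazards fits) are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from sklearn.base import clone
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score, roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "tenfold_cv",
    "auc_delong",
    "permutation_null",
    "subsample_stability",
    "calibrate_youden",
    "km_logrank",
    "quartile_pfs_ratio",
    "fit_proportional_hazards",
    "EvaluationReport",
    "evaluate_model",
]


# -- input dispatch --------------------------------------------------------

def _detect_kind(X, n: int) -> str:
    """Matrix (n, d) / per-patient bags (list of n (k_i, d)) / per-modality
    blocks (list of M (n, d_m)).  A list whose length equals n is read as
    bags; pass ``X_kind`` explicitly to disambiguate tiny cohorts."""
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return "matrix"
    if isinstance(X, (list, tuple)):
        if len(X) == n:
            return "bags"
        if all(np.asarray(b).ndim == 2 and np.asarray(b).shape[0] == n for b in X):
            return "blocks"
        return "bags"
    raise ValueError("unsupported input container")


def _take(X, idx, kind: str):
    if kind == "matrix":
        return X[idx]
    if kind == "bags":
        return [X[i] for i in idx]
    if kind == "blocks":
        return [b[idx] for b in X]
    raise ValueError(kind)


def tenfold_cv(X, y, estimator, seed: int = 0, n_folds: int = 10, X_kind: str = "auto") -> np.ndarray:
    """Merged out-of-fold scores from ``n_folds``-fold cross-validation.

    ``X`` may be a (n, d) matrix, a list of per-patient instance bags, or a
    list of per-modality blocks (each (n, d_m)); ``X_kind`` overrides the
    container autodetection with "matrix" / "bags" / "blocks".  Folds are
    random; if plain random folding leaves a training fold single-class the
    split falls back to class-stratified folding (logged).
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} patients")
    kind = _detect_kind(X, n) if X_kind == "auto" else X_kind
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [np.sort(order[i::n_folds]) for i in range(n_folds)]
    if any(len(np.unique(y[np.setdiff1d(np.arange(n), f)])) < 2 for f in folds):
        logger.info("random folding left a single-class training fold; stratifying")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [test for _, test in skf.split(np.zeros(n), y)]
    scores = np.full(n, np.nan)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        est = clone(estimator)
        est.fit(_take(X, train, kind), y[train])
        scores[fold] = est.predict_proba(_take(X, fold, kind))[:, 1]
    assert not np.isnan(scores).any()
    return scores


# -- AUC with DeLong variance ---------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i + 1
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def auc_delong(scores, labels, alpha: float = 0.05):
    """AUC (Mann-Whitney, ties count half) with a DeLong confidence interval.

    Returns ``(auc, (lo, hi), variance)``; the interval is the normal
    approximation from the DeLong variance, truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # placements of positives among negatives
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    var = s01 / m + s10 / n
    from scipy.stats import norm

    half = norm.ppf(1 - alpha / 2.0) * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), ci, float(var)


@dataclass
class PermutationNull:
    null_mean: float
    null_sd: float
    n_sigma: float
    stars: int
    null_aucs: np.ndarray


def permutation_null(X, y, estimator, n_iter: int = 20, seed: int = 0,
                     n_folds: int = 10, X_kind: str = "auto") -> PermutationNull:
    """Merged-CV AUC null distribution under label permutation.

    The full cross-validation pipeline is re-run ``n_iter`` times on permuted
    labels; significance is the distance of the observed AUC from the null
    mean in units of sqrt(DeLong variance + null s.e.m.^2), with 1-4 stars
    for 1-4+ such s.d.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    y = np.asarray(y, dtype=int)
    obs_scores = tenfold_cv(X, y, estimator, seed=seed, n_folds=n_folds, X_kind=X_kind)
    auc, _, var = auc_delong(obs_scores, y)
    rng = np.random.default_rng(seed)
    null_aucs = []
    for it in range(n_iter):
        yp = rng.permutation(y)
        if len(np.unique(yp)) < 2:  # cannot happen for permutations, kept for safety
            continue
        sc = tenfold_cv(X, yp, estimator, seed=seed + it + 1, n_folds=n_folds, X_kind=X_kind)
        null_aucs.append(auc_delong(sc, yp)[0])
    null_aucs = np.asarray(null_aucs)
    null_mean = float(null_aucs.mean())
    null_sd = float(null_aucs.std(ddof=1))
    sem = null_sd / np.sqrt(len(null_aucs))
    combined = float(np.sqrt(var + sem**2))
    n_sigma = (auc - null_mean) / combined if combined > 0 else 0.0
    stars = int(min(4, max(0, np.floor(n_sigma))))
    return PermutationNull(null_mean, null_sd, float(n_sigma), stars, null_aucs)


def subsample_stability(X, y, estimator, n_iter: int = 100, train_frac: float = 0.9,
                        seed: int = 0, X_kind: str = "auto") -> np.ndarray:
    """Test-split AUCs over repeated random 90/10 subsampling."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    kind = _detect_kind(X, n) if X_kind == "auto" else X_kind
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))
    aucs = []
    for it in range(n_iter):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            logger.info("subsample iteration %d degenerate; skipped", it)
            continue
        est = clone(estimator)
        est.fit(_take(X, train, kind), y[train])
        sc = est.predict_proba(_take(X, test, kind))[:, 1]
        aucs.append(auc_delong(sc, y[test])[0])
    return np.asarray(aucs)


def calibrate_youden(scores, labels):
    """Youden-index threshold and unit-variance rescaled scores.

    The threshold maximizes sensitivity + specificity - 1 over the observed
    scores.  Constant scores admit no threshold and raise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.ptp(scores) == 0:
        raise ValueError("constant scores: Youden threshold undefined")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    threshold = float(thresholds[best])
    rescaled = scores / scores.std()
    return threshold, rescaled


def binary_metrics(scores, labels, threshold: float) -> dict[str, float]:
    pred = (np.asarray(scores) >= threshold).astype(int)
    return {
        "accuracy": float(accuracy_score(labels, pred)),
        "recall": float(recall_score(labels, pred, zero_division=0)),
        "precision": float(precision_score(labels, pred, zero_division=0)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
    }


# -- survival readouts -----------------------------------------------------

def km_logrank(times, events, group):
    """Kaplan-Meier curves per group and the log-rank test across groups.

    Returns ``(curves, statistic, p_value)`` where ``curves`` maps group
    label to a DataFrame with columns ``time`` and ``survival``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    labels = np.unique(group)
    if any((group == g).sum() == 0 for g in labels) or len(labels) < 1:
        raise ValueError("empty group")
    curves = {}
    for g in labels:
        sel = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.values, "survival": sf.iloc[:, 0].values})
    if len(labels) == 1:
        return curves, 0.0, 1.0
    if len(labels) == 2:
        res = logrank_test(times[group == labels[0]], times[group == labels[1]],
                           events[group == labels[0]], events[group == labels[1]])
    else:
        res = multivariate_logrank_test(times, group, events)
    return curves, float(res.test_statistic), float(res.p_value)


def quartile_pfs_ratio(scores, times, events, horizon_months: float = 4.0):
    """Ratio of progression events by ``horizon_months`` between the top and
    bottom score quartiles, with a Poisson-propagated 95% CI.

    ``scores`` must be oriented as risk (higher = earlier progression); the
    top quartile is the highest-risk quarter.  Returns
    ``(ratio, (lo, hi), events_top, events_bottom)``.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(scores)
    if n < 8:
        raise ValueError("need at least 8 patients for quartiles")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    bottom = scores <= q1
    top = scores >= q3
    progressed = (events == 1) & (times <= horizon_months)
    e_top = int((progressed & top).sum())
    e_bot = int((progressed & bottom).sum())
    if e_bot == 0:
        raise ValueError("no events in the bottom quartile by the horizon: ratio undefined")
    ratio = e_top / e_bot
    if e_top == 0:
        return 0.0, (0.0, np.inf), e_top, e_bot
    se_log = np.sqrt(1.0 / e_top + 1.0 / e_bot)
    ci = (ratio * np.exp(-1.96 * se_log), ratio * np.exp(1.96 * se_log))
    return float(ratio), ci, e_top, e_bot


def fit_proportional_hazards(covariate_table: pd.DataFrame, times, events):
    """Cox proportional-hazards fit (lifelines) over a covariate table.

    Returns a dict with per-covariate hazard ratios and CIs, the
    likelihood-ratio p value and the concordance index.  Missing covariates
    or exactly collinear columns raise.
    """
    cov = pd.DataFrame(covariate_table).copy()
    if cov.isna().any().any():
        raise ValueError("missing covariate entries")
    mat = cov.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([mat, np.ones(len(mat))])) <= mat.shape[1]:
        raise ValueError("collinear covariates")
    df = cov.copy()
    df["__time"] = np.asarray(times, dtype=float)
    df["__event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="__time", event_col="__event")
    summary = cph.summary
    lr = cph.log_likelihood_ratio_test()
    return {
        "hazard_ratios": summary["exp(coef)"].to_dict(),
        "ci_lower": summary["exp(coef) lower 95%"].to_dict(),
        "ci_upper": summary["exp(coef) upper 95%"].to_dict(),
        "coef": summary["coef"].to_dict(),
        "coef_se": summary["se(coef)"].to_dict(),
        "lr_p_value": float(lr.p_value),
        "concordance": float(cph.concordance_index_),
    }


# -- full protocol ---------------------------------------------------------

@dataclass
class EvaluationReport:
    """Merged-CV scores and the derived performance readouts."""

    merged_scores: np.ndarray
    auc: float
    ci95: tuple[float, float]
    delong_var: float
    threshold: float
    metrics: dict[str, float]
    permutation: PermutationNull | None = None

    def to_dict(self) -> dict:
        out = {
            "auc": self.auc,
            "ci95": list(self.ci95),
            "threshold": self.threshold,
            **self.metrics,
        }
        if self.permutation is not None:
            out.update(
                null_mean=self.permutation.null_mean,
                null_sd=self.permutation.null_sd,
                n_sigma=self.permutation.n_sigma,
                stars=self.permutation.stars,
            )
        return out


def evaluate_model(X, y, estimator, seed: int = 0, n_folds: int = 10,
                   n_permutations: int = 0, X_kind: str = "auto") -> EvaluationReport:
    """Run the merged-CV protocol end to end for one model."""
    y = np.asarray(y, dtype=int)
    scores = tenfold_cv(X, y, estimator, seed=seed, n_folds=n_folds, X_kind=X_kind)
    auc, ci, var = auc_delong(scores, y)
    threshold, _ = calibrate_youden(scores, y)
    metrics = binary_metrics(scores, y, threshold)
    perm = None
    if n_permutations:
        perm = permutation_null(X, y, estimator, n_iter=n_permutations, seed=seed,
                                n_folds=n_folds, X_kind=X_kind)
    return EvaluationReport(scores, auc, ci, var, threshold, metrics, perm)
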