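"""Univariate ROC/bootstrap patient stratification and Youden cut-off.

Patients are classified RP-positive when their region parameter (mean
baseline-corrected T2, ms) is greater than or equal to a threshold —
elevated corrected T2 indicates radiation-induced change.  The ROC curve is
obtained by systematic thresholding over the observed values; internal
validation resamples patients with replacement (5000 bootstrap samples by
default), evaluates every replicate's ROC on a fixed 101-point FPR grid and
reports the pointwise median curve with 95% percentile bands.  The
classification cut-off maximizes the Youden index

    J = sensitivity + specificity - 1

along the median ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "roc_curve",
    "roc_auc",
    "RocSummary",
    "bootstrap_roc",
    "mann_whitney_u",
    "youden_index",
    "CutoffResult",
    "optimal_cutoff",
]


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("ROC analysis requires both classes present")


def _roc_points(values: np.ndarray, labels: np.ndarray):
    """Step-curve vertices of the 'predict RP when value >= t' classifier.

    Returns (thresholds, fpr, tpr) with a +inf sentinel at (0, 0); one
    vertex per distinct value, swept from high to low.
    """
    order = np.argsort(-values, kind="stable")
    v = values[order]
    y = labels[order]
    n1 = int(y.sum())
    n0 = y.size - n1
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep the last index of each tie group (all samples >= that value counted)
    last = np.r_[v[1:] != v[:-1], True]
    thresholds = np.r_[np.inf, v[last]]
    tpr = np.r_[0.0, tps[last] / n1]
    fpr = np.r_[0.0, fps[last] / n0]
    return thresholds, fpr, tpr


def roc_curve(values, labels):
    """ROC curve by systematic thresholding of the parameter values.

    Parameters
    ----------
    values:
        Per-patient parameter values (ms).
    labels:
        Binary outcome, 1 = RP grade >= 1, 0 = grade 0.

    Returns
    -------
    (thresholds, fpr, tpr):
        Step-curve vertices; the classifier predicts RP for
        ``value >= threshold``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be matching 1D arrays")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    _check_two_classes(labels)
    return _roc_points(values, labels)


def roc_auc(fpr, tpr) -> float:
    """Trapezoidal area under a (fpr, tpr) step curve."""
    return float(np.trapezoid(tpr, fpr))


def _tpr_on_grid(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Vertical interpolation of one ROC curve onto a fixed FPR grid.

    Vertical segments (duplicate FPR) are collapsed to their upper envelope
    — the TPR the step classifier actually attains at that FPR.
    """
    uniq, idx = np.unique(fpr, return_index=True)
    # np.unique keeps the first occurrence; take the max tpr per fpr instead
    env = np.maximum.reduceat(tpr, idx) if idx.size else tpr
    env = np.maximum.accumulate(env)
    return np.interp(grid, uniq, env)


@dataclass
class RocSummary:
    """Bootstrap summary of a univariate ROC analysis."""

    fpr_grid: np.ndarray
    tpr_median: np.ndarray
    tpr_lo: np.ndarray
    tpr_hi: np.ndarray
    auc_median: float
    auc_lo: float
    auc_hi: float
    n_boot: int
    seed: int | None
    n_redraws: int = 0


def bootstrap_roc(
    values,
    labels,
    n_boot: int = 5000,
    seed: int | None = None,
    n_grid: int = 101,
    resample: bool = True,
) -> RocSummary:
    """Median ROC curve and 95% CI from patient-level bootstrapping.

    Patients are resampled with replacement (cohort size preserved,
    unstratified); replicates that lose one class entirely are redrawn and
    counted in ``n_redraws``.  Each replicate's ROC is evaluated on the
    common FPR grid; the summary holds the pointwise median and 2.5/97.5
    percentiles, and the median/CI of the replicate trapezoidal AUCs.

    With ``resample=False`` every "replicate" is the original cohort — a
    degenerate bootstrap whose median curve is the plain empirical ROC
    (used as an oracle for cut-off extraction).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_grid)
    n = values.size

    tpr_mat = np.empty((n_boot, n_grid))
    aucs = np.empty(n_boot)
    n_redraws = 0
    for b in range(n_boot):
        if resample:
            while True:
                idx = rng.integers(0, n, size=n)
                yb = labels[idx]
                if 0 < yb.sum() < n:
                    break
                n_redraws += 1
            vb = values[idx]
        else:
            vb, yb = values, labels
        _, fpr, tpr = _roc_points(vb, yb)
        tpr_mat[b] = _tpr_on_grid(fpr, tpr, grid)
        aucs[b] = np.trapezoid(tpr, fpr)

    tpr_lo, tpr_med, tpr_hi = np.percentile(tpr_mat, [2.5, 50.0, 97.5], axis=0)
    auc_lo, auc_med, auc_hi = np.percentile(aucs, [2.5, 50.0, 97.5])
    return RocSummary(
        fpr_grid=grid,
        tpr_median=tpr_med,
        tpr_lo=tpr_lo,
        tpr_hi=tpr_hi,
        auc_median=float(auc_med),
        auc_lo=float(auc_lo),
        auc_hi=float(auc_hi),
        n_boot=n_boot,
        seed=seed,
        n_redraws=n_redraws,
    )


def mann_whitney_u(group_rp, group_non_rp, alpha: float = 0.05):
    """Two-sided Mann-Whitney U test between the RP and non-RP parameters.

    Uses the exact null distribution when both groups have <= 12
    observations and there are no ties, otherwise the normal approximation
    with tie correction.  Returns ``(U, p_two_sided, significant)`` where U
    counts pairs with RP value above non-RP value (+ half the ties), so
    U / (n1 * n0) equals the ROC AUC.
    """
    x = np.asarray(group_rp, dtype=float)
    y = np.asarray(group_non_rp, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.r_[x, y]
    has_ties = np.unique(combined).size < combined.size
    if np.ptp(combined) == 0:
        # all values identical: the tie-corrected normal SD degenerates to 0
        return float(x.size * y.size / 2.0), 1.0, False
    method = "exact" if (x.size <= 12 and y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return float(res.statistic), p, p < alpha


def youden_index(sens: float, spec: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return sens + spec - 1.0


@dataclass
class CutoffResult:
    """Youden-optimal operating point of the median ROC curve."""

    youden_max: float
    cutoff_ms: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def optimal_cutoff(summary: RocSummary, values, labels) -> CutoffResult:
    """Maximize J = TPR_median - FPR over the grid and map back to a cut-off.

    Ties in the maximum resolve to the smallest FPR.  The threshold is the
    empirical midpoint threshold on the non-RP values whose false-positive
    rate is nearest the optimal grid FPR (ties -> larger threshold), which
    reproduces the (1 - fpr) quantile at interior operating points and
    yields a separating cut-off under perfect separation.  The reported
    sensitivity/specificity are read off the median curve so that
    ``youden_max = sens + spec - 1`` holds exactly.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    j = summary.tpr_median - summary.fpr_grid
    i = int(np.argmax(j))  # argmax returns the first (= smallest fpr) maximum
    fpr_star = float(summary.fpr_grid[i])

    neg = np.sort(values[labels == 0])
    pooled = np.sort(values)
    n0 = neg.size
    # candidate k = number of false positives: the threshold sits just above
    # the (k+1)-th largest non-RP value (midpoint to the next pooled value,
    # keeping sensitivity maximal at that FPR); candidate fpr is k/n0
    cand_fpr = np.arange(n0) / n0
    k = int(np.argmin(np.abs(cand_fpr - fpr_star)))  # first minimum -> smaller fpr
    lower = neg[n0 - k - 1]
    above = pooled[pooled > lower]
    cutoff = float(0.5 * (lower + above[0]) if above.size else lower + 1.0)

    return CutoffResult(
        youden_max=float(j[i]),
        cutoff_ms=cutoff,
        sens_at_cutoff=float(summary.tpr_median[i]),
        spec_at_cutoff=float(1.0 - fpr_star),
    )
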