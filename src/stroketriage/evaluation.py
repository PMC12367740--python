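"""Assessment machinery for the triage models.

Confusion-matrix metrics with percentile-bootstrap confidence intervals,
ROC/AUC, reliability (calibration) curves, quantile-binned fairness
audits (demographic parity and equalized odds differences), the group
statistical tests used for cohort description (Shapiro–Wilk,
Mann–Whitney U, Pearson chi-squared), permutation-based feature
attribution, and side-by-side population comparisons of the cascade
against the rule-based scale baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from stroketriage.cohort import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "confusion_metrics",
    "recover_matrix_from_metrics",
    "bootstrap_ci",
    "roc_auc",
    "CalibrationCurve",
    "calibration_curve",
    "quantile_bins",
    "FairnessReport",
    "fairness_report",
    "fairness_from_rates",
    "GroupTestReport",
    "chi2_independence",
    "mann_whitney_u",
    "shapiro_wilk",
    "feature_attribution",
    "population_comparison",
]


# ---------------------------------------------------------------------------
# confusion-matrix metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(int)
        p = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((t == 1) & (p == 1)).sum()),
            fp=int(((t == 0) & (p == 1)).sum()),
            tn=int(((t == 0) & (p == 0)).sum()),
            fn=int(((t == 1) & (p == 0)).sum()),
        )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Closed-form metrics as fractions; undefined ratios are None, not 0."""
    if cm.total < 1:
        raise ValidationError("confusion matrix must hold at least one count")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and (precision + recall) > 0
        else None
    )
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "precision": precision,
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "recall": recall,
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "f1": f1,
    }


def recover_matrix_from_metrics(
    targets: Mapping[str, float],
    max_total: int = 30,
    decimals: int = 2,
) -> ConfusionMatrix:
    """Find the unique confusion matrix (total ≤ max_total) whose metrics
    round (as percentages, to ``decimals``) to the printed targets.

    Useful to reconstruct a matrix from a published table of rounded
    metrics. Scalar multiples of a matrix share every metric, so
    uniqueness is required only up to scaling and the smallest matrix is
    returned. Raises if no matrix — or more than one primitive matrix —
    matches.
    """
    matches: list[ConfusionMatrix] = []
    for total in range(1, max_total + 1):
        for tp in range(total + 1):
            for fp in range(total - tp + 1):
                for tn in range(total - tp - fp + 1):
                    cm = ConfusionMatrix(tp, fp, tn, total - tp - fp - tn)
                    m = confusion_metrics(cm)
                    ok = True
                    for name, want in targets.items():
                        got = m.get(name)
                        if got is None or round(100 * got, decimals) != round(want, decimals):
                            ok = False
                            break
                    if ok:
                        matches.append(cm)
    if not matches:
        raise ValidationError(f"no confusion matrix with total <= {max_total} matches {dict(targets)}")

    def _primitive(cm: ConfusionMatrix) -> tuple[int, int, int, int]:
        g = int(np.gcd.reduce([cm.tp, cm.fp, cm.tn, cm.fn]))
        return (cm.tp // g, cm.fp // g, cm.tn // g, cm.fn // g)

    primitives = {_primitive(cm) for cm in matches}
    if len(primitives) > 1:
        raise ValidationError(
            f"{len(primitives)} distinct matrices match {dict(targets)}; metrics underdetermined"
        )
    return ConfusionMatrix(*primitives.pop())


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    predictions: Sequence,
    labels: Sequence,
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for ``metric(labels, predictions)``.

    The point estimate comes from the original sample; resamples on
    which the metric is undefined (raises or returns NaN) are skipped
    and counted in the log.
    """
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if len(pred) < 2:
        raise ValidationError("bootstrap needs at least 2 observations")
    point = metric(lab, pred)
    if point is None or (isinstance(point, float) and np.isnan(point)):
        raise ValidationError("metric undefined on the original sample")
    rng = np.random.default_rng(seed)
    values, skipped = [], 0
    n = len(pred)
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            v = metric(lab[idx], pred[idx])
        except Exception:
            skipped += 1
            continue
        if v is None or (isinstance(v, float) and np.isnan(v)):
            skipped += 1
            continue
        values.append(v)
    if skipped:
        logger.info("bootstrap_ci: %d/%d resamples skipped (undefined metric)", skipped, n_resamples)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(values, [alpha, 1 - alpha])
    return float(point), float(lo), float(hi)


# ---------------------------------------------------------------------------
# ROC / calibration

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank statistic; ties at half weight)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("ROC AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class CalibrationCurve:
    """Equal-width reliability bins; empty bins are omitted."""

    bins: tuple[tuple[float, float, float, float, int], ...]
    # each: (lower, upper, mean_predicted, fraction_positive, count)

    @property
    def max_deviation(self) -> float:
        return max(abs(b[3] - b[2]) for b in self.bins)


def calibration_curve(
    probs: Sequence[float],
    labels: Sequence[int],
    n_bins: int = 10,
) -> CalibrationCurve:
    """Bin predicted probabilities on an equal-width [0, 1] grid and
    compare the mean prediction with the observed positive fraction."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            (
                float(edges[b]),
                float(edges[b + 1]),
                float(p[mask].mean()),
                float(y[mask].mean()),
                int(mask.sum()),
            )
        )
    return CalibrationCurve(bins=tuple(rows))


def quantile_bins(values: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Quantile-based bin index per value (0-based, monotone in value).

    With fewer distinct quantile boundaries than requested, fewer bins
    are returned with a warning.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    if len(v) < n_bins:
        raise ValidationError(f"need at least {n_bins} values for {n_bins} quantile bins")
    codes = pd.qcut(v, q=n_bins, labels=False, duplicates="drop")
    realized = int(codes.nunique())
    if realized < n_bins:
        warnings.warn(
            f"only {realized} distinct quantile bins realizable (requested {n_bins})",
            stacklevel=2,
        )
    return codes.to_numpy()


# ---------------------------------------------------------------------------
# fairness

@dataclass(frozen=True)
class FairnessReport:
    """Per-group selection rate / TPR / FPR with parity summaries.

    ``dpd`` — demographic parity difference, the spread of selection
    rates; ``eod`` — equalized odds difference, the largest TPR or FPR
    gap over group pairs. Groups with undefined rates are excluded from
    the corresponding summary.
    """

    groups: tuple[str, ...]
    selection_rate: tuple[float, ...]
    tpr: tuple[float | None, ...]
    fpr: tuple[float | None, ...]
    dpd: float
    eod: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "selection_rate": self.selection_rate,
                "tpr": self.tpr,
                "fpr": self.fpr,
            }
        )


def fairness_from_rates(
    selection_rates: Sequence[float],
    tprs: Sequence[float | None],
    fprs: Sequence[float | None],
) -> tuple[float, float]:
    """(dpd, eod) from per-group rates given as fractions in [0, 1]."""
    sel = [s for s in selection_rates if s is not None]
    dpd = max(sel) - min(sel)
    gaps = []
    for rates in (tprs, fprs):
        known = [r for r in rates if r is not None]
        if len(known) >= 2:
            gaps.append(max(known) - min(known))
    eod = max(gaps) if gaps else 0.0
    return float(dpd), float(eod)


def fairness_report(
    predictions: Sequence[int],
    labels: Sequence[int],
    groups: Sequence,
) -> FairnessReport:
    """Audit binary predictions across (at least two) groups."""
    pred = np.asarray(predictions).astype(int)
    lab = np.asarray(labels).astype(int)
    grp = np.asarray(groups)
    names = [str(g) for g in pd.unique(grp)]
    if len(names) < 2:
        raise ValidationError("fairness audit needs at least 2 groups")
    sel, tprs, fprs = [], [], []
    for g in pd.unique(grp):
        mask = grp == g
        sel.append(float(pred[mask].mean()))
        pos, neg = mask & (lab == 1), mask & (lab == 0)
        tprs.append(float(pred[pos].mean()) if pos.any() else None)
        fprs.append(float(pred[neg].mean()) if neg.any() else None)
        if not pos.any() or not neg.any():
            logger.info("fairness_report: group %r lacks positives or negatives; "
                        "excluded from the equalized-odds summary", g)
    dpd, eod = fairness_from_rates(sel, tprs, fprs)
    return FairnessReport(
        groups=tuple(names),
        selection_rate=tuple(sel),
        tpr=tuple(tprs),
        fpr=tuple(fprs),
        dpd=dpd,
        eod=eod,
    )


# ---------------------------------------------------------------------------
# group statistical tests

@dataclass(frozen=True)
class GroupTestReport:
    test: str
    statistic: float
    p_value: float
    dof: int | None = None


def chi2_independence(table: Sequence[Sequence[float]]) -> GroupTestReport:
    """Pearson chi-squared test of independence (no continuity correction)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(arr < 0):
        raise ValidationError("contingency table counts must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero marginal")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return GroupTestReport("chi_squared", float(stat), float(p), int(dof))


def mann_whitney_u(sample_x: Sequence[float], sample_y: Sequence[float]) -> GroupTestReport:
    """Two-tailed Mann–Whitney U (Wilcoxon rank-sum); U reported for x.

    Exact enumeration for untied samples of at most 8 per side, normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupTestReport("mann_whitney_u", float(res.statistic), float(res.pvalue))


def shapiro_wilk(sample: Sequence[float]) -> GroupTestReport:
    """Shapiro–Wilk normality test (delegated to scipy)."""
    res = stats.shapiro(np.asarray(sample, dtype=float))
    return GroupTestReport("shapiro_wilk", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# attribution

def feature_attribution(
    model,
    X: pd.DataFrame,
    y: Sequence,
    method: str = "permutation",
    n_repeats: int = 10,
    seed: int = 0,
    scoring: str = "roc_auc",
) -> pd.DataFrame:
    """Ranked nonnegative feature importances.

    ``permutation``: mean score drop over ``n_repeats`` shuffles of each
    column (negative drops floored at 0). ``shap_library``: delegates to
    the shap package when installed.
    """
    estimator = getattr(model, "pipeline", model)
    feature_names = getattr(model, "feature_names", None) or list(
        X.columns if hasattr(X, "columns") else range(np.asarray(X).shape[1])
    )
    if method == "permutation":
        res = permutation_importance(
            estimator, X, np.asarray(y), scoring=scoring, n_repeats=n_repeats, random_state=seed
        )
        importance = np.clip(res.importances_mean, 0.0, None)
    elif method == "shap_library":
        try:
            import shap  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the 'shap_library' method requires the shap package; "
                "use method='permutation' instead"
            ) from exc
        explainer = shap.Explainer(estimator.predict, X)
        importance = np.abs(explainer(X).values).mean(axis=0)
    else:
        raise ValidationError(f"unknown attribution method {method!r}")
    out = pd.DataFrame({"feature": feature_names, "importance": importance})
    return out.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# population comparison

def _band(delta: float, tol: float = 0.05) -> str:
    if delta > tol:
        return "better"
    if delta < -tol:
        return "worse"
    return "comparable"


def population_comparison(
    model_results: Mapping[str, tuple[Sequence[int], Sequence[int]]],
    baseline_results: Mapping[str, tuple[Sequence[int], Sequence[int]]],
    band_tolerance: float = 0.05,
) -> pd.DataFrame:
    """Per-subset, per-class precision/recall/F1 for model vs baseline.

    Inputs map subset name → (y_true, y_pred). The signed delta is
    baseline − model, banded at ±``band_tolerance`` into
    better / comparable / worse (from the baseline's perspective).
    Empty subsets are reported with absent metrics.
    """
    rows = []
    for subset, (y_true, y_pred) in model_results.items():
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        base = baseline_results.get(subset)
        for cls in (0, 1):
            if len(y_true) == 0:
                rows.append({"subset": subset, "class": cls})
                continue
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=[cls], zero_division=0
            )
            row = {
                "subset": subset,
                "class": cls,
                "model_precision": float(p[0]),
                "model_recall": float(r[0]),
                "model_f1": float(f[0]),
            }
            if base is not None and len(base[0]) > 0:
                bp, br, bf, _ = precision_recall_fscore_support(
                    np.asarray(base[0]), np.asarray(base[1]), labels=[cls], zero_division=0
                )
                for name, mv, bv in (
                    ("precision", float(p[0]), float(bp[0])),
                    ("recall", float(r[0]), float(br[0])),
                    ("f1", float(f[0]), float(bf[0])),
                ):
                    row[f"baseline_{name}"] = bv
                    row[f"delta_{name}"] = bv - mv
                    row[f"band_{name}"] = _band(bv - mv, band_tolerance)
            rows.append(row)
    return pd.DataFrame(rows)
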