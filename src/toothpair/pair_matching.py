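"""Pair enumeration, ROC threshold calibration, classification and statistics.

A *symmetric* pair compares the right tooth of an individual with the
mirrored left tooth of the same individual (a true match); a *nonsymmetric*
pair crosses individuals.  With n individuals there are n symmetric and
n(n-1) nonsymmetric comparisons per tooth type (one direction per ordered
pair: right vs mirrored left).

Classification calls a pair a match when its symmetric Hausdorff distance is
at or below a threshold.  The operating threshold is the largest observed HD
retaining 100% specificity — i.e. the point of maximal sensitivity with zero
false positives on the calibration set; the alternative rule is the smallest
HD giving 100% sensitivity (the largest symmetric-pair HD).
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "PairComparison",
    "RocCurve",
    "Threshold",
    "Classification",
    "enumerate_pairs",
    "compute_roc",
    "threshold_full_specificity",
    "threshold_full_sensitivity",
    "classify",
    "cohens_kappa",
    "one_way_anova",
    "jitter_export",
    "HausdorffPairClassifier",
]


@dataclasses.dataclass
class PairComparison:
    """One HD measurement between a right element and a mirrored left element."""

    right_individual: str
    left_individual: str
    tooth_type: str
    element_kind: str
    hd: float = float("nan")

    @property
    def is_symmetric(self) -> bool:
        return self.right_individual == self.left_individual


def enumerate_pairs(individual_ids, tooth_type: str, element_kind: str = "crown"):
    """All ordered (right of i, mirrored left of j) comparisons for one tooth type.

    n individuals -> n symmetric (i = j) plus n(n-1) nonsymmetric (i != j)
    comparison stubs with the HD left unfilled.
    """
    ids = list(individual_ids)
    return [
        PairComparison(ri, lj, tooth_type, element_kind)
        for ri in ids
        for lj in ids
    ]


def _split_values(comparisons):
    sym, nonsym = [], []
    for c in comparisons:
        (sym if c.is_symmetric else nonsym).append(float(c.hd))
    return np.asarray(sym), np.asarray(nonsym)


@dataclasses.dataclass
class RocCurve:
    """ROC over candidate thresholds = the sorted distinct observed HD values."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    symmetric_values: np.ndarray
    nonsymmetric_values: np.ndarray


def compute_roc(comparisons) -> RocCurve:
    """Sweep every distinct observed HD as the match threshold (hd <= t positive)."""
    sym, nonsym = _split_values(comparisons)
    if len(sym) == 0 or len(nonsym) == 0:
        raise ValueError("need at least one symmetric and one nonsymmetric pair")
    if np.any(np.isnan(sym)) or np.any(np.isnan(nonsym)):
        raise ValueError("comparisons contain unfilled HD values")
    thresholds = np.unique(np.concatenate([sym, nonsym]))
    sym_sorted = np.sort(sym)
    non_sorted = np.sort(nonsym)
    tp = np.searchsorted(sym_sorted, thresholds, side="right")
    fp = np.searchsorted(non_sorted, thresholds, side="right")
    sens = tp / len(sym)
    spec = (len(nonsym) - fp) / len(nonsym)
    fpr = np.concatenate([[0.0], 1 - spec])
    tpr = np.concatenate([[0.0], sens])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, sens, spec, auc, sym_sorted, non_sorted)


@dataclasses.dataclass
class Threshold:
    value: float
    degenerate: bool = False


def threshold_full_specificity(roc: RocCurve) -> Threshold:
    """Largest candidate threshold with specificity 1 (zero false positives).

    This is the operating point maximizing sensitivity subject to 100%
    specificity.  If even the smallest observed HD belongs to a nonsymmetric
    pair, no positive-sensitivity threshold qualifies and a degenerate
    threshold below all observed values is returned, flagged.
    """
    ok = roc.specificity == 1.0
    if not ok.any():
        lo = float(roc.thresholds[0])
        return Threshold(lo - max(1e-9, 1e-9 * abs(lo)), degenerate=True)
    return Threshold(float(roc.thresholds[ok].max()))


def threshold_full_sensitivity(roc: RocCurve) -> Threshold:
    """Smallest threshold with sensitivity 1: the largest symmetric-pair HD."""
    return Threshold(float(roc.symmetric_values.max()))


@dataclasses.dataclass
class Classification:
    """Confusion counts of pair matching at a fixed HD threshold."""

    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total


def classify(comparisons, threshold) -> Classification:
    """Confusion counts with match <=> hd <= threshold (ties positive)."""
    t = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    sym, nonsym = _split_values(comparisons)
    tp = int((sym <= t).sum())
    fp = int((nonsym <= t).sum())
    return Classification(t, tp, len(sym) - tp, len(nonsym) - fp, fp)


@dataclasses.dataclass
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float


def cohens_kappa(table) -> KappaResult:
    """Cohen's kappa for a square 2-rater contingency table, with 95% CI.

    k = (p_o - p_e) / (1 - p_e); the CI uses the large-sample standard error
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)) and z = 1.96.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("contingency table must be square")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    po = np.trace(t) / n
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        raise ValueError("chance agreement is 1; kappa undefined")
    k = (po - pe) / (1 - pe)
    se = float(np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)))
    return KappaResult(float(k), se, float(k - 1.96 * se), float(k + 1.96 * se))


@dataclasses.dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False


def one_way_anova(groups) -> AnovaResult:
    """Standard one-way between/within variance decomposition.

    Zero within-group variance with nonzero between-group variance is
    reported as F = inf, p = 0 with the degenerate flag set.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([len(a) for a in arrays])
    if ns.min() < 1:
        raise ValueError("empty group")
    total_n = int(ns.sum())
    dfb, dfw = len(arrays) - 1, total_n - len(arrays)
    if dfw < 1:
        raise ValueError("not enough residual degrees of freedom")
    grand = np.concatenate(arrays).mean()
    means = np.array([a.mean() for a in arrays])
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw)
        return AnovaResult(float("inf"), 0.0, dfb, dfw, degenerate=True)
    f = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(f), float(stats.f.sf(f, dfb, dfw)), dfb, dfw)


def jitter_export(comparisons, threshold, max_true_negatives: int = 100) -> pd.DataFrame:
    """Labelled HD values for jitter plotting.

    Exports every true-positive and false-negative symmetric pair, plus the
    smallest ``min(max_true_negatives, count)`` true-negative values, per
    (tooth_type, element_kind) group.
    """
    t = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    rows = []
    groups: dict[tuple, list] = {}
    for c in comparisons:
        groups.setdefault((c.tooth_type, c.element_kind), []).append(c)
    for (tooth_type, element_kind), comps in sorted(groups.items()):
        tn_vals = []
        for c in comps:
            if c.is_symmetric:
                label = "TP" if c.hd <= t else "FN"
                rows.append((tooth_type, element_kind, label, float(c.hd)))
            elif c.hd > t:
                tn_vals.append(float(c.hd))
        for v in sorted(tn_vals)[:max_true_negatives]:
            rows.append((tooth_type, element_kind, "TN", v))
    return pd.DataFrame(
        rows, columns=["tooth_type", "element_kind", "label", "hd"]
    )


class HausdorffPairClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style HD-threshold pair matcher.

    fit(X, y) calibrates the match threshold on HD values ``X`` (shape (n,)
    or (n, 1), mm) with binary labels ``y`` (1 = symmetric/true pair);
    predict(X) returns 1 where ``hd <= threshold_``.

    Parameters
    ----------
    rule : {"full_specificity", "full_sensitivity"} or float
        Threshold calibration rule, or a fixed threshold in mm.
    """

    def __init__(self, rule="full_specificity"):
        self.rule = rule

    @staticmethod
    def _values(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("X must be a vector of HD values")
        return x

    def fit(self, X, y):
        x = self._values(X)
        y = np.asarray(y).astype(bool).ravel()
        if len(x) != len(y):
            raise ValueError("X and y length mismatch")
        comps = [
            PairComparison("a", "a" if yi else "b", "any", "any", xi)
            for xi, yi in zip(x, y)
        ]
        if isinstance(self.rule, (int, float)):
            self.threshold_ = float(self.rule)
            self.roc_ = None
        else:
            self.roc_ = compute_roc(comps)
            if self.rule == "full_specificity":
                self.threshold_ = threshold_full_specificity(self.roc_).value
            elif self.rule == "full_sensitivity":
                self.threshold_ = threshold_full_sensitivity(self.roc_).value
            else:
                raise ValueError(f"unknown rule {self.rule!r}")
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        if not hasattr(self, "threshold_"):
            raise ValueError("classifier is not fitted")
        return (self._values(X) <= self.threshold_).astype(int)
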