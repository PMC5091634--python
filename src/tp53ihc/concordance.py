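"""Cross-tabulation of IHC staining against TP53 mutation class and the derived
diagnostic-performance metrics.

Two evaluations are supported:

* **binary** — any abnormal staining (OE, CA or CY) predicts the presence of a
  deleterious TP53 mutation; normal (WT) staining predicts its absence;
* **ternary** — OE predicts GOF, CA predicts LOF and WT predicts NDM; cases
  with cytoplasmic staining are excluded from the ternary comparison because
  CY maps to no single class.

Cases unscored for IHC (non-assessable cores) are excluded from both modes and
reported in the exclusion tally, never silently dropped.  Metrics follow the
standard diagnostic-test definitions with one-vs-rest sensitivity/specificity
per class in ternary mode, balanced accuracy = (sensitivity + specificity)/2,
and an exact (Clopper-Pearson) 95% binomial interval on overall accuracy.
Undefined metrics (zero denominators) propagate as ``None`` with a warning,
never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .predict import PATTERNS, UNSCORED

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "KappaResult",
    "build_confusion",
    "binary_metrics",
    "ternary_metrics",
    "metrics_for",
    "cohens_kappa",
    "ABNORMAL_PATTERNS",
    "PATTERN_TO_CLASS",
]

#: Patterns counted as "abnormal" for the binary mutation-presence classifier.
ABNORMAL_PATTERNS = ("OE", "CA", "CY")
#: Ternary mapping of scored pattern to the mutation class it predicts.
PATTERN_TO_CLASS = {"OE": "GOF", "CA": "LOF", "WT": "NDM"}

BINARY_ROWS = ("abnormal", "normal")
BINARY_COLS = ("deleterious", "NDM")
TERNARY_ROWS = ("OE", "CA", "WT")
TERNARY_COLS = ("GOF", "LOF", "NDM")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of predicted label (rows) against truth label (columns)."""

    mode: str  # {"binary", "ternary"}
    cells: pd.DataFrame
    excluded: Dict[str, int]
    method_id: int = 1

    @property
    def included(self) -> int:
        return int(self.cells.to_numpy().sum())

    @property
    def cohort_size(self) -> int:
        return self.included + sum(self.excluded.values())

    def __post_init__(self) -> None:
        arr = self.cells.to_numpy()
        if (arr < 0).any():
            raise ValueError("confusion-matrix cells must be non-negative")


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity family; ``None`` marks an undefined (0/0) metric."""

    mode: str
    sensitivity: Optional[float]
    specificity: Optional[float]
    balanced_accuracy: Optional[float]
    overall_accuracy: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_included: int
    per_class: Dict[str, Dict[str, Optional[float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_included": self.n_included,
        }
        if self.per_class:
            d["per_class"] = self.per_class
        return d


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    n: int
    observed_agreement: float
    expected_agreement: float


def _pattern_series(cohort: pd.DataFrame, method_id: int) -> pd.Series:
    col = f"pattern_m{method_id}"
    if col not in cohort.columns:
        raise KeyError(f"cohort has no staining column {col!r}")
    patterns = cohort[col]
    valid = set(PATTERNS) | {UNSCORED}
    bad = cohort.loc[~patterns.isin(valid) & patterns.notna(), "case_id"]
    if len(bad):
        raise ValueError(
            "unknown staining pattern token for case(s): " + ", ".join(map(str, bad))
        )
    return patterns


def build_confusion(
    cohort: pd.DataFrame, mode: str, method_id: int = 1
) -> ConfusionMatrix:
    """Cross-tabulate one assay method's staining against the mutation class.

    The cohort must carry ``case_id``, ``functional_class`` and a
    ``pattern_m<method_id>`` column (see
    :func:`tp53ihc.classify.classify_cohort`).  Missing pattern values count as
    unscored.
    """
    if mode not in ("binary", "ternary"):
        raise ValueError(f"mode must be 'binary' or 'ternary', got {mode!r}")
    if "functional_class" not in cohort.columns:
        raise KeyError("cohort lacks a functional_class column; classify it first")
    patterns = _pattern_series(cohort, method_id).fillna(UNSCORED)
    fclass = cohort["functional_class"].astype(str)

    unscored_mask = patterns == UNSCORED
    excluded = {"unscored": int(unscored_mask.sum()), "cytoplasmic": 0}
    keep = ~unscored_mask

    if mode == "binary":
        rows, cols = BINARY_ROWS, BINARY_COLS
        pred = np.where(patterns[keep].isin(ABNORMAL_PATTERNS), "abnormal", "normal")
        truth = np.where(fclass[keep] == "NDM", "NDM", "deleterious")
    else:
        cy_mask = keep & (patterns == "CY")
        excluded["cytoplasmic"] = int(cy_mask.sum())
        keep = keep & ~cy_mask
        rows, cols = TERNARY_ROWS, TERNARY_COLS
        pred = patterns[keep].to_numpy()
        truth = fclass[keep].to_numpy()

    cells = (
        pd.crosstab(pd.Series(pred, name="predicted"), pd.Series(truth, name="truth"))
        .reindex(index=rows, columns=cols, fill_value=0)
        .astype(int)
    )
    return ConfusionMatrix(mode=mode, cells=cells, excluded=excluded, method_id=method_id)


def _ratio(num: int, den: int, what: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{what} undefined: zero denominator", stacklevel=3)
        return None
    return num / den


def _mean2(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    return (a + b) / 2


def _accuracy_ci(correct: int, n: int) -> Tuple[Optional[float], Optional[float]]:
    if n == 0:
        return None, None
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="beta")
    return float(lo), float(hi)


def binary_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity/specificity of abnormal staining for deleterious mutation."""
    if cm.mode != "binary":
        raise ValueError("binary_metrics requires a binary confusion matrix")
    c = cm.cells
    tp = int(c.loc["abnormal", "deleterious"])
    fn = int(c.loc["normal", "deleterious"])
    tn = int(c.loc["normal", "NDM"])
    fp = int(c.loc["abnormal", "NDM"])
    n = cm.included
    sens = _ratio(tp, tp + fn, "binary sensitivity")
    spec = _ratio(tn, tn + fp, "binary specificity")
    acc = _ratio(tp + tn, n, "binary overall accuracy")
    lo, hi = _accuracy_ci(tp + tn, n)
    return DiagnosticMetrics(
        mode="binary", sensitivity=sens, specificity=spec,
        balanced_accuracy=_mean2(sens, spec), overall_accuracy=acc,
        ci_low=lo, ci_high=hi, n_included=n,
    )


def ternary_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """One-vs-rest metrics per class (GOF/LOF/NDM) plus overall accuracy."""
    if cm.mode != "ternary":
        raise ValueError("ternary_metrics requires a ternary confusion matrix")
    c = cm.cells
    n = cm.included
    arr = c.to_numpy()
    trace = int(np.trace(arr))
    per_class: Dict[str, Dict[str, Optional[float]]] = {}
    for i, klass in enumerate(TERNARY_COLS):
        row = TERNARY_ROWS[i]  # the pattern predicting this class
        tp = int(c.loc[row, klass])
        class_total = int(c[klass].sum())
        pred_total = int(c.loc[row].sum())
        fp = pred_total - tp
        rest = n - class_total
        sens = _ratio(tp, class_total, f"{klass} sensitivity")
        spec = _ratio(rest - fp, rest, f"{klass} specificity")
        per_class[klass] = {
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": _mean2(sens, spec),
        }
    acc = _ratio(trace, n, "ternary overall accuracy")
    lo, hi = _accuracy_ci(trace, n)
    return DiagnosticMetrics(
        mode="ternary", sensitivity=None, specificity=None, balanced_accuracy=None,
        overall_accuracy=acc, ci_low=lo, ci_high=hi, n_included=n,
        per_class=per_class,
    )


def metrics_for(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Dispatch to the metric family matching the matrix mode."""
    return binary_metrics(cm) if cm.mode == "binary" else ternary_metrics(cm)


def cohens_kappa(
    ratings_a: Sequence[str], ratings_b: Sequence[str]
) -> KappaResult:
    """Unweighted (equal-weights) Cohen's kappa between two raters.

    Computed from the raters' contingency table over whatever labels occur:
    kappa = (p_o - p_e) / (1 - p_e) with p_e from the product of marginals.
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError(
            f"rating lists differ in length ({len(ratings_a)} vs {len(ratings_b)})"
        )
    n = len(ratings_a)
    if n == 0:
        raise ValueError("cannot compute kappa on empty ratings")
    a = pd.Series(ratings_a)
    b = pd.Series(ratings_b)
    table = pd.crosstab(a, b)
    labels = sorted(set(table.index) | set(table.columns))
    table = table.reindex(index=labels, columns=labels, fill_value=0)
    arr = table.to_numpy(dtype=float)
    p_o = np.trace(arr) / n
    p_e = float(np.sum(arr.sum(axis=1) * arr.sum(axis=0)) / n**2)
    kappa = 1.0 if p_e == 1.0 and p_o == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa), n=n,
        observed_agreement=float(p_o), expected_agreement=p_e,
    )
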