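"""Model/Results interface over the concordance analysis.

``ConcordanceModel`` holds a classified cohort plus the evaluation settings;
``fit()`` cross-tabulates and estimates the diagnostic metrics, returning a
``ConcordanceResults`` with the confusion matrix, the point estimates, the
exact 95% interval on overall accuracy and a printable ``summary()`` table.

    >>> from tp53ihc import datasets, ConcordanceModel
    >>> res = ConcordanceModel(datasets.load_table4_cohort(), mode="binary").fit()
    >>> round(res.metrics.sensitivity, 2)
    0.96
"""

from __future__ import annotations

from typing import Dict, Optional

import pandas as pd

from .classify import classify_cohort
from .concordance import (
    ConfusionMatrix,
    DiagnosticMetrics,
    build_confusion,
    metrics_for,
)

__all__ = ["ConcordanceModel", "ConcordanceResults"]


class ConcordanceModel:
    """Diagnostic-concordance model of IHC staining vs TP53 mutation class.

    Parameters
    ----------
    cohort : pandas.DataFrame
        One row per case with ``case_id``, ``variant`` and ``pattern_m<k>``
        columns.  If the derived ``functional_class`` column is missing the
        cohort is classified on construction.
    mode : {"binary", "ternary"}
        Binary = abnormal-vs-normal staining against deleterious-vs-NDM;
        ternary = OE/CA/WT against GOF/LOF/NDM with CY excluded.
    method : int
        Assay method whose staining column is evaluated (1-4).
    """

    def __init__(self, cohort: pd.DataFrame, mode: str = "binary", method: int = 1):
        if mode not in ("binary", "ternary"):
            raise ValueError(f"mode must be 'binary' or 'ternary', got {mode!r}")
        if "functional_class" not in cohort.columns:
            cohort = classify_cohort(cohort)
        self.cohort = cohort
        self.mode = mode
        self.method = method

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, mode: str = "binary", method: int = 1
    ) -> "ConcordanceModel":
        return cls(df, mode=mode, method=method)

    @classmethod
    def from_csv(
        cls, path, mode: str = "binary", method: int = 1, sep: str = ","
    ) -> "ConcordanceModel":
        from .io import read_cohort

        return cls(read_cohort(path, sep=sep), mode=mode, method=method)

    def fit(self) -> "ConcordanceResults":
        cm = build_confusion(self.cohort, self.mode, self.method)
        return ConcordanceResults(self, cm, metrics_for(cm))


class ConcordanceResults:
    """Fitted concordance estimates with their uncertainty and diagnostics."""

    def __init__(
        self,
        model: ConcordanceModel,
        confusion: ConfusionMatrix,
        metrics: DiagnosticMetrics,
    ):
        self.model = model
        self.confusion = confusion
        self.metrics = metrics

    @property
    def excluded(self) -> Dict[str, int]:
        return self.confusion.excluded

    def to_dict(self) -> dict:
        return {
            "mode": self.confusion.mode,
            "method": self.confusion.method_id,
            "confusion": {
                row: self.confusion.cells.loc[row].to_dict()
                for row in self.confusion.cells.index
            },
            "excluded": dict(self.confusion.excluded),
            "n_included": self.confusion.included,
            "metrics": self.metrics.to_dict(),
        }

    @staticmethod
    def _fmt(x: Optional[float]) -> str:
        return "   undef" if x is None else f"{x:8.3f}"

    def summary(self) -> str:
        cm, m = self.confusion, self.metrics
        lines = [
            "IHC / TP53 mutation concordance",
            "=" * 47,
            f"mode: {cm.mode:<10} assay method: {cm.method_id}",
            f"cases included: {cm.included}   "
            f"excluded: unscored={cm.excluded['unscored']}, "
            f"cytoplasmic={cm.excluded['cytoplasmic']}",
            "-" * 47,
            "Confusion matrix (predicted x truth)",
            cm.cells.to_string(),
            "-" * 47,
        ]
        if cm.mode == "binary":
            lines += [
                f"sensitivity        {self._fmt(m.sensitivity)}",
                f"specificity        {self._fmt(m.specificity)}",
                f"balanced accuracy  {self._fmt(m.balanced_accuracy)}",
            ]
        else:
            lines.append(f"{'class':<6}{'sens':>8}{'spec':>8}{'bal.acc':>9}")
            for klass, vals in m.per_class.items():
                lines.append(
                    f"{klass:<6}"
                    f"{self._fmt(vals['sensitivity'])}"
                    f"{self._fmt(vals['specificity'])}"
                    f"{self._fmt(vals['balanced_accuracy']).rjust(9)}"
                )
        lines.append(f"overall accuracy   {self._fmt(m.overall_accuracy)}")
        if m.ci_low is not None:
            lines.append(f"95% CI (exact)     [{m.ci_low:.3f}, {m.ci_high:.3f}]")
        lines.append("=" * 47)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ConcordanceResults mode={self.confusion.mode} "
            f"method={self.confusion.method_id} n={self.confusion.included}>"
        )
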