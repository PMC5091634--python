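"""Discordant-case triage and auditable revision bookkeeping.

A discordance is a case whose observed staining contradicts its sequencing
class: in binary mode, abnormal staining without a deleterious mutation (or
normal staining with one); in ternary mode, an observed OE/CA/WT whose implied
class (GOF/LOF/NDM) differs from the sequencing class.  Cytoplasmic and
unscored cases are reported in a separate advisory list, never silently
dropped.

Revisions are external evidence (re-staining of full sections, re-sequencing)
booked as records, never inferred by the software.  Applying them returns a
new cohort plus an audit log; every record's ``old_value`` must match the
cohort's current state, so re-applying an already-applied record set fails
loudly instead of double-applying.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .classify import classify_cohort
from .concordance import ABNORMAL_PATTERNS, PATTERN_TO_CLASS, build_confusion, metrics_for
from .predict import PATTERNS, UNSCORED

__all__ = [
    "RevisionRecord",
    "StaleRevisionError",
    "find_discordant",
    "apply_revisions",
    "primary_vs_revised_report",
]


class StaleRevisionError(ValueError):
    """A revision's old_value no longer matches the cohort (stale or re-applied)."""


@dataclass(frozen=True)
class RevisionRecord:
    case_id: str
    field: str  # {"ihc_pattern", "mutation"}
    old_value: str
    new_value: str
    evidence: str = ""
    method_id: int = 1  # which assay's staining column an ihc_pattern revision targets

    def __post_init__(self) -> None:
        if self.field not in ("ihc_pattern", "mutation"):
            raise ValueError(f"unknown revision field {self.field!r}")


def _implied_class(pattern: str) -> Optional[str]:
    return PATTERN_TO_CLASS.get(pattern)


def find_discordant(
    cohort: pd.DataFrame, mode: str = "ternary", method_id: int = 1
) -> Tuple[List[dict], List[dict]]:
    """Cases whose staining contradicts their mutation class.

    Returns ``(discordant, advisory)``: each discordant entry carries the
    case id, observed pattern, mutation class and a mismatch descriptor; the
    advisory list holds unscored cases (both modes) and cytoplasmic cases
    (ternary mode), which cannot be adjudicated by the classifier.
    """
    if mode not in ("binary", "ternary"):
        raise ValueError(f"mode must be 'binary' or 'ternary', got {mode!r}")
    if "functional_class" not in cohort.columns:
        cohort = classify_cohort(cohort)
    col = f"pattern_m{method_id}"
    discordant: List[dict] = []
    advisory: List[dict] = []
    for _, row in cohort.iterrows():
        pattern = row[col]
        fclass = row["functional_class"]
        if pd.isna(pattern) or pattern == UNSCORED:
            advisory.append({
                "case_id": row["case_id"], "pattern": UNSCORED,
                "functional_class": fclass, "reason": "not assessable",
            })
            continue
        if mode == "binary":
            abnormal = pattern in ABNORMAL_PATTERNS
            deleterious = fclass != "NDM"
            if abnormal != deleterious:
                discordant.append({
                    "case_id": row["case_id"], "pattern": pattern,
                    "functional_class": fclass,
                    "mismatch": (
                        "normal staining with deleterious mutation"
                        if deleterious else "abnormal staining without mutation"
                    ),
                })
        else:
            implied = _implied_class(pattern)
            if implied is None:  # CY maps to no single class
                advisory.append({
                    "case_id": row["case_id"], "pattern": pattern,
                    "functional_class": fclass, "reason": "cytoplasmic staining",
                })
            elif implied != fclass:
                discordant.append({
                    "case_id": row["case_id"], "pattern": pattern,
                    "functional_class": fclass,
                    "mismatch": f"{pattern} implies {implied}, sequencing says {fclass}",
                })
    return discordant, advisory


def apply_revisions(
    cohort: pd.DataFrame, revisions: Sequence[RevisionRecord]
) -> Tuple[pd.DataFrame, List[dict]]:
    """Apply revision records to a copy of the cohort; returns (revised, audit log).

    The original cohort is untouched.  Derived classification columns are
    recomputed after mutation revisions.  Unknown case ids and stale
    ``old_value`` entries raise.
    """
    revised = cohort.copy()
    audit: List[dict] = []
    index = {cid: i for i, cid in zip(revised.index, revised["case_id"])}
    for rec in revisions:
        if rec.case_id not in index:
            raise KeyError(f"revision names unknown case {rec.case_id!r}")
        i = index[rec.case_id]
        col = f"pattern_m{rec.method_id}" if rec.field == "ihc_pattern" else "variant"
        current = revised.at[i, col]
        if str(current) != str(rec.old_value):
            raise StaleRevisionError(
                f"case {rec.case_id}: expected {rec.field}={rec.old_value!r}, "
                f"cohort holds {current!r}"
            )
        if rec.field == "ihc_pattern" and rec.new_value not in (*PATTERNS, UNSCORED):
            raise ValueError(f"unknown staining pattern {rec.new_value!r}")
        revised.at[i, col] = rec.new_value
        audit.append({
            "case_id": rec.case_id, "field": rec.field, "column": col,
            "old_value": rec.old_value, "new_value": rec.new_value,
            "evidence": rec.evidence,
        })
    if any(rec.field == "mutation" for rec in revisions) or "functional_class" not in revised.columns:
        revised = classify_cohort(revised.drop(
            columns=[c for c in ("mutation_type", "indel_frame", "functional_class")
                     if c in revised.columns]
        ))
    return revised, audit


def primary_vs_revised_report(
    cohort: pd.DataFrame,
    revisions: Sequence[RevisionRecord],
    mode: str = "binary",
    method_id: int = 1,
) -> dict:
    """Diagnostic metrics before and after applying revisions, with deltas."""
    if "functional_class" not in cohort.columns:
        cohort = classify_cohort(cohort)
    primary = metrics_for(build_confusion(cohort, mode, method_id))
    revised_cohort, audit = apply_revisions(cohort, revisions)
    revised = metrics_for(build_confusion(revised_cohort, mode, method_id))
    deltas: Dict[str, Optional[float]] = {}
    for key in ("sensitivity", "specificity", "balanced_accuracy", "overall_accuracy"):
        a, b = getattr(primary, key), getattr(revised, key)
        deltas[key] = None if a is None or b is None else b - a
    return {
        "mode": mode,
        "method": method_id,
        "primary": primary.to_dict(),
        "revised": revised.to_dict(),
        "deltas": deltas,
        "audit": audit,
    }
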