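"""Mutation-type taxonomy and GOF/LOF/NDM functional classification.

The class scheme follows the diagnostic convention for p53: any nonsynonymous
(missense) mutation is treated as gain-of-function (GOF) because the mutant
protein escapes MDM2-mediated degradation and accumulates; stopgain, indel and
splicing mutations are loss-of-function (LOF); synonymous changes and absent
mutations are "no detectable mutation" (NDM).  The functional class is a pure
function of the mutation type, so the partition {GOF, LOF, NDM} is total and
auditable.

Note the deliberate decoupling from staining prediction: an in-frame indel is
class LOF here even though it is expected to stain like a missense mutation
(see :mod:`tp53ihc.predict`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .reference import ProteinVariant, VariantKind, parse_variant_field

__all__ = [
    "MutationType",
    "FunctionalClass",
    "mutation_type_of",
    "functional_class_of",
    "is_deleterious",
    "classify_case",
    "classify_cohort",
    "MUTATION_TYPE_VALUES",
]

MUTATION_TYPE_VALUES = (
    "nonsynonymous", "stopgain", "indel", "splicing", "synonymous", "none",
)


class FunctionalClass(str, Enum):
    GOF = "GOF"
    LOF = "LOF"
    NDM = "NDM"


@dataclass(frozen=True)
class MutationType:
    """One of the six reportable mutation types; indels carry a frame qualifier."""

    value: str
    indel_frame: Optional[str] = None  # {"inframe", "frameshift"} iff value == "indel"

    def __post_init__(self) -> None:
        if self.value not in MUTATION_TYPE_VALUES:
            raise ValueError(f"unknown mutation type {self.value!r}")
        if (self.value == "indel") != (self.indel_frame is not None):
            raise ValueError("indel_frame must be present exactly for indels")
        if self.indel_frame is not None and self.indel_frame not in ("inframe", "frameshift"):
            raise ValueError(f"unknown indel frame qualifier {self.indel_frame!r}")


_KIND_TO_TYPE = {
    VariantKind.STOPGAIN: MutationType("stopgain"),
    VariantKind.DELETION_INFRAME: MutationType("indel", "inframe"),
    VariantKind.INSERTION_INFRAME: MutationType("indel", "inframe"),
    VariantKind.FRAMESHIFT: MutationType("indel", "frameshift"),
    VariantKind.SPLICING: MutationType("splicing"),
    VariantKind.SYNONYMOUS: MutationType("synonymous"),
    VariantKind.NONE: MutationType("none"),
}


def mutation_type_of(variant: ProteinVariant) -> MutationType:
    """Map a parsed variant onto the reportable taxonomy (total, deterministic)."""
    if variant.kind is VariantKind.SUBSTITUTION:
        if variant.alt_aa == "*":
            return MutationType("stopgain")
        if variant.ref_aa is not None and variant.ref_aa == variant.alt_aa:
            return MutationType("synonymous")
        return MutationType("nonsynonymous")
    return _KIND_TO_TYPE[variant.kind]


def functional_class_of(mtype: MutationType) -> FunctionalClass:
    """GOF for nonsynonymous; LOF for stopgain/indel/splicing; NDM otherwise."""
    if mtype.value == "nonsynonymous":
        return FunctionalClass.GOF
    if mtype.value in ("stopgain", "indel", "splicing"):
        return FunctionalClass.LOF
    return FunctionalClass.NDM


def is_deleterious(mtype: MutationType) -> bool:
    """True iff the mutation type implies a deleterious (GOF or LOF) mutation."""
    return functional_class_of(mtype) is not FunctionalClass.NDM


# Priority for multi-variant cases: most disruptive first, conservative toward LOF.
_PRIORITY = (
    MutationType("stopgain"),
    MutationType("indel", "frameshift"),
    MutationType("splicing"),
    MutationType("indel", "inframe"),
    MutationType("nonsynonymous"),
    MutationType("synonymous"),
    MutationType("none"),
)
_RANK = {mt: i for i, mt in enumerate(_PRIORITY)}


def classify_case(variants: Sequence[ProteinVariant]):
    """Classify a case that may carry several variants.

    Returns ``(primary_variant, mutation_type, functional_class, multi_hit)``
    where the primary variant is chosen by the fixed disruption priority
    stopgain > frameshift > splicing > in-frame indel > nonsynonymous >
    synonymous > none.  An empty sequence classifies as NDM.
    """
    if not variants:
        v = parse_variant_field(None)
        return v, MutationType("none"), FunctionalClass.NDM, False
    typed = [(v, mutation_type_of(v)) for v in variants]
    typed.sort(key=lambda pair: _RANK[pair[1]])
    primary, mtype = typed[0]
    multi_hit = sum(is_deleterious(mt) for _, mt in typed) > 1
    return primary, mtype, functional_class_of(mtype), multi_hit


def classify_cohort(cohort: pd.DataFrame, variant_col: str = "variant") -> pd.DataFrame:
    """Add derived ``mutation_type``, ``indel_frame`` and ``functional_class`` columns.

    Returns a new frame; the input is not modified.  Variant strings are parsed
    with :func:`tp53ihc.reference.parse_variant_field`, so both protein- and
    coding-level HGVS plus the NDM sentinel are accepted.
    """
    out = cohort.copy()
    mtypes = [mutation_type_of(parse_variant_field(v)) for v in out[variant_col]]
    out["mutation_type"] = [mt.value for mt in mtypes]
    out["indel_frame"] = [mt.indel_frame for mt in mtypes]
    out["functional_class"] = [functional_class_of(mt).value for mt in mtypes]
    return out
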