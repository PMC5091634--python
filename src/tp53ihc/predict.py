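"""Mechanistic prediction of the expected p53 IHC staining pattern.

The rules model what the DO-7 antibody (epitope at amino acids 19-26) can see
of the mutant protein:

* missense (nonsynonymous) mutations stabilise p53 -> nuclear overexpression (OE);
* truncating mutations with a premature termination codon before codon 213
  trigger nonsense-mediated RNA decay -> no protein -> complete absence (CA);
* terminations at or after codon 245 leave an expressed, N-terminally intact
  truncated protein; if its length falls in 292-306 aa the nuclear localization
  signal (aa 316-325) is lost and the protein accumulates in the cytoplasm (CY),
  otherwise the truncated protein reads as wild-type-pattern staining (WT);
* stop codons in the unruled 213-244 window are predicted CA with
  ``ambiguous`` confidence (CA is the majority truncating outcome);
* splicing mutations default to CA at low confidence;
* in-frame indels are expected to behave conformationally like missense
  mutations -> OE at low confidence;
* synonymous or absent mutations -> WT.

Every prediction carries a rule trace so discordance review can audit exactly
which rules fired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .classify import FunctionalClass, functional_class_of, mutation_type_of
from .reference import (
    DomainMap,
    ProteinVariant,
    VariantKind,
    default_domain_map,
    parse_variant_field,
)

__all__ = [
    "ProteinProduct",
    "PredictedPattern",
    "predict_protein_product",
    "predict_ihc_pattern",
    "pattern_concordant",
    "predict_cohort",
    "NotAssessableError",
    "PATTERNS",
    "UNSCORED",
]

PATTERNS = ("OE", "CA", "WT", "CY")
UNSCORED = "unscored"

FULL_LENGTH = "full_length"


class NotAssessableError(ValueError):
    """Raised when concordance is requested against an unscored observation."""


@dataclass(frozen=True)
class ProteinProduct:
    """The protein consequence of a variant, as visible to IHC."""

    expressed: bool
    predicted_length_aa: Optional[Union[int, str]]  # int, FULL_LENGTH, or None if unknown
    nmd_predicted: bool
    retains_epitope: bool
    retains_nls: bool
    confidence: str  # {"high", "low", "ambiguous"}

    def __post_init__(self) -> None:
        if self.nmd_predicted and self.expressed:
            raise ValueError("an NMD-degraded transcript yields no expressed protein")
        if self.retains_nls and isinstance(self.predicted_length_aa, int):
            if self.predicted_length_aa < default_domain_map().nls[1]:
                raise ValueError("NLS retention requires the product to span the NLS")


@dataclass(frozen=True)
class PredictedPattern:
    pattern: str  # one of PATTERNS
    confidence: str  # {"high", "low", "ambiguous"}
    rationale: str  # ordered, ';'-separated trace of the rules fired

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown staining pattern {self.pattern!r}")


def _truncation_product(
    ptc_codon: int, domains: DomainMap, exact_stop: bool
) -> ProteinProduct:
    """Product of a premature termination codon; exact for stopgains, proxy for frameshifts."""
    confidence = "high" if exact_stop else "low"
    if ptc_codon < domains.nmd_ca_max_codon:
        return ProteinProduct(
            expressed=False, predicted_length_aa=None, nmd_predicted=True,
            retains_epitope=False, retains_nls=False, confidence=confidence,
        )
    if ptc_codon < domains.expressed_min_codon:
        # the 213-244 window is unruled by observation; declare the ambiguity
        return ProteinProduct(
            expressed=False, predicted_length_aa=None, nmd_predicted=False,
            retains_epitope=False, retains_nls=False, confidence="ambiguous",
        )
    length = ptc_codon - 1
    return ProteinProduct(
        expressed=True, predicted_length_aa=length, nmd_predicted=False,
        retains_epitope=length >= domains.do7_epitope[1],
        retains_nls=length >= domains.nls[1],
        confidence=confidence,
    )


def predict_protein_product(
    variant: ProteinVariant, domains: Optional[DomainMap] = None
) -> ProteinProduct:
    """Predict expression, length and domain retention of the mutant protein.

    Frameshift termination uses the frameshift start codon as the premature
    termination codon (a lower bound within a few codons of the true shifted
    stop, which depends on nucleotide context); the product therefore carries
    ``low`` confidence whenever it is expressed.
    """
    domains = domains or default_domain_map()
    k = variant.kind

    if k is VariantKind.STOPGAIN or (
        k is VariantKind.SUBSTITUTION and variant.alt_aa == "*"
    ):
        return _truncation_product(variant.codon_start, domains, exact_stop=True)
    if k is VariantKind.FRAMESHIFT:
        return _truncation_product(variant.codon_start, domains, exact_stop=False)
    if k is VariantKind.SPLICING:
        return ProteinProduct(
            expressed=False, predicted_length_aa=None, nmd_predicted=False,
            retains_epitope=False, retains_nls=False, confidence="low",
        )
    if k in (VariantKind.DELETION_INFRAME, VariantKind.INSERTION_INFRAME):
        span = 1
        if variant.codon_start is not None and variant.codon_end is not None:
            span = variant.codon_end - variant.codon_start + 1
        delta = -span if k is VariantKind.DELETION_INFRAME else span
        return ProteinProduct(
            expressed=True,
            predicted_length_aa=domains.protein_length_aa + delta,
            nmd_predicted=False, retains_epitope=True, retains_nls=True,
            confidence="high",
        )
    # substitution / synonymous / none: full-length protein
    return ProteinProduct(
        expressed=True, predicted_length_aa=FULL_LENGTH, nmd_predicted=False,
        retains_epitope=True, retains_nls=True, confidence="high",
    )


def predict_ihc_pattern(
    variant: ProteinVariant, domains: Optional[DomainMap] = None
) -> PredictedPattern:
    """Predict the expected staining pattern (OE/CA/WT/CY) for a variant."""
    domains = domains or default_domain_map()
    k = variant.kind

    if k is VariantKind.SUBSTITUTION and variant.alt_aa != "*":
        return PredictedPattern("OE", "high", "nonsynonymous:stabilised-mutant-p53->OE")
    if k in (VariantKind.NONE, VariantKind.SYNONYMOUS):
        return PredictedPattern("WT", "high", "no-deleterious-mutation->WT")
    if k in (VariantKind.DELETION_INFRAME, VariantKind.INSERTION_INFRAME):
        return PredictedPattern(
            "OE", "low", "inframe-indel:conformational-missense-like->OE"
        )
    if k is VariantKind.SPLICING:
        return PredictedPattern("CA", "low", "splicing:aberrant-transcript->CA")

    product = predict_protein_product(variant, domains)
    if not product.expressed:
        if product.nmd_predicted:
            trace = f"ptc<{domains.nmd_ca_max_codon}:NMD->CA"
            return PredictedPattern("CA", "high", trace)
        if product.confidence == "ambiguous":
            trace = (
                f"ptc-in[{domains.nmd_ca_max_codon},{domains.expressed_min_codon - 1}]:"
                "unruled-window->CA"
            )
            return PredictedPattern("CA", "ambiguous", trace)
        return PredictedPattern("CA", "low", "non-expressed-product->CA")
    lo, hi = domains.cy_length_range
    length = product.predicted_length_aa
    if (
        isinstance(length, int)
        and not product.retains_nls
        and lo <= length <= hi
    ):
        trace = f"expressed-truncation;no-NLS;length-in[{lo},{hi}]->CY"
        return PredictedPattern("CY", "low", trace)
    return PredictedPattern("WT", "low", "expressed-truncation:detectable-protein->WT")


def pattern_concordant(predicted: PredictedPattern, observed: str) -> bool:
    """Is an observed scored pattern concordant with the prediction?

    Ambiguous-confidence predictions never register as discordance of record.
    An unscored observation is not assessable and raises.
    """
    if observed == UNSCORED or observed is None or (isinstance(observed, float)):
        raise NotAssessableError("observation is unscored; excluded from comparison")
    if observed not in PATTERNS:
        raise ValueError(f"unknown staining pattern {observed!r}")
    if predicted.confidence == "ambiguous":
        return True
    return predicted.pattern == observed


def predict_cohort(cohort: pd.DataFrame, variant_col: str = "variant") -> pd.DataFrame:
    """Batch mode: append predicted_pattern / prediction_confidence / rationale columns."""
    out = cohort.copy()
    preds = [predict_ihc_pattern(parse_variant_field(v)) for v in out[variant_col]]
    out["predicted_pattern"] = [p.pattern for p in preds]
    out["prediction_confidence"] = [p.confidence for p in preds]
    out["prediction_rationale"] = [p.rationale for p in preds]
    return out
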