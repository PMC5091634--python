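"""Synthetic ovarian-carcinoma cohorts with the statistical structure of the study.

The generator draws, per case: histotype (171 HGSOC + 80 EC by default),
presence of a deleterious TP53 mutation (prevalence 169/171 in HGSOC, 7/80 in
EC), the functional class given mutation (HGSOC 112 GOF : 57 LOF; EC 5 : 2),
the mutation type given class, a syntactically valid HGVS notation consistent
with the type (published hotspots p.R175H/p.Y220C/p.R273H among substitutions
and p.R196X among stopgains at their observed relative frequencies, the rest
uniform over the DNA-binding domain), and finally the observed staining
pattern per assay method from a conditional table P(pattern | mutation type).

Method 1's conditional is anchored on the published post-revision contingency
table; methods 2-4 default to perturbed copies with inflated WT->CA and
OE->WT confusion, emulating the weaker-staining assays.  All randomness flows
from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import STUDY_DESIGN, TABLE4_CELLS
from .predict import PATTERNS, UNSCORED
from .reference import default_domain_map

__all__ = [
    "GeneratorParams",
    "default_params",
    "generate_cohort",
    "generate_rater_pair",
    "method1_conditional",
    "perturb_conditional",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_PROB_TOL = 1e-9

Conditional = Dict[str, Dict[str, float]]


def method1_conditional() -> Conditional:
    """P(observed pattern | mutation type) for the anchor assay, from the
    published contingency counts (column-normalised)."""
    cond: Conditional = {}
    for mtype in ("nonsynonymous", "indel", "stopgain", "splicing", "NDM"):
        total = sum(TABLE4_CELLS[p][mtype] for p in TABLE4_CELLS)
        cond_key = "none" if mtype == "NDM" else mtype
        cond[cond_key] = {
            p: TABLE4_CELLS[p][mtype] / total for p in ("OE", "CA", "WT", "CY")
        }
    return cond


def perturb_conditional(
    base: Conditional, wt_to_ca: float, oe_to_wt: float
) -> Conditional:
    """Emulate a weaker-staining assay: move WT mass to CA and OE mass to WT."""
    out: Conditional = {}
    for mtype, row in base.items():
        new = dict(row)
        shift_wt = new["WT"] * wt_to_ca
        shift_oe = new["OE"] * oe_to_wt
        new["WT"] = new["WT"] - shift_wt + shift_oe
        new["CA"] += shift_wt
        new["OE"] -= shift_oe
        out[mtype] = new
    return out


@dataclass(frozen=True)
class GeneratorParams:
    """All dials of the synthetic cohort; defaults are the study conditions."""

    n_hgsoc: int = STUDY_DESIGN["n_hgsoc"]
    n_ec: int = STUDY_DESIGN["n_ec"]
    mutation_prevalence: Dict[str, float] = field(
        default_factory=lambda: {
            "HGSOC": STUDY_DESIGN["hgsoc_deleterious"] / STUDY_DESIGN["n_hgsoc"],
            "EC": STUDY_DESIGN["ec_deleterious"] / STUDY_DESIGN["n_ec"],
        }
    )
    #: per-histotype (GOF, LOF) split given a deleterious mutation
    class_mix: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"HGSOC": (112 / 169, 57 / 169), "EC": (5 / 7, 2 / 7)}
    )
    #: (indel, stopgain, splicing) split given LOF, from the published type totals
    lof_type_mix: Tuple[float, float, float] = (24 / 58, 17 / 58, 17 / 58)
    #: probability that an indel is in-frame (2 of 24 published indels)
    indel_inframe_prob: float = 2 / 24
    #: named substitution hotspots, weights = observed counts among 115 substitutions
    hotspot_weights: Dict[str, float] = field(
        default_factory=lambda: {"p.R175H": 9.0, "p.Y220C": 6.0, "p.R273H": 5.0}
    )
    stopgain_hotspot_weights: Dict[str, float] = field(
        default_factory=lambda: {"p.R196X": 4.0}
    )
    n_substitutions_observed: float = 115.0
    n_stopgains_observed: float = 17.0
    #: per assay method: P(observed pattern | mutation type)
    staining_conditional: Dict[int, Conditional] = field(
        default_factory=lambda: {
            1: method1_conditional(),
            2: perturb_conditional(method1_conditional(), 0.05, 0.05),
            3: perturb_conditional(method1_conditional(), 0.10, 0.08),
            4: perturb_conditional(method1_conditional(), 0.15, 0.12),
        }
    )
    unscored_rate: float = 0.02
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_hgsoc <= 0 or self.n_ec <= 0:
            raise ValueError("cohort counts must be positive")
        for hist, p in self.mutation_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {hist} outside [0, 1]")
        for hist, (gof, lof) in self.class_mix.items():
            if abs(gof + lof - 1.0) > _PROB_TOL:
                raise ValueError(f"class mix for {hist} does not sum to 1")
        if abs(sum(self.lof_type_mix) - 1.0) > _PROB_TOL:
            raise ValueError("LOF type mix does not sum to 1")
        if not 0.0 <= self.unscored_rate <= 1.0:
            raise ValueError("unscored_rate outside [0, 1]")
        for method, cond in self.staining_conditional.items():
            for mtype, row in cond.items():
                s = sum(row.values())
                if abs(s - 1.0) > _PROB_TOL:
                    raise ValueError(
                        f"staining conditional method {method} / {mtype} sums to {s}"
                    )
                if any(p < 0 for p in row.values()):
                    raise ValueError("staining probabilities must be non-negative")


def default_params(seed: Optional[int] = None) -> GeneratorParams:
    """The study conditions; pass a seed for reproducible generation."""
    return GeneratorParams(seed=seed)


def _weighted_named(
    rng: np.random.Generator,
    named: Dict[str, float],
    total_observed: float,
) -> Optional[str]:
    """Pick a named hotspot with probability weight/total, else defer to uniform."""
    if not named:
        return None
    names = list(named)
    weights = np.array([named[n] for n in names]) / total_observed
    u = rng.random()
    acc = 0.0
    for name, w in zip(names, weights):
        acc += w
        if u < acc:
            return name
    return None


def _random_missense(rng: np.random.Generator, params: GeneratorParams) -> str:
    hotspot = _weighted_named(rng, params.hotspot_weights, params.n_substitutions_observed)
    if hotspot:
        return hotspot
    lo, hi = default_domain_map().dbd
    codon = int(rng.integers(lo, hi + 1))
    ref, alt = rng.choice(list(_AA), size=2, replace=False)
    return f"p.{ref}{codon}{alt}"


def _random_stopgain(rng: np.random.Generator, params: GeneratorParams) -> str:
    hotspot = _weighted_named(
        rng, params.stopgain_hotspot_weights, params.n_stopgains_observed
    )
    if hotspot:
        return hotspot
    lo, hi = default_domain_map().dbd
    codon = int(rng.integers(lo, hi + 1))
    ref = rng.choice(list(_AA))
    return f"p.{ref}{codon}X"


def _random_indel(rng: np.random.Generator, params: GeneratorParams) -> str:
    codon = int(rng.integers(2, default_domain_map().protein_length_aa))
    ref = rng.choice(list(_AA))
    if rng.random() < params.indel_inframe_prob:
        return f"p.{ref}{codon}del"
    return f"p.{ref}{codon}fs"


def _random_splice(rng: np.random.Generator) -> str:
    exons = default_domain_map().cds_exons
    off = int(rng.integers(1, 3))
    if rng.random() < 0.5:  # acceptor side of an internal exon start
        k = int(rng.integers(1, len(exons)))
        return f"c.{exons[k][0]}-{off}G>A"
    k = int(rng.integers(0, len(exons) - 1))  # donor side of an internal exon end
    return f"c.{exons[k][1]}+{off}G>A"


def _draw_variant(rng: np.random.Generator, params: GeneratorParams, histotype: str):
    """Returns (variant notation, mutation type token)."""
    if rng.random() >= params.mutation_prevalence[histotype]:
        return "NDM", "none"
    gof_p, _ = params.class_mix[histotype]
    if rng.random() < gof_p:
        return _random_missense(rng, params), "nonsynonymous"
    r = rng.random()
    p_indel, p_stop, _ = params.lof_type_mix
    if r < p_indel:
        return _random_indel(rng, params), "indel"
    if r < p_indel + p_stop:
        return _random_stopgain(rng, params), "stopgain"
    return _random_splice(rng), "splicing"


def _draw_pattern(
    rng: np.random.Generator, cond: Conditional, mtype: str, unscored_rate: float
) -> str:
    if rng.random() < unscored_rate:
        return UNSCORED
    row = cond[mtype if mtype in cond else "none"]
    labels = list(row)
    probs = np.array([row[p] for p in labels])
    return str(rng.choice(labels, p=probs / probs.sum()))


def generate_cohort(
    params: Optional[GeneratorParams] = None, seed: Optional[int] = None
) -> pd.DataFrame:
    """Generate a synthetic cohort table (deterministic given the seed).

    Columns match the real-input schema: ``case_id``, ``histotype``,
    ``variant`` (HGVS or ``NDM``) and ``pattern_m1``..``pattern_m4``.
    """
    params = params or default_params()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    rows = []
    histotypes = ["HGSOC"] * params.n_hgsoc + ["EC"] * params.n_ec
    methods = sorted(params.staining_conditional)
    for i, histotype in enumerate(histotypes):
        variant, mtype = _draw_variant(rng, params, histotype)
        patterns = {
            f"pattern_m{m}": _draw_pattern(
                rng, params.staining_conditional[m], mtype, params.unscored_rate
            )
            for m in methods
        }
        rows.append({
            "case_id": f"S{i + 1:04d}",
            "histotype": histotype,
            "variant": variant,
            **patterns,
        })
    return pd.DataFrame(rows)


def generate_rater_pair(
    cohort: pd.DataFrame,
    disagreement_rate: float,
    seed: Optional[int] = None,
    method_id: int = 1,
) -> Tuple[List[str], List[str]]:
    """Two parallel pattern lists emulating independent observers.

    The second rater copies the first, then independently perturbs each label
    with the given probability; confusions concentrate between CA and WT (the
    patterns observers actually disagree about), with OE and CY drifting to WT.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    col = f"pattern_m{method_id}"
    rater_a = [p for p in cohort[col] if p in PATTERNS]
    rater_b = []
    flip = {"CA": "WT", "WT": "CA", "OE": "WT", "CY": "WT"}
    for label in rater_a:
        if rng.random() < disagreement_rate:
            rater_b.append(flip[label])
        else:
            rater_b.append(label)
    return rater_a, rater_b
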