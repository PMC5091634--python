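"""Canonical TP53 reference data and HGVS variant-notation parsing.

Everything downstream works on codon coordinates of the canonical 393-amino-acid
p53 protein (the major TP53 transcript, coding exons 2-11, 1182-nt CDS).  Domain
intervals and exon boundaries ship as a packaged JSON fixture so the pipeline is
fully self-contained: no network lookups, no transcript databases.

Coordinates are 1-based and intervals are closed throughout, following HGVS
convention.  The protein-level parser accepts the mixed dialects that appear in
clinical reports: one- and three-letter amino-acid codes, ``X``/``*``/``Ter``
for a stop, an optional trailing digit on deletions (``p.I255del1``), and an
optional ``p.`` prefix.  Parsed variants normalise to one-letter codes with
``*`` for stop.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from enum import Enum
from functools import lru_cache
from importlib import resources
from math import ceil
from typing import Optional, Tuple

__all__ = [
    "DomainMap",
    "ProteinVariant",
    "VariantKind",
    "HgvsParseError",
    "CodonRangeError",
    "UnsupportedNotationError",
    "default_domain_map",
    "parse_protein_hgvs",
    "parse_coding_hgvs",
    "parse_variant_field",
    "format_protein_hgvs",
    "STOP",
    "NDM_TOKEN",
]

STOP = "*"
#: Cohort-table token meaning "no detectable mutation".
NDM_TOKEN = "NDM"


class HgvsParseError(ValueError):
    """Raised when a variant notation cannot be parsed; names the offending token."""


class CodonRangeError(ValueError):
    """Raised when a parsed codon or CDS position falls outside the canonical protein."""


class UnsupportedNotationError(ValueError):
    """Raised for syntactically valid notation outside the documented dialect."""


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    STOPGAIN = "stopgain"
    DELETION_INFRAME = "deletion_inframe"
    INSERTION_INFRAME = "insertion_inframe"
    FRAMESHIFT = "frameshift"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    NONE = "none"


Interval = Tuple[int, int]


@dataclass(frozen=True)
class DomainMap:
    """Codon intervals and position thresholds of canonical p53.

    The thresholds encode the mechanistic staining rules: premature termination
    codons before ``nmd_ca_max_codon`` trigger nonsense-mediated decay (no
    protein, complete-absence staining); terminations at or after
    ``expressed_min_codon`` leave a detectable truncated protein.  Truncations
    whose product length falls inside ``cy_length_range`` lose the nuclear
    localization signal (``nls``) and stain cytoplasmic.
    """

    protein_length_aa: int
    cds_length_nt: int
    tad: Interval
    dbd: Interval
    tmd: Interval
    nls: Interval
    do7_epitope: Interval
    nmd_ca_max_codon: int
    expressed_min_codon: int
    cy_length_range: Interval
    splice_window_nt: int
    cds_exons: Tuple[Interval, ...]

    def __post_init__(self) -> None:
        for name in ("tad", "dbd", "tmd", "nls", "do7_epitope", "cy_length_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= self.protein_length_aa):
                raise ValueError(f"interval {name}=({lo}, {hi}) outside [1, {self.protein_length_aa}]")
        if not self.nmd_ca_max_codon < self.expressed_min_codon:
            raise ValueError("NMD cutoff must precede the expressed-truncation cutoff")
        if not self.cy_length_range[1] < self.nls[0]:
            raise ValueError("cytoplasmic length range must lie strictly below the NLS start")


@lru_cache(maxsize=1)
def default_domain_map() -> DomainMap:
    """Load the packaged canonical p53 domain map (immutable singleton)."""
    raw = json.loads(
        resources.files("tp53ihc").joinpath("data/tp53_reference.json").read_text()
    )
    dom = raw["domains"]
    return DomainMap(
        protein_length_aa=raw["protein_length_aa"],
        cds_length_nt=raw["cds_length_nt"],
        tad=tuple(dom["tad"]),
        dbd=tuple(dom["dbd"]),
        tmd=tuple(dom["tmd"]),
        nls=tuple(dom["nls"]),
        do7_epitope=tuple(dom["do7_epitope"]),
        nmd_ca_max_codon=raw["nmd_ca_max_codon"],
        expressed_min_codon=raw["expressed_min_codon"],
        cy_length_range=tuple(raw["cy_length_range"]),
        splice_window_nt=raw["splice_window_nt"],
        cds_exons=tuple(tuple(e) for e in raw["cds_exon_boundaries"]["exons"]),
    )


@dataclass(frozen=True)
class ProteinVariant:
    """A TP53 variant resolved to protein level.

    ``codon_start``/``codon_end`` are absent (``None``) for splicing variants
    and for the no-mutation sentinel.  ``alt_aa`` is ``"*"`` for stopgains.
    """

    raw: str
    kind: VariantKind
    codon_start: Optional[int] = None
    codon_end: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if self.codon_start is not None and self.codon_end is not None:
            if self.codon_start > self.codon_end:
                raise ValueError("codon_start must not exceed codon_end")
        if self.kind is VariantKind.STOPGAIN and self.alt_aa != STOP:
            raise ValueError("stopgain variants must carry the stop symbol as alt")
        if self.kind is VariantKind.NONE and (
            self.codon_start is not None or self.codon_end is not None
        ):
            raise ValueError("no-mutation variants carry no positional fields")

    def same_structure(self, other: "ProteinVariant") -> bool:
        """Structural equality ignoring the raw notation string."""
        return replace(self, raw="") == replace(other, raw="")


_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": STOP,
}
_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

_AA_TOKEN = r"(?:[A-Z][a-z]{2}|[A-Z])"
_RES = rf"(?P<ref>{_AA_TOKEN})(?P<pos>\d+)"
_RES2 = rf"(?P<ref2>{_AA_TOKEN})(?P<pos2>\d+)"

_SUB_RE = re.compile(rf"^{_RES}(?P<alt>{_AA_TOKEN}|\*|=)$")
_FS_RE = re.compile(rf"^{_RES}(?P<altfs>{_AA_TOKEN})?fs(?:\*?\d*|Ter\d*)?$", re.IGNORECASE)
_DEL_RE = re.compile(rf"^{_RES}(?:_{_RES2})?del(?:\d+|{_AA_TOKEN}*)?$")
_DUP_RE = re.compile(rf"^{_RES}(?:_{_RES2})?dup$")
_INS_RE = re.compile(rf"^{_RES}_{_RES2}ins(?P<insseq>{_AA_TOKEN}+|\d+)$")
_DELINS_RE = re.compile(rf"^{_RES}(?:_{_RES2})?delins(?P<insseq>{_AA_TOKEN}+)$")


def _one_letter(token: str, notation: str) -> str:
    if token in ("*", "X", "x"):
        return STOP
    if len(token) == 1:
        if token not in _AA1:
            raise HgvsParseError(f"unknown amino-acid code {token!r} in {notation!r}")
        return token
    try:
        return _AA3_TO_1[token.capitalize()]
    except KeyError:
        raise HgvsParseError(f"unknown amino-acid code {token!r} in {notation!r}") from None


def _check_codon(codon: int, notation: str, length: int) -> int:
    if not (1 <= codon <= length):
        raise CodonRangeError(
            f"codon {codon} in {notation!r} outside canonical p53 [1, {length}]"
        )
    return codon


def parse_protein_hgvs(notation: str) -> ProteinVariant:
    """Parse protein-level HGVS (``p.R175H``, ``p.Arg196Ter``, ``p.I255del1``, ``p.K382fs``).

    Total over the documented dialect; unparseable input raises
    :class:`HgvsParseError` naming the offending token, and codons outside the
    393-aa protein raise :class:`CodonRangeError`.
    """
    if not notation or not notation.strip():
        raise HgvsParseError("empty variant notation")
    length = default_domain_map().protein_length_aa
    body = notation.strip()
    if body[:2].lower() == "p.":
        body = body[2:]
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    if not body:
        raise HgvsParseError(f"no variant body in {notation!r}")

    m = _FS_RE.match(body)
    if m:
        codon = _check_codon(int(m.group("pos")), notation, length)
        return ProteinVariant(
            raw=notation, kind=VariantKind.FRAMESHIFT,
            codon_start=codon, codon_end=codon,
            ref_aa=_one_letter(m.group("ref"), notation),
        )

    m = _SUB_RE.match(body)
    if m:
        codon = _check_codon(int(m.group("pos")), notation, length)
        ref = _one_letter(m.group("ref"), notation)
        alt_tok = m.group("alt")
        alt = ref if alt_tok == "=" else _one_letter(alt_tok, notation)
        if alt == STOP:
            kind = VariantKind.STOPGAIN
        elif alt == ref:
            kind = VariantKind.SYNONYMOUS
        else:
            kind = VariantKind.SUBSTITUTION
        return ProteinVariant(
            raw=notation, kind=kind,
            codon_start=codon, codon_end=codon, ref_aa=ref, alt_aa=alt,
        )

    for regex, kind in (
        (_DEL_RE, VariantKind.DELETION_INFRAME),
        (_DELINS_RE, VariantKind.DELETION_INFRAME),
        (_DUP_RE, VariantKind.INSERTION_INFRAME),
        (_INS_RE, VariantKind.INSERTION_INFRAME),
    ):
        m = regex.match(body)
        if m:
            start = _check_codon(int(m.group("pos")), notation, length)
            end = start
            if m.groupdict().get("pos2"):
                end = _check_codon(int(m.group("pos2")), notation, length)
            alt = None
            insseq = m.groupdict().get("insseq")
            if insseq and not insseq.isdigit():
                alt = "".join(
                    _one_letter(t, notation)
                    for t in re.findall(_AA_TOKEN, insseq)
                )
            return ProteinVariant(
                raw=notation, kind=kind,
                codon_start=start, codon_end=end,
                ref_aa=_one_letter(m.group("ref"), notation), alt_aa=alt,
            )

    raise HgvsParseError(f"unparseable protein variant notation {notation!r}")


_CODING_RE = re.compile(
    r"^c\.(?P<pos>\d+)(?P<off>[+-]\d+)?(?:_(?P<pos2>\d+)(?P<off2>[+-]\d+)?)?(?P<rest>.*)$"
)
_CODING_SUB_RE = re.compile(r"^(?P<ref>[ACGT])>(?P<alt>[ACGT])$")


def parse_coding_hgvs(notation: str) -> ProteinVariant:
    """Parse coding-level HGVS against the packaged canonical TP53 CDS.

    Intronic-offset positions within the documented splice window (+/-2 nt of
    an exon boundary, the dialect used for splice-site variants such as
    ``c.356-2delA``) map to ``kind=splicing``; larger offsets raise
    :class:`UnsupportedNotationError`.  Exonic positions translate to codons as
    ``ceil(cds_pos / 3)``.
    """
    if not notation or not notation.strip():
        raise HgvsParseError("empty variant notation")
    dom = default_domain_map()
    body = notation.strip()
    m = _CODING_RE.match(body)
    if not m:
        raise HgvsParseError(f"unparseable coding variant notation {notation!r}")
    pos = int(m.group("pos"))
    if not (1 <= pos <= dom.cds_length_nt):
        raise CodonRangeError(
            f"CDS position {pos} in {notation!r} outside [1, {dom.cds_length_nt}]"
        )
    offsets = [m.group("off"), m.group("off2")]
    offsets = [int(o) for o in offsets if o]
    if offsets:
        if all(abs(o) <= dom.splice_window_nt for o in offsets):
            return ProteinVariant(raw=notation, kind=VariantKind.SPLICING)
        raise UnsupportedNotationError(
            f"intronic offset beyond the +/-{dom.splice_window_nt} splice window "
            f"in {notation!r}"
        )

    rest = m.group("rest")
    codon = _check_codon(ceil(pos / 3), notation, dom.protein_length_aa)
    end_codon = codon
    span = 1
    if m.group("pos2"):
        pos2 = int(m.group("pos2"))
        if not (pos <= pos2 <= dom.cds_length_nt):
            raise CodonRangeError(f"CDS range in {notation!r} outside the CDS")
        end_codon = ceil(pos2 / 3)
        span = pos2 - pos + 1

    sub = _CODING_SUB_RE.match(rest)
    if sub:
        # nucleotide-level ref/alt cannot be translated without the base sequence;
        # downstream classification only needs kind + codon
        return ProteinVariant(
            raw=notation, kind=VariantKind.SUBSTITUTION,
            codon_start=codon, codon_end=codon,
        )
    low = rest.lower()
    if low.startswith("del") or low.startswith("dup") or low.startswith("ins"):
        seq = rest[3:]
        if seq.isdigit():
            span = int(seq)
        elif seq:
            span = len(seq)
        inframe = span % 3 == 0
        if low.startswith("del"):
            kind = VariantKind.DELETION_INFRAME if inframe else VariantKind.FRAMESHIFT
        else:
            kind = VariantKind.INSERTION_INFRAME if inframe else VariantKind.FRAMESHIFT
        return ProteinVariant(
            raw=notation, kind=kind, codon_start=codon, codon_end=end_codon,
        )
    raise HgvsParseError(f"unparseable coding variant tail {rest!r} in {notation!r}")


def parse_variant_field(value: object) -> ProteinVariant:
    """Parse a cohort-table variant field: HGVS (p. or c.) or the NDM sentinel."""
    if value is None:
        return ProteinVariant(raw=NDM_TOKEN, kind=VariantKind.NONE)
    text = str(value).strip()
    if not text or text.upper() == NDM_TOKEN or text.lower() in ("nan", "none"):
        return ProteinVariant(raw=NDM_TOKEN, kind=VariantKind.NONE)
    if text[:2].lower() == "c.":
        return parse_coding_hgvs(text)
    return parse_protein_hgvs(text)


def format_protein_hgvs(variant: ProteinVariant) -> str:
    """Render a protein-level variant in the normalised dialect (round-trips)."""
    k = variant.kind
    if k is VariantKind.NONE:
        return NDM_TOKEN
    if k is VariantKind.SPLICING:
        return variant.raw  # splice variants keep their coding notation
    if k in (VariantKind.SUBSTITUTION, VariantKind.STOPGAIN, VariantKind.SYNONYMOUS):
        alt = variant.alt_aa if variant.alt_aa is not None else "?"
        return f"p.{variant.ref_aa}{variant.codon_start}{alt}"
    if k is VariantKind.FRAMESHIFT:
        return f"p.{variant.ref_aa}{variant.codon_start}fs"
    if k is VariantKind.DELETION_INFRAME:
        if variant.codon_end != variant.codon_start:
            return f"p.{variant.ref_aa}{variant.codon_start}_{variant.ref_aa}{variant.codon_end}del"
        return f"p.{variant.ref_aa}{variant.codon_start}del"
    if k is VariantKind.INSERTION_INFRAME:
        ins = variant.alt_aa or "A"
        if variant.codon_end != variant.codon_start:
            return (
                f"p.{variant.ref_aa}{variant.codon_start}_"
                f"{variant.ref_aa}{variant.codon_end}ins{ins}"
            )
        return f"p.{variant.ref_aa}{variant.codon_start}dup"
    raise ValueError(f"cannot format variant kind {k}")
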