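"""HGVS parsing against the canonical 393-aa p53 reference."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tp53ihc.reference import (
    NDM_TOKEN,
    STOP,
    CodonRangeError,
    HgvsParseError,
    ProteinVariant,
    UnsupportedNotationError,
    VariantKind,
    default_domain_map,
    format_protein_hgvs,
    parse_coding_hgvs,
    parse_protein_hgvs,
    parse_variant_field,
)


class TestDomainMap:
    def test_packaged_constants(self):
        dom = default_domain_map()
        assert dom.protein_length_aa == 393
        assert dom.nls == (316, 325)
        assert dom.do7_epitope == (19, 26)
        assert dom.cy_length_range == (292, 306)
        assert dom.nmd_ca_max_codon == 213
        assert dom.expressed_min_codon == 245

    def test_structural_invariants(self):
        dom = default_domain_map()
        assert dom.nmd_ca_max_codon < dom.expressed_min_codon
        assert dom.cy_length_range[1] < dom.nls[0]
        for iv in (dom.tad, dom.dbd, dom.tmd, dom.nls, dom.do7_epitope):
            assert 1 <= iv[0] <= iv[1] <= dom.protein_length_aa
        # coding exons tile the CDS contiguously
        assert dom.cds_exons[0][0] == 1
        assert dom.cds_exons[-1][1] == dom.cds_length_nt
        for (_, e), (s, _) in zip(dom.cds_exons, dom.cds_exons[1:]):
            assert s == e + 1

    def test_singleton(self):
        assert default_domain_map() is default_domain_map()


class TestProteinParser:
    @pytest.mark.parametrize(
        "notation, kind, codon, ref, alt",
        [
            ("p.R175H", VariantKind.SUBSTITUTION, 175, "R", "H"),
            ("p.Arg175His", VariantKind.SUBSTITUTION, 175, "R", "H"),
            ("P.r175h", None, None, None, None),  # prefix case-insensitivity only
            ("p.R196X", VariantKind.STOPGAIN, 196, "R", STOP),
            ("p.R196*", VariantKind.STOPGAIN, 196, "R", STOP),
            ("p.Arg196Ter", VariantKind.STOPGAIN, 196, "R", STOP),
            ("p.I255del", VariantKind.DELETION_INFRAME, 255, "I", None),
            ("p.I255del1", VariantKind.DELETION_INFRAME, 255, "I", None),
            ("p.K382fs", VariantKind.FRAMESHIFT, 382, "K", None),
            ("p.K382Nfs*40", VariantKind.FRAMESHIFT, 382, "K", None),
            ("p.R175R", VariantKind.SYNONYMOUS, 175, "R", "R"),
            ("p.R175=", VariantKind.SYNONYMOUS, 175, "R", "R"),
            ("p.T253dup", VariantKind.INSERTION_INFRAME, 253, "T", None),
        ],
    )
    def test_dialects(self, notation, kind, codon, ref, alt):
        if kind is None:
            with pytest.raises(HgvsParseError):
                parse_protein_hgvs(notation)
            return
        v = parse_protein_hgvs(notation)
        assert v.kind is kind
        assert v.codon_start == codon
        assert v.ref_aa == ref
        assert v.alt_aa == alt

    def test_range_error_beyond_protein(self):
        with pytest.raises(CodonRangeError):
            parse_protein_hgvs("p.Q999X")

    @pytest.mark.parametrize("bad", ["", "p.", "p.175H", "p.R175", "gibberish", "p.B175H"])
    def test_parse_errors_name_token(self, bad):
        with pytest.raises(HgvsParseError):
            parse_protein_hgvs(bad)

    def test_multi_codon_deletion(self):
        v = parse_protein_hgvs("p.R175_H179del")
        assert v.kind is VariantKind.DELETION_INFRAME
        assert (v.codon_start, v.codon_end) == (175, 179)


class TestCodingParser:
    def test_splice_acceptor(self):
        v = parse_coding_hgvs("c.356-2delA")
        assert v.kind is VariantKind.SPLICING
        assert v.codon_start is None  # splicing carries no codon

    def test_exonic_substitution_codon_arithmetic(self):
        assert parse_coding_hgvs("c.524G>A").codon_start == 175

    def test_positions_are_one_based(self):
        with pytest.raises((HgvsParseError, CodonRangeError)):
            parse_coding_hgvs("c.0A>T")

    def test_offset_beyond_splice_window(self):
        with pytest.raises(UnsupportedNotationError):
            parse_coding_hgvs("c.356-15delA")

    def test_frame_of_coding_indels(self):
        assert parse_coding_hgvs("c.100delA").kind is VariantKind.FRAMESHIFT
        assert parse_coding_hgvs("c.100_102del").kind is VariantKind.DELETION_INFRAME

    def test_cds_range_error(self):
        with pytest.raises(CodonRangeError):
            parse_coding_hgvs("c.2000G>A")


class TestVariantField:
    @pytest.mark.parametrize("token", [NDM_TOKEN, "ndm", "", None, float("nan")])
    def test_ndm_sentinels(self, token):
        v = parse_variant_field(token)
        assert v.kind is VariantKind.NONE
        assert v.codon_start is None

    def test_dispatch_by_prefix(self):
        assert parse_variant_field("c.356-2delA").kind is VariantKind.SPLICING
        assert parse_variant_field("p.R175H").kind is VariantKind.SUBSTITUTION


_aa = st.sampled_from(list("ACDEFGHIKLMNPQRSTVWY"))
_codon = st.integers(min_value=1, max_value=393)


@st.composite
def protein_variants(draw):
    kind = draw(st.sampled_from([
        VariantKind.SUBSTITUTION, VariantKind.STOPGAIN, VariantKind.SYNONYMOUS,
        VariantKind.DELETION_INFRAME, VariantKind.FRAMESHIFT,
    ]))
    codon = draw(_codon)
    ref = draw(_aa)
    if kind is VariantKind.SUBSTITUTION:
        alt = draw(_aa.filter(lambda a: a != ref))
        return ProteinVariant("", kind, codon, codon, ref, alt)
    if kind is VariantKind.STOPGAIN:
        return ProteinVariant("", kind, codon, codon, ref, STOP)
    if kind is VariantKind.SYNONYMOUS:
        return ProteinVariant("", kind, codon, codon, ref, ref)
    if kind is VariantKind.DELETION_INFRAME:
        end = draw(st.integers(min_value=codon, max_value=min(codon + 5, 393)))
        return ProteinVariant("", kind, codon, end, ref, None)
    return ProteinVariant("", kind, codon, codon, ref, None)


@given(protein_variants())
@settings(derandomize=True, max_examples=200)
def test_format_parse_round_trip(variant):
    """Formatting then re-parsing preserves the variant structure."""
    reparsed = parse_protein_hgvs(format_protein_hgvs(variant))
    assert reparsed.same_structure(variant)
    assert 1 <= reparsed.codon_start <= 393


@given(protein_variants())
@settings(derandomize=True, max_examples=50)
def test_parse_is_deterministic(variant):
    notation = format_protein_hgvs(variant)
    assert parse_protein_hgvs(notation) == parse_protein_hgvs(notation)
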