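"""Confusion-matrix construction and diagnostic metrics, checked against an
independent per-case loop oracle and (for kappa) against scikit-learn."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from tp53ihc.concordance import (
    ABNORMAL_PATTERNS,
    PATTERN_TO_CLASS,
    binary_metrics,
    build_confusion,
    cohens_kappa,
    ternary_metrics,
)
from conftest import random_labelled_cohort


def loop_binary(cohort):
    """Naive per-case oracle for the binary classifier metrics."""
    tp = fp = fn = tn = 0
    for _, row in cohort.iterrows():
        pat = row["pattern_m1"]
        if pd.isna(pat) or pat == "unscored":
            continue
        abnormal = pat in ABNORMAL_PATTERNS
        deleterious = row["functional_class"] != "NDM"
        tp += abnormal and deleterious
        fp += abnormal and not deleterious
        fn += (not abnormal) and deleterious
        tn += (not abnormal) and not deleterious
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    n = tp + fp + fn + tn
    acc = (tp + tn) / n if n else None
    return sens, spec, acc, n


def loop_ternary(cohort):
    """Naive per-case oracle for the one-vs-rest ternary metrics."""
    rows = []
    for _, row in cohort.iterrows():
        pat = row["pattern_m1"]
        if pd.isna(pat) or pat in ("unscored", "CY"):
            continue
        rows.append((PATTERN_TO_CLASS[pat], row["functional_class"]))
    n = len(rows)
    acc = sum(p == t for p, t in rows) / n if n else None
    per_class = {}
    for klass in ("GOF", "LOF", "NDM"):
        tp = sum(1 for p, t in rows if p == klass and t == klass)
        fn = sum(1 for p, t in rows if p != klass and t == klass)
        fp = sum(1 for p, t in rows if p == klass and t != klass)
        tn = n - tp - fn - fp
        per_class[klass] = (
            tp / (tp + fn) if tp + fn else None,
            tn / (tn + fp) if tn + fp else None,
        )
    return per_class, acc, n


class TestTable4Tabulation:
    def test_binary_cells(self, table4):
        cm = build_confusion(table4, "binary")
        assert cm.cells.loc["abnormal", "deleterious"] == 166
        assert cm.cells.loc["abnormal", "NDM"] == 0
        assert cm.cells.loc["normal", "deleterious"] == 7
        assert cm.cells.loc["normal", "NDM"] == 76
        assert cm.included == 249
        assert cm.excluded == {"unscored": 0, "cytoplasmic": 0}

    def test_ternary_exclusion_of_cytoplasmic(self, table4):
        cm = build_confusion(table4, "ternary")
        assert cm.included == 245
        assert cm.excluded["cytoplasmic"] == 4
        assert cm.cells.loc["OE", "GOF"] == 115
        assert cm.cells.loc["CA", "LOF"] == 41
        assert cm.cells.loc["WT", "NDM"] == 76

    def test_marginal_conservation(self, table4):
        for mode in ("binary", "ternary"):
            cm = build_confusion(table4, mode)
            assert cm.included + sum(cm.excluded.values()) == len(table4)

    def test_empty_cohort_all_zero(self, table4):
        empty = table4.iloc[0:0]
        cm = build_confusion(empty, "binary")
        assert cm.included == 0
        assert (cm.cells.to_numpy() == 0).all()

    def test_unknown_pattern_token_names_case(self, table4):
        bad = table4.copy()
        bad.loc[bad.index[0], "pattern_m1"] = "OD"
        with pytest.raises(ValueError, match=str(bad.iloc[0]["case_id"])):
            build_confusion(bad, "binary")


class TestMetricDefinitions:
    def test_balanced_accuracy_identity(self, table4):
        m = binary_metrics(build_confusion(table4, "binary"))
        assert m.balanced_accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)
        t = ternary_metrics(build_confusion(table4, "ternary"))
        for vals in t.per_class.values():
            assert vals["balanced_accuracy"] == pytest.approx(
                (vals["sensitivity"] + vals["specificity"]) / 2
            )

    def test_exact_ci_brackets_accuracy(self, table4):
        m = binary_metrics(build_confusion(table4, "binary"))
        assert m.ci_low < m.overall_accuracy < m.ci_high
        assert 0 <= m.ci_low and m.ci_high <= 1

    def test_zero_denominator_undefined_not_zero(self, table4):
        no_ndm = table4[table4["functional_class"] != "NDM"]
        with pytest.warns(UserWarning, match="specificity undefined"):
            m = binary_metrics(build_confusion(no_ndm, "binary"))
        assert m.specificity is None
        assert m.balanced_accuracy is None
        assert m.sensitivity is not None

    def test_mode_mismatch_rejected(self, table4):
        with pytest.raises(ValueError):
            ternary_metrics(build_confusion(table4, "binary"))


class TestOracleEquivalence:
    """Tabulated metrics equal a naive per-case loop on random cohorts."""

    def test_binary_oracle(self, rng):
        for _ in range(50):
            cohort = random_labelled_cohort(rng, int(rng.integers(5, 120)))
            cm = build_confusion(cohort, "binary")
            m = binary_metrics(cm)
            sens, spec, acc, n = loop_binary(cohort)
            assert m.n_included == n
            for ours, theirs in ((m.sensitivity, sens), (m.specificity, spec),
                                 (m.overall_accuracy, acc)):
                if theirs is None:
                    assert ours is None
                else:
                    assert ours == pytest.approx(theirs)

    def test_ternary_oracle(self, rng):
        for _ in range(50):
            cohort = random_labelled_cohort(rng, int(rng.integers(5, 120)))
            cm = build_confusion(cohort, "ternary")
            m = ternary_metrics(cm)
            per_class, acc, n = loop_ternary(cohort)
            assert m.n_included == n
            if acc is None:
                assert m.overall_accuracy is None
            else:
                assert m.overall_accuracy == pytest.approx(acc)
            for klass, (sens, spec) in per_class.items():
                got = m.per_class[klass]
                if sens is None:
                    assert got["sensitivity"] is None
                else:
                    assert got["sensitivity"] == pytest.approx(sens)
                if spec is None:
                    assert got["specificity"] is None
                else:
                    assert got["specificity"] == pytest.approx(spec)


class TestKappa:
    def test_perfect_agreement(self):
        r = cohens_kappa(["OE", "CA", "WT"] * 10, ["OE", "CA", "WT"] * 10)
        assert r.kappa == pytest.approx(1.0)
        assert r.observed_agreement == 1.0

    def test_maximal_disagreement_closed_form(self):
        # two labels split 50/50 with total disagreement -> kappa = -1
        r = cohens_kappa(["CA", "WT"] * 20, ["WT", "CA"] * 20)
        assert r.kappa == pytest.approx(-1.0)

    def test_independent_raters_near_zero(self, rng):
        labels = ["OE", "CA", "WT", "CY"]
        a = rng.choice(labels, size=20000, p=[0.45, 0.2, 0.3, 0.05])
        b = rng.choice(labels, size=20000, p=[0.45, 0.2, 0.3, 0.05])
        assert abs(cohens_kappa(list(a), list(b)).kappa) < 0.03

    def test_matches_sklearn(self, rng):
        """Cross-check against the independent library implementation."""
        labels = ["OE", "CA", "WT", "CY"]
        for _ in range(20):
            n = int(rng.integers(10, 300))
            a = list(rng.choice(labels, size=n))
            b = list(rng.choice(labels, size=n))
            ours = cohens_kappa(a, b)
            assert ours.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)
            # identity kappa = (po - pe) / (1 - pe)
            assert ours.kappa == pytest.approx(
                (ours.observed_agreement - ours.expected_agreement)
                / (1 - ours.expected_agreement)
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa(["OE"], ["OE", "CA"])
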