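"""Classification groups, missense rule, hypomorphic registry, FMR1 bins."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecscreen.classify import (
    GROUP_NAMES,
    HypomorphicRegistry,
    MissenseScores,
    benchmark_missense_rule,
    classify_fmr1_repeat,
    classify_variant,
    classify_variants,
    conflicting_plp_qualifies,
    high_stringency_missense,
    mark_hypomorphic,
)

from conftest import make_annotation


@pytest.mark.parametrize(
    "plp, total, expected",
    [(17, 18, True), (3, 6, False), (3, 4, True), (2, 3, False)],
)
def test_conflicting_plp_entry_fraction(plp, total, expected):
    assert conflicting_plp_qualifies("conflicting", plp / total) is expected


def test_conflicting_requires_conflicting_class_and_entries():
    assert conflicting_plp_qualifies("VUS", 0.9) is False
    assert conflicting_plp_qualifies("conflicting", float("nan")) is False


@pytest.mark.parametrize(
    "vipur, cadd, n_del, n_avail, expected",
    [
        (0.90, 25.0, 7, 8, True),    # 0.875 >= 0.85
        (0.84, 30.0, 8, 8, False),   # VIPUR boundary fails
        (0.90, 19.9, 8, 8, False),   # CADD boundary fails
        (0.85, 20.0, 6, 7, True),    # 6/7 = 0.857, both scores at boundary
        (0.90, 25.0, 5, 6, False),   # 5/6 = 0.833 < 0.85
        (0.90, 25.0, 6, 6, True),    # vote fraction over available calls only
    ],
)
def test_high_stringency_missense_rule(vipur, cadd, n_del, n_avail, expected):
    calls = ["deleterious"] * n_del + ["tolerated"] * (n_avail - n_del)
    calls += ["missing"] * (8 - n_avail)
    assert high_stringency_missense(MissenseScores(vipur, cadd, calls)) is expected


def test_all_predictors_missing_fails_with_warning(caplog):
    scores = MissenseScores(0.99, 30.0, ["missing"] * 8)
    assert high_stringency_missense(scores) is False


class TestGroupTaxonomy:
    @pytest.mark.parametrize(
        "kwargs, expected_group",
        [
            (dict(in_clinvar=True, clinvar_class="P", clinvar_stars=2,
                  hgmd_class="DM"), 1),
            (dict(in_clinvar=True, clinvar_class="LP", clinvar_stars=1,
                  hgmd_class="non-DM"), 2),
            (dict(in_clinvar=True, clinvar_class="P/LP", clinvar_stars=3,
                  hgmd_class="none"), 3),
            (dict(in_clinvar=True, clinvar_class="conflicting",
                  plp_entry_fraction=0.94, hgmd_class="DM"), 4),
            (dict(in_clinvar=True, clinvar_class="conflicting",
                  plp_entry_fraction=0.75, hgmd_class="non-DM"), 5),
            (dict(in_clinvar=True, clinvar_class="conflicting",
                  plp_entry_fraction=0.8, hgmd_class="none"), 6),
            (dict(in_clinvar=True, clinvar_class="P", clinvar_stars=0,
                  hgmd_class="DM"), 7),
            (dict(in_clinvar=True, clinvar_class="LP", clinvar_stars=0,
                  hgmd_class="non-DM"), 8),
            (dict(in_clinvar=True, clinvar_class="P", clinvar_stars=0,
                  hgmd_class="none"), 9),
            (dict(hgmd_class="DM", functional_class="truncating"), 10),
            (dict(hgmd_class="DM", functional_class="missense",
                  high_stringency=True), 11),
            (dict(hgmd_class="DM", functional_class="protein_length_alteration"), 12),
            (dict(functional_class="truncating"), 13),
            (dict(functional_class="canonical_splice"), 13),  # counts as truncating
            (dict(functional_class="missense", high_stringency=True), 14),
            (dict(functional_class="non_canonical_splice"), 15),
            (dict(functional_class="protein_length_alteration"), 16),
            # no-group cases
            (dict(functional_class="missense", high_stringency=False), None),
            (dict(in_clinvar=True, clinvar_class="VUS", clinvar_stars=2), None),
            (dict(in_clinvar=True, clinvar_class="conflicting",
                  plp_entry_fraction=0.5), None),
            (dict(hgmd_class="non-DM", functional_class="truncating"), None),
        ],
    )
    def test_scalar_assignment(self, kwargs, expected_group):
        defaults = dict(in_clinvar=False, clinvar_class="none", clinvar_stars=0,
                        plp_entry_fraction=float("nan"), hgmd_class="none",
                        functional_class="truncating", high_stringency=False)
        defaults.update(kwargs)
        assert classify_variant(**defaults) == expected_group

    def test_inconsistent_annotation_is_hard_error(self):
        with pytest.raises(ValueError, match="inconsistent"):
            classify_variant(False, "P", 2, float("nan"), "DM", "truncating")

    def test_vectorized_agrees_with_scalar_on_full_grid(self):
        rows = []
        for in_cv, cls, stars, plp, hgmd, fc, hs in itertools.product(
            [True, False],
            ["P", "conflicting", "VUS", "none"],
            [0, 2],
            [0.9, 0.5],
            ["DM", "non-DM", "none"],
            ["truncating", "missense", "non_canonical_splice",
             "protein_length_alteration", "canonical_splice"],
            [True, False],
        ):
            if in_cv == (cls == "none"):
                continue  # inconsistent combinations raise; tested separately
            rows.append(dict(in_clinvar=in_cv, clinvar_class=cls if in_cv else "none",
                             clinvar_stars=stars, plp_entry_fraction=plp,
                             hgmd_class=hgmd, functional_class=fc, hs=hs))
        df = pd.DataFrame(rows)
        # encode the high-stringency decision through the score columns
        df["vipur"] = np.where(df.pop("hs"), 0.95, 0.1)
        df["cadd"] = 30.0
        df["n_deleterious"] = 8
        df["n_predictors"] = 8
        df["missense_eligible"] = (~df["in_clinvar"]) & (df["functional_class"] == "missense")
        out = classify_variants(df)
        for i, row in df.iterrows():
            expected = classify_variant(
                row["in_clinvar"], row["clinvar_class"], row["clinvar_stars"],
                row["plp_entry_fraction"], row["hgmd_class"], row["functional_class"],
                bool(out.loc[i, "high_stringency"]),
            )
            got = out.loc[i, "group_index"]
            assert (expected is None and pd.isna(got)) or got == expected

    def test_groups_partition_assigned_variants(self):
        # every assigned variant matches exactly one group: re-running the
        # scalar classifier on each assigned row returns the same single group
        assert len(GROUP_NAMES) == 16
        assert len(set(GROUP_NAMES.values())) == 16


class TestHypomorphic:
    def test_registry_match_and_override(self):
        reg = HypomorphicRegistry(
            variant_keys={"6:100:A:T"},
            gene_wildcards={"SERPINA1"},
            keep_pathogenic={"1:271:A:AT"},
        )
        df = pd.DataFrame(
            {
                "variant_key": ["6:100:A:T", "19:5:C:G", "1:271:A:AT", "2:2:G:C"],
                "gene": ["HFE", "SERPINA1", "MMACHC", "PAH"],
            }
        )
        out = mark_hypomorphic(df, reg)
        assert out["hypomorphic"].tolist() == [True, True, False, False]

    def test_empty_registry_marks_nothing(self):
        df = pd.DataFrame({"variant_key": ["1:1:A:T"], "gene": ["HFE"]})
        assert not mark_hypomorphic(df, HypomorphicRegistry())["hypomorphic"].any()


@pytest.mark.parametrize(
    "cgg, expected",
    [
        (30, "normal"), (44, "normal"), (45, "intermediate"), (54, "intermediate"),
        (55, "premutation"), (67, "premutation"), (134, "premutation"),
        (200, "premutation"), (201, "full_mutation"), (350, "full_mutation"),
    ],
)
def test_fmr1_repeat_bins(cgg, expected):
    assert classify_fmr1_repeat(cgg) == expected


def test_fmr1_rejects_non_positive():
    with pytest.raises(ValueError):
        classify_fmr1_repeat(0)


class TestBenchmark:
    def _scores(self, passing):
        if passing:
            return MissenseScores(0.95, 30.0, ["deleterious"] * 8)
        return MissenseScores(0.1, 5.0, ["tolerated"] * 8)

    def test_perfect_separation(self):
        labeled = [(self._scores(True), "P/LP")] * 5 + [(self._scores(False), "B/LB")] * 5
        assert benchmark_missense_rule(labeled) == (1.0, 1.0)

    def test_confusion_matrix_arithmetic(self):
        # 24 of 100 positives pass, 3 of 100 negatives pass -> (0.24, 0.97)
        labeled = (
            [(self._scores(True), "P/LP")] * 24
            + [(self._scores(False), "P/LP")] * 76
            + [(self._scores(True), "B/LB")] * 3
            + [(self._scores(False), "B/LB")] * 97
        )
        sens, spec = benchmark_missense_rule(labeled)
        assert sens == pytest.approx(0.24)
        assert spec == pytest.approx(0.97)

    def test_single_class_input_flagged_nan(self):
        sens, spec = benchmark_missense_rule([(self._scores(True), "P/LP")])
        assert sens == 1.0 and np.isnan(spec)

    @given(st.integers(0, 2**31 - 1))
    def test_threshold_rule_matches_exhaustive_count_oracle(self, seed):
        # two-Gaussian VIPUR score mix, simple vipur >= 0.5 rule
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.7, 0.2, 60).clip(0, 1)
        neg = rng.normal(0.3, 0.2, 60).clip(0, 1)
        labeled = [(MissenseScores(v, 99.0, ["deleterious"] * 8), "P/LP") for v in pos]
        labeled += [(MissenseScores(v, 99.0, ["deleterious"] * 8), "B/LB") for v in neg]
        rule = lambda s: s.vipur >= 0.5
        sens, spec = benchmark_missense_rule(labeled, rule=rule)
        # independent brute-force count
        tp = sum(v >= 0.5 for v in pos)
        tn = sum(v < 0.5 for v in neg)
        assert sens == pytest.approx(tp / 60)
        assert spec == pytest.approx(tn / 60)
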