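"""At-risk couples, virtual mating, risk-reduction potential, statistics."""
import itertools

import numpy as np
import pandas as pd
import pytest

from ecscreen import couples as cp


def make_profiles(rows):
    """rows: (sample_id, gene, variant_key, group, hypomorphic[, zygosity])"""
    recs = []
    for row in rows:
        sample, gene, key, group, hypo = row[:5]
        zyg = row[5] if len(row) > 5 else "het"
        recs.append(dict(sample_id=sample, gene=gene, variant_key=key,
                         group_index=group, hypomorphic=hypo, zygosity=zyg,
                         functional_class="truncating", gnomad_maf=1e-3))
    df = pd.DataFrame(recs)
    df["group_index"] = df["group_index"].astype("Int64")
    return df


def make_couples(pairs):
    return pd.DataFrame(
        [{"couple_id": f"p{i}", "mother_id": m, "father_id": f, "child_id": f"c{i}"}
         for i, (m, f) in enumerate(pairs)]
    )


class TestCarrierFrequencies:
    def test_gene_carrier_frequency(self):
        profiles = make_profiles(
            [("S1", "G1", "k1", 1, False), ("S2", "G1", "k2", 1, False)])
        assert cp.gene_carrier_frequency(profiles, "G1", 700, 14) == pytest.approx(2 / 700)
        assert cp.gene_carrier_frequency(profiles, "NOPE", 700, 14) == 0.0

    def test_threshold_changes_counts(self):
        profiles = make_profiles(
            [("S1", "G1", "k1", 1, False), ("S2", "G1", "k2", 14, False),
             ("S3", "G1", "k3", 14, False)]
            + [(f"S{i}", "G2", f"x{i}", 1, False) for i in range(4, 11)])
        assert cp.gene_carrier_frequency(profiles, "G1", 10, 1) == pytest.approx(0.1)
        assert cp.gene_carrier_frequency(profiles, "G1", 10, 14) == pytest.approx(0.3)

    def test_total_carrier_frequency_formula(self):
        # two individuals carrying one variant each in different genes: 2/2 = 1.0
        profiles = make_profiles(
            [("S1", "G1", "k1", 1, False), ("S2", "G2", "k2", 1, False)])
        m = cp.cumulative_carrier_metrics(profiles, ["S1", "S2"], 14)
        assert m["total_carrier_frequency"] == pytest.approx(1.0)
        assert m["frac_ge1"] == pytest.approx(1.0)
        # one individual with three genes: the formula exceeds 1
        profiles = make_profiles(
            [("S1", g, f"k{g}", 1, False) for g in ("G1", "G2", "G3")])
        m = cp.cumulative_carrier_metrics(profiles, ["S1"], 14)
        assert m["total_carrier_frequency"] == pytest.approx(3.0)

    def test_distribution_counts_zero_carriers(self):
        profiles = make_profiles([("S1", "G1", "k1", 1, False)])
        m = cp.cumulative_carrier_metrics(profiles, ["S1", "S2", "S3"], 14)
        assert m["min_variants"] == 0
        assert m["frac_ge1"] == pytest.approx(1 / 3)


class TestAtRisk:
    def test_both_partners_same_gene(self):
        profiles = make_profiles(
            [("M", "G1", "k1", 1, False), ("F", "G1", "k2", 1, False)])
        couples = make_couples([("M", "F")])
        at_risk = cp.find_at_risk_couples(couples, profiles, set(), 14)
        assert at_risk["p0"].ar_genes == {"G1"}

    def test_hypomorphic_only_constellation_excluded(self):
        profiles = make_profiles(
            [("M", "HFE", "k1", 4, True), ("F", "HFE", "k1", 4, True)])
        couples = make_couples([("M", "F")])
        at_risk = cp.find_at_risk_couples(couples, profiles, set(), 14)
        assert not at_risk["p0"].at_risk

    def test_hypomorph_plus_pathogenic_counts(self):
        profiles = make_profiles(
            [("M", "HFE", "k1", 4, True), ("F", "HFE", "k2", 1, False)])
        couples = make_couples([("M", "F")])
        assert cp.find_at_risk_couples(couples, profiles, set(), 14)["p0"].at_risk

    def test_xl_counts_mother_only(self):
        profiles = make_profiles(
            [("M", "XG", "k1", 1, False), ("F2", "XG", "k2", 1, False, "hemi")])
        couples = make_couples([("M", "F"), ("M2", "F2")])
        at_risk = cp.find_at_risk_couples(couples, profiles, {"XG"}, 14)
        assert at_risk["p0"].xl_genes == {"XG"}
        assert not at_risk["p1"].at_risk  # paternal hemizygous never at-risk

    def test_threshold_gates_at_risk(self):
        profiles = make_profiles(
            [("M", "G1", "k1", 1, False), ("F", "G1", "k2", 13, False)])
        couples = make_couples([("M", "F")])
        assert not cp.find_at_risk_couples(couples, profiles, set(), 12)["p0"].at_risk
        assert cp.find_at_risk_couples(couples, profiles, set(), 13)["p0"].at_risk


class TestVirtualEstimates:
    def test_single_ar_gene_two_of_four(self):
        est = cp.estimate_virtual_at_risk({"G1": 2}, {}, 4)
        assert est["ar_rate"] == pytest.approx(1 / 6)

    def test_single_xl_gene_one_of_four(self):
        est = cp.estimate_virtual_at_risk({}, {"XG": 1}, 4)
        assert est["xl_rate"] == pytest.approx(1 / 6)

    def test_carrier_count_exceeding_cohort_rejected(self):
        with pytest.raises(ValueError):
            cp.estimate_virtual_at_risk({"G1": 5}, {}, 4)

    def test_equals_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(12)]
        for trial in range(5):
            n = int(rng.integers(10, 51))
            carrier_sets = {
                f"S{i}": set(rng.choice(genes, size=rng.integers(0, 5), replace=False))
                for i in range(n)
            }
            counts = {g: sum(g in s for s in carrier_sets.values()) for g in genes}
            est = cp.estimate_virtual_at_risk(counts, {}, n)
            assert est["ar_rate"] == pytest.approx(
                cp.brute_force_virtual_ar(carrier_sets), abs=0, rel=1e-12)

    def test_xl_per_female_alternative(self):
        est = cp.estimate_virtual_at_risk({}, {"XG": 3}, 100, n_females=50,
                                          xl_per_female=True)
        assert est["xl_rate"] == pytest.approx(3 / 50)


class TestRiskReduction:
    def _trio(self, mode=cp.AR_COMPHET, keys=("k1", "k2")):
        profiles = make_profiles(
            [("M", "G1", keys[0], 1, False), ("F", "G1", keys[1], 1, False)])
        couples = make_couples([("M", "F")])
        children = pd.DataFrame(
            [{"couple_id": "p0", "child_id": "c0", "sex": "M", "mode": mode}])
        diagnoses = pd.DataFrame(
            [{"couple_id": "p0", "gene": "G1", "variant_key": keys[0],
              "origin": "maternal", "is_cnv": False},
             {"couple_id": "p0", "gene": "G1", "variant_key": keys[1],
              "origin": "paternal", "is_cnv": False}])
        return couples, children, diagnoses, profiles

    def test_matched_transmission(self):
        couples, children, diagnoses, profiles = self._trio()
        at_risk = cp.find_at_risk_couples(couples, profiles, set(), 14)
        rrp = cp.risk_reduction_potential(couples, children, diagnoses, at_risk, profiles)
        assert rrp["ar_rrp"] == pytest.approx(1.0)
        assert rrp["xl_rrp"] == 0.0

    def test_no_diagnosed_children_gives_zero(self):
        couples, children, diagnoses, profiles = self._trio()
        children["mode"] = None
        at_risk = cp.find_at_risk_couples(couples, profiles, set(), 14)
        rrp = cp.risk_reduction_potential(couples, children, diagnoses, at_risk, profiles)
        assert rrp["total_rrp"] == 0.0

    def test_partially_qualifying_inheritance_not_matched(self):
        # one causal allele fails the screen -> the couple does not count
        couples, children, diagnoses, profiles = self._trio()
        profiles = profiles.iloc[:1]  # father's causal variant not qualifying
        at_risk = cp.find_at_risk_couples(couples, profiles, set(), 14)
        rrp = cp.risk_reduction_potential(couples, children, diagnoses, at_risk, profiles)
        assert rrp["total_rrp"] == 0.0

    def test_rrp_never_exceeds_at_risk_frequency(self):
        couples, children, diagnoses, profiles = self._trio()
        for k in range(1, 15):
            at_risk = cp.find_at_risk_couples(couples, profiles, set(), k)
            rrp = cp.risk_reduction_potential(
                couples, children, diagnoses, at_risk, profiles, k)
            assert rrp["total_rrp"] <= cp.at_risk_frequency(at_risk) + 1e-12


class TestUndetectedAccounting:
    def test_empty_when_no_diagnoses(self):
        profiles = make_profiles([("M", "G1", "k1", 1, False)])
        couples = make_couples([("M", "F")])
        children = pd.DataFrame(
            [{"couple_id": "p0", "child_id": "c0", "sex": "M", "mode": None}])
        out = cp.undetected_risk_accounting(
            couples, children, pd.DataFrame(columns=["couple_id", "gene",
                                                     "variant_key", "origin", "is_cnv"]),
            {}, profiles)
        assert out["n_detectable"] == 0
        assert np.isnan(out["sensitivity"])


class TestStatistics:
    def test_consanguinity_enrichment_table(self):
        # 13/52 consanguineous among at-risk vs 10/262 among not-at-risk
        out = cp.fisher_test([[13, 39], [10, 262]])
        assert out["p_value"] == pytest.approx(1e-4, abs=1e-4)
        assert out["p_value"] <= 0.05

    def test_fisher_identity_table(self):
        assert cp.fisher_test([[1, 0], [0, 1]])["p_value"] == pytest.approx(1.0)

    def test_fisher_exhaustive_hypergeometric_oracle(self):
        # enumerate all tables with the same margins; two-sided p = sum of
        # probabilities of tables at most as probable as the observed one
        from math import comb
        a, b, c, d = 3, 1, 2, 4
        n, r1, c1_ = a + b + c + d, a + b, a + c
        def prob(x):
            return (comb(r1, x) * comb(n - r1, c1_ - x)) / comb(n, c1_)
        p_obs = prob(a)
        p_two = sum(prob(x) for x in range(max(0, c1_ - (n - r1)), min(r1, c1_) + 1)
                    if prob(x) <= p_obs * (1 + 1e-9))
        assert cp.fisher_test([[a, b], [c, d]])["p_value"] == pytest.approx(p_two)

    def test_welch_identical_groups(self):
        out = cp.welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        out = cp.fisher_test([[0, 0], [1, 2]])
        assert np.isnan(out["p_value"])


class TestPolicy:
    def test_missense_only_couple_dropped_truncating_trigger_kept(self):
        profiles = pd.DataFrame([
            # couple p0: both partners high-stringency missense only -> drop
            dict(sample_id="M", gene="G1", variant_key="k1", group_index=14,
                 hypomorphic=False, zygosity="het", functional_class="missense",
                 gnomad_maf=1e-3),
            dict(sample_id="F", gene="G1", variant_key="k2", group_index=14,
                 hypomorphic=False, zygosity="het", functional_class="missense",
                 gnomad_maf=1e-3),
            # couple p1: truncating partner triggers missense assessment -> keep
            dict(sample_id="M2", gene="G2", variant_key="k3", group_index=13,
                 hypomorphic=False, zygosity="het", functional_class="truncating",
                 gnomad_maf=1e-3),
            dict(sample_id="F2", gene="G2", variant_key="k4", group_index=14,
                 hypomorphic=False, zygosity="het", functional_class="missense",
                 gnomad_maf=1e-3),
        ])
        profiles["group_index"] = profiles["group_index"].astype("Int64")
        couples = make_couples([("M", "F"), ("M2", "F2")])
        plain = cp.find_at_risk_couples(couples, profiles, set(), 14)
        assert plain["p0"].at_risk and plain["p1"].at_risk
        policy = cp.pragmatic_policy(couples, profiles, set(), 14)
        assert not policy["p0"].at_risk
        assert policy["p1"].at_risk

    def test_common_truncating_does_not_auto_qualify(self):
        # unannotated truncating variant at MAF 0.6% fails the policy
        assert cp.policy_class(13, "truncating", 0.006) == "fail"
        assert cp.policy_class(13, "truncating", 0.004) == "auto"
        assert cp.policy_class(7, "truncating", 0.1) == "manual"
        assert cp.policy_class(1, "truncating", 0.1) == "auto"
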