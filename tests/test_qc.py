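"""Quality, consequence, artifact and frequency filters."""
import pandas as pd
import pytest

from ecscreen.qc import (
    apply_qc,
    artifact_filter,
    frequency_filter,
    prefilter_variants,
    rare_missense_gate,
)

from conftest import make_annotation, make_call


def _annotated(calls, annotations):
    from ecscreen.qc import annotate_calls
    return annotate_calls(pd.DataFrame(calls), pd.DataFrame(annotations))


class TestPrefilter:
    def test_quality_below_12_removed_even_if_clinvar_pathogenic(self, frames):
        calls, ann = frames(
            [make_call(quality=11.9)],
            [make_annotation(in_clinvar=True, clinvar_class="P", clinvar_stars=2)],
        )
        retained, report = prefilter_variants(calls, ann)
        assert len(retained) == 0
        assert list(report["reason"]) == ["quality<12"]

    @pytest.mark.parametrize("fclass", ["synonymous", "utr", "intronic_far"])
    def test_non_clinvar_silent_consequences_removed(self, frames, fclass):
        calls, ann = frames([make_call(quality=50)], [make_annotation(functional_class=fclass)])
        retained, _ = prefilter_variants(calls, ann)
        assert len(retained) == 0

    def test_clinvar_branch_bypasses_consequence_filter(self, frames):
        calls, ann = frames(
            [make_call(quality=50)],
            [make_annotation(in_clinvar=True, clinvar_class="VUS",
                             functional_class="synonymous")],
        )
        retained, _ = prefilter_variants(calls, ann)
        assert len(retained) == 1

    def test_non_clinvar_call_without_functional_class_is_hard_error(self, frames):
        calls, ann = frames([make_call()], [make_annotation(functional_class=None)])
        with pytest.raises(ValueError, match="functional class"):
            prefilter_variants(calls, ann)


class TestArtifactFilter:
    def test_lone_low_alt_fraction_removed(self):
        df = _annotated([make_call(alt_fraction=0.25)], [make_annotation()])
        retained, report = artifact_filter(df)
        assert len(retained) == 0 and list(report["reason"]) == ["low_alt_fraction"]

    def test_recurrence_rule_removes_all_calls_of_the_variant(self):
        # 10 carriers, 9 below 28% -> 90% of carriers low -> all 10 discarded
        calls = [make_call(sample_id=f"S{i}", alt_fraction=0.20) for i in range(9)]
        calls.append(make_call(sample_id="S9", alt_fraction=0.50))
        df = _annotated(calls, [make_annotation()])
        retained, report = artifact_filter(df)
        assert len(retained) == 0
        assert set(report["reason"]) == {"recurrent_low_alt_fraction"}

    def test_recurrence_rule_below_90pct_keeps_normal_carriers(self):
        # 8 of 10 low (80% < 90%): only the individually-low calls drop
        calls = [make_call(sample_id=f"S{i}", alt_fraction=0.20) for i in range(8)]
        calls += [make_call(sample_id=f"S{8 + i}", alt_fraction=0.50) for i in range(2)]
        df = _annotated(calls, [make_annotation()])
        retained, _ = artifact_filter(df)
        assert sorted(retained["sample_id"]) == ["S8", "S9"]

    @pytest.mark.parametrize("ff, removed", [(0.5, False), (0.19, True), (0.81, True),
                                             (0.2, False), (0.8, False)])
    def test_strand_ratio_bounds(self, ff, removed):
        df = _annotated([make_call(forward_fraction=ff)], [make_annotation()])
        retained, _ = artifact_filter(df)
        assert (len(retained) == 0) == removed

    def test_homology_region_removed(self):
        df = _annotated([make_call()], [make_annotation(homology_region=True)])
        retained, report = artifact_filter(df)
        assert len(retained) == 0 and list(report["reason"]) == ["homology_region"]

    @pytest.mark.parametrize("zygosity", ["hom", "hemi"])
    def test_alt_fraction_rules_skip_non_heterozygous_calls(self, zygosity):
        df = _annotated(
            [make_call(zygosity=zygosity, alt_fraction=0.95)], [make_annotation()])
        retained, _ = artifact_filter(df)
        assert len(retained) == 1

    def test_clean_call_retained(self):
        df = _annotated([make_call()], [make_annotation()])
        retained, report = artifact_filter(df)
        assert len(retained) == 1 and len(report) == 0


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "maf, homhemi, removed",
        [(0.06, 0, True), (0.001, 3, True), (0.004, 0, False), (0.05, 2, False)],
    )
    def test_gnomad_thresholds(self, maf, homhemi, removed):
        df = _annotated(
            [make_call()],
            [make_annotation(gnomad_maf=maf, gnomad_homhemi=homhemi)],
        )
        retained, _ = frequency_filter(df, n_samples=700)
        assert (len(retained) == 0) == removed

    def test_cohort_frequency_rule(self):
        # 8 het carriers among 10 samples -> cohort AF 0.4 > 5%
        calls = [make_call(sample_id=f"S{i}") for i in range(8)]
        df = _annotated(calls, [make_annotation(gnomad_maf=0.001)])
        retained, _ = frequency_filter(df, n_samples=10)
        assert len(retained) == 0

    def test_clinvar_calls_unaffected(self):
        calls = [make_call(sample_id=f"S{i}") for i in range(8)]
        df = _annotated(
            calls,
            [make_annotation(in_clinvar=True, clinvar_class="conflicting",
                             plp_entry_fraction=0.8, gnomad_maf=0.14)],
        )
        retained, _ = frequency_filter(df, n_samples=10)
        assert len(retained) == 8


class TestRareMissenseGate:
    @pytest.mark.parametrize(
        "in_cv, fclass, maf, eligible",
        [
            (False, "missense", 0.019, True),
            (False, "missense", 0.02, False),   # strict boundary
            (False, "truncating", 0.001, False),
            (True, "missense", 0.001, False),
        ],
    )
    def test_eligibility(self, in_cv, fclass, maf, eligible):
        kwargs = dict(in_clinvar=in_cv, functional_class=fclass, gnomad_maf=maf)
        if in_cv:
            kwargs["clinvar_class"] = "VUS"
        df = _annotated([make_call()], [make_annotation(**kwargs)])
        assert rare_missense_gate(df).tolist() == [eligible]


class TestFilterAlgebra:
    def _cohort(self):
        calls = [
            make_call(sample_id="S1", pos=100),
            make_call(sample_id="S2", pos=100),
            make_call(sample_id="S1", pos=200, alt_fraction=0.22),
            make_call(sample_id="S3", pos=300, quality=5),
            make_call(sample_id="S4", pos=400, forward_fraction=0.95),
        ]
        ann = [
            make_annotation(pos=100),
            make_annotation(pos=200),
            make_annotation(pos=300),
            make_annotation(pos=400),
        ]
        return pd.DataFrame(calls), pd.DataFrame(ann)

    def test_output_subset_and_report_accounting(self):
        calls, ann = self._cohort()
        result = apply_qc(calls, ann)
        assert len(result.retained) + len(result.report) == len(calls)
        keys = set(zip(calls["sample_id"], calls["pos"]))
        kept = set(zip(result.retained["sample_id"], result.retained["pos"]))
        assert kept <= keys

    def test_filters_are_idempotent(self):
        calls, ann = self._cohort()
        once = apply_qc(calls, ann)
        twice = apply_qc(
            once.retained[calls.columns].reset_index(drop=True), ann,
            n_samples=calls["sample_id"].nunique(),
        )
        assert len(twice.report) == 0
        assert twice.retained[calls.columns].reset_index(drop=True).equals(
            once.retained[calls.columns].reset_index(drop=True))

    def test_strand_homology_quality_rules_commute(self):
        calls, ann = self._cohort()
        df = _annotated(calls.to_dict("records"), ann.to_dict("records"))
        a, _ = artifact_filter(df)
        b, _ = frequency_filter(a, n_samples=4)
        # swapped order gives the same surviving set
        c, _ = frequency_filter(df, n_samples=4)
        d, _ = artifact_filter(c)
        key = ["sample_id", "variant_key"]
        assert sorted(map(tuple, b[key].values.tolist())) == sorted(
            map(tuple, d[key].values.tolist()))
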