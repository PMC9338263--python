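import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ecscreen import analyze_cohort, paper_counts_fixture

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_bundle():
    """The deterministic 700-parent reference cohort."""
    return paper_counts_fixture()


@pytest.fixture(scope="session")
def reference_result(reference_bundle):
    """Full analysis of the reference cohort at the default threshold."""
    return analyze_cohort(reference_bundle, k=14)


def make_annotation(chrom="1", pos=100, ref="A", alt="T", gene="GENE1",
                    in_clinvar=False, clinvar_class="none", clinvar_stars=0,
                    plp_entry_fraction=np.nan, hgmd_class="none",
                    gnomad_maf=1e-4, gnomad_homhemi=0,
                    functional_class="truncating", homology_region=False,
                    vipur=np.nan, cadd=np.nan, n_deleterious=np.nan,
                    n_predictors=np.nan):
    return dict(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        in_clinvar=in_clinvar, clinvar_class=clinvar_class,
        clinvar_stars=clinvar_stars, plp_entry_fraction=plp_entry_fraction,
        hgmd_class=hgmd_class, gnomad_maf=gnomad_maf,
        gnomad_homhemi=gnomad_homhemi, functional_class=functional_class,
        homology_region=homology_region, vipur=vipur, cadd=cadd,
        n_deleterious=n_deleterious, n_predictors=n_predictors,
    )


def make_call(sample_id="S1", gene="GENE1", chrom="1", pos=100, ref="A",
              alt="T", zygosity="het", quality=50.0, alt_fraction=0.5,
              forward_fraction=0.5):
    return dict(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos, ref=ref,
        alt=alt, zygosity=zygosity, quality=quality,
        alt_fraction=alt_fraction, forward_fraction=forward_fraction,
    )


@pytest.fixture
def frames():
    """Factory turning row dicts into (calls, annotations) DataFrames."""

    def build(calls, annotations):
        return pd.DataFrame(calls), pd.DataFrame(annotations)

    return build
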