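"""Variant-level quality control for cohort carrier screening.

Filters raw per-sample variant calls before pathogenicity classification:

* overall call quality >= 12;
* consequence filter for variants without a ClinVar record (UTR, deep
  intronic beyond +-3 bp, synonymous);
* artifact removal: low alternative-read fraction in a single carrier
  (< 28%), variant-wide removal when >= 90% of carriers sit below that
  fraction, extreme forward/reverse strand ratio (< 0.2 or > 0.8), and
  calls inside known homology regions;
* population/cohort frequency filter for non-ClinVar variants (gnomAD
  MAF > 5%, cohort allele frequency > 5%, or > 2 homozygotes/hemizygotes
  reported in gnomAD).

All filters have set semantics (the output is a subset of the input and
reapplication is a no-op).  The alternative-read-fraction rules target
heterozygous calls only: homozygous and hemizygous calls legitimately sit
near an alternative fraction of 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QUALITY_MIN = 12.0
ALT_FRACTION_MIN = 0.28
RECURRENCE_CARRIER_FRACTION = 0.90
STRAND_MIN, STRAND_MAX = 0.2, 0.8
MAF_MAX = 0.05
GNOMAD_HOMHEMI_MAX = 2
RARE_MISSENSE_MAF = 0.02

#: consequence classes removed for variants without a ClinVar record
NON_CLINVAR_DROPPED_CLASSES = frozenset({"utr", "intronic_far", "synonymous"})

CALL_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "zygosity", "quality", "alt_fraction", "forward_fraction",
]

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "in_clinvar", "clinvar_class",
    "clinvar_stars", "plp_entry_fraction", "hgmd_class", "gnomad_maf",
    "gnomad_homhemi", "functional_class", "homology_region",
]


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def add_variant_key(df: pd.DataFrame) -> pd.DataFrame:
    if "variant_key" not in df.columns:
        df = df.copy()
        df["variant_key"] = (
            df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str)
            + ":" + df["ref"].astype(str) + ":" + df["alt"].astype(str)
        )
    return df


def annotate_calls(calls: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Left-join calls with the annotation table on the variant key.

    Calls without an annotation row are treated as non-ClinVar with unknown
    functional class (the prefilter turns that into a hard error, since the
    consequence filter cannot be evaluated).
    """
    calls = add_variant_key(calls)
    ann = add_variant_key(annotations)
    ann_cols = [c for c in ann.columns if c not in ("chrom", "pos", "ref", "alt", "gene")]
    merged = calls.merge(ann[ann_cols], on="variant_key", how="left")
    merged["in_clinvar"] = merged["in_clinvar"].fillna(False).astype(bool)
    merged["homology_region"] = merged.get("homology_region", False)
    merged["homology_region"] = merged["homology_region"].fillna(False).astype(bool)
    return merged


@dataclass
class QcResult:
    retained: pd.DataFrame
    report: pd.DataFrame  # one row per removed call with a reason

    @property
    def n_removed(self) -> int:
        return len(self.report)


def _split(df: pd.DataFrame, removed_mask: pd.Series, reason: str):
    removed = df.loc[removed_mask, ["sample_id", "variant_key"]].copy()
    removed["reason"] = reason
    return df.loc[~removed_mask], removed


def prefilter_variants(calls: pd.DataFrame, annotations: pd.DataFrame):
    """Quality and consequence filter.

    ClinVar-annotated calls are retained regardless of consequence; variants
    without ClinVar record are dropped when their functional class is UTR,
    deep intronic (> +-3 bp) or synonymous.
    """
    df = annotate_calls(calls, annotations)
    reports = []

    df, rem = _split(df, df["quality"] < QUALITY_MIN, "quality<12")
    reports.append(rem)

    non_cv = ~df["in_clinvar"]
    missing_fc = non_cv & df["functional_class"].isna()
    if missing_fc.any():
        keys = sorted(df.loc[missing_fc, "variant_key"].unique())
        raise ValueError(
            f"non-ClinVar calls without functional class: {keys[:5]}"
            + ("..." if len(keys) > 5 else "")
        )
    drop = non_cv & df["functional_class"].isin(NON_CLINVAR_DROPPED_CLASSES)
    df, rem = _split(df, drop, "non_clinvar_consequence")
    reports.append(rem)

    return df.reset_index(drop=True), pd.concat(reports, ignore_index=True)


def artifact_filter(calls: pd.DataFrame):
    """Cohort-wide artifact removal (alt fraction, recurrence, strand, homology).

    The recurrence rule is evaluated over the heterozygous carriers of each
    variant: when a variant is seen in >= 2 carriers and >= 90% of them show
    an alternative-read fraction below 28%, every call of that variant is
    discarded.  The single-sample and recurrence rules skip homozygous and
    hemizygous calls.
    """
    df = calls
    het = df["zygosity"] == "het"

    low_single = het & (df["alt_fraction"] < ALT_FRACTION_MIN)

    het_calls = df.loc[het]
    by_key = het_calls.groupby("variant_key")["alt_fraction"]
    n_carriers = by_key.size()
    frac_low = by_key.apply(lambda s: float(np.mean(s < ALT_FRACTION_MIN)))
    recurrent_keys = n_carriers.index[
        (n_carriers >= 2) & (frac_low >= RECURRENCE_CARRIER_FRACTION)
    ]
    recurrent = df["variant_key"].isin(set(recurrent_keys))

    strand = (df["forward_fraction"] < STRAND_MIN) | (df["forward_fraction"] > STRAND_MAX)
    homology = df["homology_region"].astype(bool)

    reasons = np.select(
        [recurrent, low_single, strand, homology],
        ["recurrent_low_alt_fraction", "low_alt_fraction", "strand_bias", "homology_region"],
        default="",
    )
    removed_mask = pd.Series(reasons != "", index=df.index)
    report = df.loc[removed_mask, ["sample_id", "variant_key"]].copy()
    report["reason"] = reasons[removed_mask.to_numpy()]
    return df.loc[~removed_mask].reset_index(drop=True), report.reset_index(drop=True)


def cohort_allele_frequency(calls: pd.DataFrame, n_samples: int | None = None) -> pd.Series:
    """Per-variant cohort allele frequency (het = 1 allele, hom = 2, hemi = 1)."""
    if n_samples is None:
        n_samples = calls["sample_id"].nunique()
    alleles = calls["zygosity"].map({"het": 1, "hom": 2, "hemi": 1}).fillna(1)
    return alleles.groupby(calls["variant_key"]).sum() / (2.0 * n_samples)


def frequency_filter(calls: pd.DataFrame, n_samples: int | None = None):
    """Frequency filter for non-ClinVar calls.

    ClinVar-annotated calls are not subject to frequency removal at this
    stage (common hypomorphic alleles are handled downstream).
    """
    df = calls
    cohort_af = cohort_allele_frequency(df, n_samples)
    af = df["variant_key"].map(cohort_af)
    non_cv = ~df["in_clinvar"]
    drop = non_cv & (
        (df["gnomad_maf"].fillna(0.0) > MAF_MAX)
        | (af > MAF_MAX)
        | (df["gnomad_homhemi"].fillna(0) > GNOMAD_HOMHEMI_MAX)
    )
    retained, report = _split(df, drop, "frequency")
    return retained.reset_index(drop=True), report.reset_index(drop=True)


def rare_missense_gate(calls: pd.DataFrame) -> pd.Series:
    """Boolean mask of calls eligible for high-stringency missense scoring.

    Eligible calls are non-ClinVar missense with gnomAD MAF strictly below
    2%; everything else (including non-ClinVar truncating variants, which
    are classified directly) bypasses the in-silico stringency rule.
    """
    return (
        ~calls["in_clinvar"]
        & (calls["functional_class"] == "missense")
        & (calls["gnomad_maf"].fillna(1.0) < RARE_MISSENSE_MAF)
    )


def apply_qc(calls: pd.DataFrame, annotations: pd.DataFrame, n_samples: int | None = None) -> QcResult:
    """Run the full filter cascade in the canonical order.

    Order: quality -> consequence -> artifact rules (on the post-quality
    set) -> frequency.  ``n_samples`` fixes the cohort size for allele
    frequencies (defaults to the number of distinct samples in ``calls``).
    """
    if n_samples is None:
        n_samples = calls["sample_id"].nunique()
    reports = []
    df, rep = prefilter_variants(calls, annotations)
    reports.append(rep)
    df, rep = artifact_filter(df)
    reports.append(rep)
    df, rep = frequency_filter(df, n_samples)
    reports.append(rep)
    report = pd.concat(reports, ignore_index=True)
    logger.info("QC: %d calls in, %d removed, %d retained", len(calls), len(report), len(df))
    return QcResult(retained=df, report=report)
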