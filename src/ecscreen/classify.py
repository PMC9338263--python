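"""Pathogenicity classification of QC-retained variants.

Every retained variant is assigned to one of 16 ordered classification
groups built from three evidence axes: ClinVar state (P/LP with at least
one review star, P/LP with zero stars, or "conflicting" records in which
at least 75% of entries vote P/LP), HGMD state (DM, non-DM, absent), and
variant functional class (truncating, missense passing the
high-stringency rule, protein-length alteration, non-canonical splice).
Cumulative sets over the group index k form the pathogenicity-threshold
sweep used by the couple analysis; groups 15-16 exist but are excluded
from headline analyses by default because they are dominated by benign
variants.

The high-stringency missense rule requires VIPUR >= 0.85, CADD >= 20 and
>= 85% "deleterious" votes among the available calls of an eight-tool
ensemble (SIFT, PolyPhen2, LRT, MutationTaster, MutationAssessor, FATHMM,
PROVEAN, M-CAP); the vote fraction is computed over non-missing tools.

Canonical +-1/2 splice variants are treated as truncating; "non-canonical
splice" refers to intronic positions within 3 bp of the exon boundary
(deeper intronic calls never reach classification).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VIPUR_MIN = 0.85
CADD_MIN = 20.0
DELETERIOUS_VOTE_MIN = 0.85
CONFLICTING_PLP_MIN = 0.75

PLP_CLASSES = frozenset({"P", "LP", "P/LP"})
TRUNCATING_CLASSES = frozenset({"truncating", "canonical_splice"})

GROUP_NAMES = {
    1: "CV-P/LP_HGMD-DM",
    2: "CV-P/LP_HGMD-non-DM",
    3: "CV-P/LP_non-HGMD",
    4: "CV-conflicting_75%P/LP_HGMD-DM",
    5: "CV-conflicting_75%P/LP_HGMD-non-DM",
    6: "CV-conflicting_75%P/LP_non-HGMD",
    7: "CV-P/LP_HGMD-DM_zero-stars",
    8: "CV-P/LP_HGMD-non-DM_zero-stars",
    9: "CV-P/LP_non-HGMD_zero-stars",
    10: "non-CV_HGMD-DM_truncating",
    11: "non-CV_HGMD-DM_high-stringency-missense",
    12: "non-CV_HGMD-DM_protein-length-alteration",
    13: "non-CV_non-HGMD_truncating",
    14: "non-CV_non-HGMD_high-stringency-missense",
    15: "non-CV_non-HGMD_non-canonical-splice",
    16: "non-CV_non-HGMD_protein-length-alteration",
}

#: zero-review-star ClinVar groups (droppable by the "no unreviewed entries" option)
ZERO_STAR_GROUPS = frozenset({7, 8, 9})

#: default upper group index for headline analyses (15-16 excluded)
DEFAULT_K_MAX = 14


@dataclass
class MissenseScores:
    """In-silico evidence for one missense variant (scores are inputs)."""

    vipur: float
    cadd: float
    predictor_calls: list = field(default_factory=list)  # "deleterious"/"tolerated"/"missing"

    @property
    def n_available(self) -> int:
        return sum(c != "missing" for c in self.predictor_calls)

    @property
    def n_deleterious(self) -> int:
        return sum(c == "deleterious" for c in self.predictor_calls)


def high_stringency_missense(scores: MissenseScores) -> bool:
    """Apply the three-way in-silico threshold rule to one missense variant."""
    if scores.n_available == 0:
        logger.warning("missense variant with no available predictor calls")
        return False
    return (
        scores.vipur >= VIPUR_MIN
        and scores.cadd >= CADD_MIN
        and scores.n_deleterious / scores.n_available >= DELETERIOUS_VOTE_MIN
    )


def high_stringency_mask(
    vipur: pd.Series, cadd: pd.Series, n_deleterious: pd.Series, n_predictors: pd.Series
) -> pd.Series:
    """Vectorized high-stringency rule over annotation columns."""
    n_avail = n_predictors.fillna(0)
    frac = n_deleterious.fillna(0) / n_avail.where(n_avail > 0, np.nan)
    return (
        (vipur.fillna(0) >= VIPUR_MIN)
        & (cadd.fillna(0) >= CADD_MIN)
        & (frac >= DELETERIOUS_VOTE_MIN)
    ).fillna(False)


def conflicting_plp_qualifies(clinvar_class, plp_entry_fraction) -> bool:
    """True for ClinVar "conflicting" records with >= 75% P/LP entries."""
    if clinvar_class != "conflicting":
        return False
    if plp_entry_fraction is None or (isinstance(plp_entry_fraction, float) and math.isnan(plp_entry_fraction)):
        logger.warning("conflicting ClinVar record without entry counts")
        return False
    return plp_entry_fraction >= CONFLICTING_PLP_MIN


def classify_variant(
    in_clinvar: bool,
    clinvar_class: str,
    clinvar_stars: int,
    plp_entry_fraction,
    hgmd_class: str,
    functional_class: str,
    high_stringency: bool = False,
) -> int | None:
    """Assign one variant to its classification group (scalar reference path).

    Returns the group index 1..16, or None when the variant matches no group
    (it then drops out of the carrier analysis).  Pure function of its
    arguments; the vectorized :func:`classify_variants` must agree with it.
    """
    if not in_clinvar and clinvar_class not in (None, "none"):
        raise ValueError(f"inconsistent annotation: not in ClinVar but class={clinvar_class!r}")
    hgmd = hgmd_class if hgmd_class in ("DM", "non-DM") else "none"
    truncating = functional_class in TRUNCATING_CLASSES

    if in_clinvar:
        if clinvar_class in PLP_CLASSES:
            offset = {"DM": 0, "non-DM": 1, "none": 2}[hgmd]
            return (1 if clinvar_stars >= 1 else 7) + offset
        if conflicting_plp_qualifies(clinvar_class, plp_entry_fraction):
            return 4 + {"DM": 0, "non-DM": 1, "none": 2}[hgmd]
        return None
    if hgmd == "DM":
        if truncating:
            return 10
        if high_stringency:
            return 11
        if functional_class == "protein_length_alteration":
            return 12
        return None
    if hgmd == "none":
        if truncating:
            return 13
        if high_stringency:
            return 14
        if functional_class == "non_canonical_splice":
            return 15
        if functional_class == "protein_length_alteration":
            return 16
    return None


def classify_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized group assignment over an annotated call/variant table.

    Expects columns ``in_clinvar, clinvar_class, clinvar_stars,
    plp_entry_fraction, hgmd_class, functional_class`` and the in-silico
    score columns ``vipur, cadd, n_deleterious, n_predictors`` (used for
    the high-stringency flag of missense variants eligible per the rare
    missense gate, supplied as boolean column ``missense_eligible`` or
    derived as non-ClinVar missense).  Adds ``group_index`` (nullable
    integer) and ``group_name``.
    """
    df = df.copy()
    bad = (~df["in_clinvar"]) & df["clinvar_class"].notna() & (df["clinvar_class"] != "none")
    if bad.any():
        raise ValueError("inconsistent annotation: non-ClinVar rows with a ClinVar class")

    if "missense_eligible" in df.columns:
        eligible = df["missense_eligible"].astype(bool)
    else:
        eligible = (~df["in_clinvar"]) & (df["functional_class"] == "missense")
    hs = eligible & high_stringency_mask(
        df.get("vipur", pd.Series(np.nan, index=df.index)),
        df.get("cadd", pd.Series(np.nan, index=df.index)),
        df.get("n_deleterious", pd.Series(np.nan, index=df.index)),
        df.get("n_predictors", pd.Series(np.nan, index=df.index)),
    )
    df["high_stringency"] = hs

    cv = df["in_clinvar"].astype(bool)
    plp = cv & df["clinvar_class"].isin(PLP_CLASSES)
    conf75 = cv & (df["clinvar_class"] == "conflicting") & (
        df["plp_entry_fraction"].fillna(-1.0) >= CONFLICTING_PLP_MIN
    )
    stars1 = df["clinvar_stars"].fillna(0) >= 1
    dm = df["hgmd_class"] == "DM"
    nondm = df["hgmd_class"] == "non-DM"
    nohgmd = ~dm & ~nondm
    trunc = df["functional_class"].isin(TRUNCATING_CLASSES)
    pla = df["functional_class"] == "protein_length_alteration"
    ncs = df["functional_class"] == "non_canonical_splice"

    conditions = [
        plp & stars1 & dm,
        plp & stars1 & nondm,
        plp & stars1 & nohgmd,
        conf75 & dm,
        conf75 & nondm,
        conf75 & nohgmd,
        plp & ~stars1 & dm,
        plp & ~stars1 & nondm,
        plp & ~stars1 & nohgmd,
        ~cv & dm & trunc,
        ~cv & dm & hs,
        ~cv & dm & pla,
        ~cv & nohgmd & trunc,
        ~cv & nohgmd & hs,
        ~cv & nohgmd & ncs,
        ~cv & nohgmd & pla,
    ]
    group = np.select(conditions, list(range(1, 17)), default=0)
    df["group_index"] = pd.array(np.where(group == 0, pd.NA, group), dtype="Int64")
    df["group_name"] = df["group_index"].map(GROUP_NAMES)
    return df


# ---------------------------------------------------------------------------
# hypomorphic registry

@dataclass
class HypomorphicRegistry:
    """Known hypomorphic alleles (e.g. the common HFE/SERPINA1/BTD/FECH ones).

    Registered variants keep their classification group and count toward
    carrier frequencies, but a couple in which both partners carry only
    hypomorphic alleles of a gene is not an at-risk couple.
    ``keep_pathogenic`` overrides the registry for variants with convincing
    pathogenicity evidence despite a conflicting ClinVar record.
    """

    variant_keys: set = field(default_factory=set)
    gene_wildcards: set = field(default_factory=set)
    keep_pathogenic: set = field(default_factory=set)

    def is_hypomorphic(self, key: str, gene: str) -> bool:
        if key in self.keep_pathogenic:
            return False
        return key in self.variant_keys or gene in self.gene_wildcards


def mark_hypomorphic(df: pd.DataFrame, registry: HypomorphicRegistry) -> pd.DataFrame:
    df = df.copy()
    df["hypomorphic"] = [
        registry.is_hypomorphic(k, g) for k, g in zip(df["variant_key"], df["gene"])
    ]
    return df


# ---------------------------------------------------------------------------
# FMR1 repeat classes

def classify_fmr1_repeat(cgg: int) -> str:
    """Bin an FMR1 CGG repeat length: <45 normal, 45-54 intermediate,
    55-200 premutation, >200 full mutation."""
    cgg = int(cgg)
    if cgg < 1:
        raise ValueError("CGG repeat length must be positive")
    if cgg < 45:
        return "normal"
    if cgg <= 54:
        return "intermediate"
    if cgg <= 200:
        return "premutation"
    return "full_mutation"


# ---------------------------------------------------------------------------
# benchmarking harness for the missense rule

def benchmark_missense_rule(labeled, rule=high_stringency_missense):
    """Confusion-matrix sensitivity/specificity of a missense decision rule.

    ``labeled`` is an iterable of (MissenseScores, label) with labels
    "P/LP" (positive) or "B/LB" (negative).  Returns (sensitivity,
    specificity); a missing class yields NaN for its metric with a warning.
    """
    tp = fn = tn = fp = 0
    for scores, label in labeled:
        pred = rule(scores)
        if label == "P/LP":
            tp += pred
            fn += not pred
        elif label == "B/LB":
            fp += pred
            tn += not pred
        else:
            raise ValueError(f"unknown label {label!r}")
    if tp + fn == 0:
        logger.warning("no positive examples; sensitivity undefined")
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        logger.warning("no negative examples; specificity undefined")
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    return sens, spec
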