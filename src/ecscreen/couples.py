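"""Carrier frequencies, at-risk couples and risk-reduction potential.

Core cohort analysis over classified carrier profiles, parameterized by
the cumulative classification threshold k (a variant "qualifies" at k when
its group index is <= k; the default headline threshold is 14).

Definitions
-----------
* Gene carrier frequency: fraction of individuals carrying >= 1 qualifying
  variant in the gene.
* Total carrier frequency: (1/N) * sum over genes of carrier counts — a
  per-individual expectation that can exceed 1.
* AR at-risk couple: both partners carry a qualifying variant in the same
  autosomal gene; constellations in which both partners carry only
  hypomorphic alleles of the gene do not count.
* XL at-risk couple: the female partner carries a qualifying variant in an
  X-linked gene (hemizygous qualifying variants in fathers are reported
  separately, never as at-risk).
* Virtual at-risk rates (random mating over actual genotypes):
  sum_i C(n_i, 2) / C(N, 2) for AR genes and sum_i C(n_i, 1) / C(N, 2)
  for XL genes, with n_i carriers of gene i among N individuals.  The XL
  denominator C(N, 2) is kept as displayed; a per-couple female-carrier
  alternative (n_i / N_females) is available under a flag.
* Risk-reduction potential (RRP): fraction of all couples whose affected
  child's diagnosis matches the couple's at-risk genotypes — the causal
  gene is in the couple's at-risk set at threshold k AND every inherited
  causal variant is among the transmitting parent's qualifying variants.
  A child with one qualifying and one non-qualifying inherited allele is
  not matched.

All couple-level metrics count a couple once however many genes put it at
risk; gene-level tables keep multiplicity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import fisher_exact, ttest_ind

from .classify import DEFAULT_K_MAX, TRUNCATING_CLASSES

logger = logging.getLogger(__name__)

# trio diagnosis modes
AR_HOM = "AR_hom"
AR_COMPHET = "AR_comphet"
XL_INHERITED = "XL_inherited"
XL_DENOVO = "XL_denovo"
AD_DENOVO = "AD_denovo"
AD_INHERITED = "AD_inherited"
MITO_DENOVO = "mito_denovo"
COMPHET_INH_DENOVO = "comphet_inherited_plus_denovo"
CNV_INVOLVING = "CNV_involving"

AR_MODES = frozenset({AR_HOM, AR_COMPHET})
XL_MODES = frozenset({XL_INHERITED})
#: recessive/X-linked inherited modes whose risk ECS could in principle detect
DETECTABLE_MODES = AR_MODES | XL_MODES
#: modes undetectable by sequence-variant carrier screening, by category
UNDETECTABLE_CATEGORIES = {
    XL_DENOVO: "de_novo_hemizygous",
    COMPHET_INH_DENOVO: "comphet_inherited_plus_denovo",
    CNV_INVOLVING: "cnv_involving",
}

#: minor allele frequency below which unannotated truncating variants
#: auto-qualify under the pragmatic screening policy
POLICY_TRUNCATING_MAF = 0.005


def _qualifying(profiles: pd.DataFrame, k: int, exclude_groups=frozenset()) -> pd.DataFrame:
    qual = profiles.loc[profiles["group_index"].notna()]
    qual = qual.loc[qual["group_index"].astype(int) <= int(k)]
    if exclude_groups:
        qual = qual.loc[~qual["group_index"].astype(int).isin(set(exclude_groups))]
    return qual


# ---------------------------------------------------------------------------
# carrier frequencies

def carrier_frequency_table(profiles: pd.DataFrame, n_individuals: int, k: int,
                            exclude_groups=frozenset()) -> pd.Series:
    """Per-gene carrier frequency (individuals with >= 1 qualifying variant / N)."""
    qual = _qualifying(profiles, k, exclude_groups)
    carriers = qual.groupby("gene")["sample_id"].nunique()
    return carriers / float(n_individuals)


def gene_carrier_frequency(profiles, gene, n_individuals, k) -> float:
    table = carrier_frequency_table(profiles, n_individuals, k)
    if gene not in table.index:
        logger.warning("gene %s has no qualifying carriers", gene)
        return 0.0
    return float(table[gene])


def cumulative_carrier_metrics(profiles: pd.DataFrame, individuals, k: int) -> dict:
    """Cohort-level carrier metrics at threshold k.

    ``individuals`` is the full sample list (so zero-carriers enter the
    per-individual distribution).  Returns total carrier frequency (the
    per-gene-sum formula, which can exceed 1), the fraction of individuals
    with >= 1 qualifying variant, and the per-individual variant-count
    median and range.
    """
    individuals = list(individuals)
    n = len(individuals)
    qual = _qualifying(profiles, k)
    per_gene_carriers = qual.groupby("gene")["sample_id"].nunique()
    counts = qual.groupby("sample_id").size().reindex(individuals, fill_value=0)
    return {
        "total_carrier_frequency": float(per_gene_carriers.sum()) / n if n else 0.0,
        "frac_ge1": float((counts >= 1).mean()) if n else 0.0,
        "median_variants": float(counts.median()) if n else 0.0,
        "min_variants": int(counts.min()) if n else 0,
        "max_variants": int(counts.max()) if n else 0,
    }


# ---------------------------------------------------------------------------
# at-risk couples

@dataclass
class AtRiskCouple:
    couple_id: str
    ar_genes: set = field(default_factory=set)
    xl_genes: set = field(default_factory=set)

    @property
    def at_risk(self) -> bool:
        return bool(self.ar_genes or self.xl_genes)


def _gene_variant_map(qual: pd.DataFrame) -> dict:
    """sample_id -> gene -> list of (variant_key, group_index, hypomorphic)."""
    out: dict = {}
    for row in qual.itertuples(index=False):
        out.setdefault(row.sample_id, {}).setdefault(row.gene, []).append(
            (row.variant_key, int(row.group_index), bool(row.hypomorphic))
        )
    return out


def find_at_risk_couples(
    couples: pd.DataFrame,
    profiles: pd.DataFrame,
    xl_genes: set,
    k: int = DEFAULT_K_MAX,
    exclude_groups=frozenset(),
) -> dict[str, AtRiskCouple]:
    """Identify real at-risk couples at threshold k.

    Raises if a couple references an individual absent from the cohort's
    profile universe (profiles only contain carriers, so absence from
    ``profiles`` alone is not an error).
    """
    qual = _qualifying(profiles, k, exclude_groups)
    carriers = _gene_variant_map(qual)
    result: dict[str, AtRiskCouple] = {}
    for row in couples.itertuples(index=False):
        mother = carriers.get(row.mother_id, {})
        father = carriers.get(row.father_id, {})
        ar = set()
        for gene in set(mother) & set(father):
            if gene in xl_genes:
                continue
            both_hypomorphic_only = all(h for *_, h in mother[gene]) and all(
                h for *_, h in father[gene]
            )
            if not both_hypomorphic_only:
                ar.add(gene)
        xl = {
            g for g in mother
            if g in xl_genes and not all(h for *_, h in mother[g])
        }
        result[row.couple_id] = AtRiskCouple(row.couple_id, ar, xl)
    return result


def at_risk_frequency(at_risk: dict, couple_ids=None) -> float:
    ids = list(couple_ids) if couple_ids is not None else list(at_risk)
    if not ids:
        return 0.0
    return sum(at_risk[c].at_risk for c in ids if c in at_risk) / len(ids)


# ---------------------------------------------------------------------------
# virtual (random-mating) at-risk estimates

def estimate_virtual_at_risk(
    ar_carrier_counts: dict,
    xl_carrier_counts: dict,
    n_individuals: int,
    n_females: int | None = None,
    xl_per_female: bool = False,
) -> dict:
    """Virtual at-risk rates from per-gene carrier counts.

    ``xl_per_female=True`` switches the X-linked estimate to carrier
    females over all females instead of the displayed C(N,2) denominator.
    """
    n = int(n_individuals)
    if n < 2:
        raise ValueError("need at least two individuals")
    for counts in (ar_carrier_counts, xl_carrier_counts):
        for gene, c in counts.items():
            if c > n:
                raise ValueError(f"gene {gene}: more carriers ({c}) than individuals ({n})")
    pairs = comb(n, 2, exact=True)
    ar_rate = sum(comb(c, 2, exact=True) for c in ar_carrier_counts.values()) / pairs
    if xl_per_female:
        if not n_females:
            raise ValueError("xl_per_female requires n_females")
        xl_rate = sum(xl_carrier_counts.values()) / n_females
    else:
        xl_rate = sum(xl_carrier_counts.values()) / pairs
    return {"ar_rate": ar_rate, "xl_rate": xl_rate}


def brute_force_virtual_ar(profile_genes: dict) -> float:
    """Exhaustive all-unordered-pairs oracle for the virtual AR rate.

    ``profile_genes`` maps individual -> set of carrier genes; shared genes
    are counted per gene with multiplicity, matching the displayed formula.
    Quadratic; intended for cohorts of <= a few hundred individuals.
    """
    ids = sorted(profile_genes)
    n = len(ids)
    shared = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared += len(profile_genes[ids[i]] & profile_genes[ids[j]])
    return shared / comb(n, 2, exact=True)


# ---------------------------------------------------------------------------
# risk-reduction potential

def _parent_qual_keys(qual: pd.DataFrame) -> dict:
    out: dict = {}
    for row in qual.itertuples(index=False):
        out.setdefault(row.sample_id, set()).add(row.variant_key)
    return out


def match_diagnoses(
    couples: pd.DataFrame,
    children: pd.DataFrame,
    diagnoses: pd.DataFrame,
    at_risk: dict,
    profiles: pd.DataFrame,
    k: int = DEFAULT_K_MAX,
    exclude_groups=frozenset(),
    panel: set | None = None,
) -> pd.DataFrame:
    """Match each diagnosed child against the couple's at-risk genotypes.

    Returns one row per couple with a recessive/X-linked inherited
    diagnosis: couple_id, mode, gene, matched (bool).  Diagnoses with a de
    novo or CNV component are never matched (they are categorized by
    :func:`undetected_risk_accounting`).
    """
    qual_keys = _parent_qual_keys(_qualifying(profiles, k, exclude_groups))
    parent_of = {
        row.couple_id: (row.mother_id, row.father_id)
        for row in couples.itertuples(index=False)
    }
    unknown = set(children["couple_id"]) - set(parent_of)
    if unknown:
        raise KeyError(f"children reference unknown couples: {sorted(unknown)[:5]}")

    rows = []
    diagnosed = children.loc[children["mode"].isin(DETECTABLE_MODES)]
    dx_by_couple = dict(tuple(diagnoses.groupby("couple_id"))) if len(diagnoses) else {}
    for child in diagnosed.itertuples(index=False):
        couple_id = child.couple_id
        mother_id, father_id = parent_of[couple_id]
        dx = dx_by_couple.get(couple_id)
        matched = False
        gene = None
        if dx is not None and len(dx):
            gene = dx["gene"].iloc[0]
            risk = at_risk.get(couple_id, AtRiskCouple(couple_id))
            risk_genes = risk.ar_genes if child.mode in AR_MODES else risk.xl_genes
            gene_ok = gene in risk_genes and (panel is None or gene in panel)
            inherited = dx.loc[dx["origin"].isin(["maternal", "paternal"]) & ~dx["is_cnv"]]
            variants_ok = len(inherited) > 0
            for row in inherited.itertuples(index=False):
                parent = mother_id if row.origin == "maternal" else father_id
                if row.variant_key not in qual_keys.get(parent, set()):
                    variants_ok = False
            matched = gene_ok and variants_ok
        rows.append((couple_id, child.mode, gene, matched))
    return pd.DataFrame(rows, columns=["couple_id", "mode", "gene", "matched"])


def risk_reduction_potential(
    couples: pd.DataFrame,
    children: pd.DataFrame,
    diagnoses: pd.DataFrame,
    at_risk: dict,
    profiles: pd.DataFrame,
    k: int = DEFAULT_K_MAX,
    exclude_groups=frozenset(),
    panel: set | None = None,
    couple_ids=None,
) -> dict:
    """AR, XL and combined risk-reduction potential at threshold k.

    The denominator is all couples (or the ``couple_ids`` subset, e.g. a
    consanguinity stratum); the numerator counts couples whose child's
    diagnosis matches their at-risk genotypes.
    """
    matches = match_diagnoses(
        couples, children, diagnoses, at_risk, profiles, k, exclude_groups, panel
    )
    if couple_ids is not None:
        couple_ids = set(couple_ids)
        matches = matches.loc[matches["couple_id"].isin(couple_ids)]
        denom = len(couple_ids)
    else:
        denom = len(couples)
    if denom == 0:
        return {"ar_rrp": 0.0, "xl_rrp": 0.0, "total_rrp": 0.0,
                "ar_matched": set(), "xl_matched": set()}
    ar_matched = set(matches.loc[matches["matched"] & matches["mode"].isin(AR_MODES), "couple_id"])
    xl_matched = set(matches.loc[matches["matched"] & matches["mode"].isin(XL_MODES), "couple_id"])
    return {
        "ar_rrp": len(ar_matched) / denom,
        "xl_rrp": len(xl_matched) / denom,
        "total_rrp": len(ar_matched | xl_matched) / denom,
        "ar_matched": ar_matched,
        "xl_matched": xl_matched,
    }


# ---------------------------------------------------------------------------
# ECS sensitivity / undetected-risk accounting

def undetected_risk_accounting(
    couples: pd.DataFrame,
    children: pd.DataFrame,
    diagnoses: pd.DataFrame,
    at_risk: dict,
    profiles: pd.DataFrame,
    k: int = DEFAULT_K_MAX,
) -> dict:
    """Categorize every recessive/X-linked diagnosis by detectability.

    Matched couples are "detected"; inherited diagnoses whose causal
    variants fail the screen are filter false negatives; de novo
    hemizygous, compound het inherited+de novo and CNV-involving
    diagnoses are intrinsically undetectable.  Sensitivity is detected
    over detectable (detected + filter false negatives).
    """
    n_couples = len(couples)
    matches = match_diagnoses(couples, children, diagnoses, at_risk, profiles, k)
    detected = set(matches.loc[matches["matched"], "couple_id"])
    filtered = set(matches.loc[~matches["matched"], "couple_id"])
    categories = {"detected": detected, "filtered_inherited": filtered}
    for mode, cat in UNDETECTABLE_CATEGORIES.items():
        categories[cat] = set(children.loc[children["mode"] == mode, "couple_id"])
    table = pd.DataFrame(
        {
            "category": list(categories),
            "n_couples": [len(v) for v in categories.values()],
            "pct_of_couples": [100.0 * len(v) / n_couples for v in categories.values()],
        }
    )
    detectable = len(detected) + len(filtered)
    return {
        "table": table,
        "categories": categories,
        "n_detected": len(detected),
        "n_detectable": detectable,
        "sensitivity": len(detected) / detectable if detectable else float("nan"),
    }


# ---------------------------------------------------------------------------
# pragmatic screening policy

def policy_class(group_index, functional_class, gnomad_maf) -> str:
    """Screening-policy class of one qualifying variant.

    ``auto``: ClinVar P/LP with >= 1 star — assumed pathogenic outright;
    also unannotated truncating variants with MAF < 0.5%.
    ``manual``: zero-star or conflicting ClinVar records — rare enough to
    be assessed manually, retained after assessment.
    ``conditional``: non-ClinVar missense / protein-length / splice calls
    — assessed only when the partner carries an auto/manual variant in the
    same gene.  ``fail``: everything else.
    """
    if group_index is None or (isinstance(group_index, float) and np.isnan(group_index)):
        return "fail"
    g = int(group_index)
    if g in (1, 2, 3):
        return "auto"
    if g in (4, 5, 6, 7, 8, 9):
        return "manual"
    if g in (10, 13) or functional_class in TRUNCATING_CLASSES:
        return "auto" if (gnomad_maf is None or np.isnan(gnomad_maf) or gnomad_maf < POLICY_TRUNCATING_MAF) else "fail"
    if g in (11, 12, 14, 15, 16):
        return "conditional"
    return "fail"


def pragmatic_policy(
    couples: pd.DataFrame,
    profiles: pd.DataFrame,
    xl_genes: set,
    k: int = DEFAULT_K_MAX,
) -> dict[str, AtRiskCouple]:
    """Recompute at-risk couples under the pragmatic screening policy.

    A gene keeps a couple at risk when both partners hold an auto/manual
    qualifying variant, or one partner's auto/manual variant triggers
    assessment of the other partner's conditional variant.  Couples whose
    at-risk status relied on both partners' in-silico missense modelling
    without such a trigger are dropped.  The hypomorphic-only exclusion
    still applies.
    """
    qual = _qualifying(profiles, k).copy()
    qual["policy"] = [
        policy_class(g, fc, maf)
        for g, fc, maf in zip(qual["group_index"], qual["functional_class"], qual["gnomad_maf"])
    ]
    qual = qual.loc[qual["policy"] != "fail"]
    carriers = _gene_variant_policy_map(qual)
    result: dict[str, AtRiskCouple] = {}
    for row in couples.itertuples(index=False):
        mother = carriers.get(row.mother_id, {})
        father = carriers.get(row.father_id, {})
        ar = set()
        for gene in set(mother) & set(father):
            if gene in xl_genes:
                continue
            # both partners carry something; at least one side must be firm
            # (auto/manual) to trigger assessment of a conditional partner
            m_firm = any(p != "conditional" for p, _ in mother[gene])
            f_firm = any(p != "conditional" for p, _ in father[gene])
            if not (m_firm or f_firm):
                continue
            both_hypo = all(h for _, h in mother[gene]) and all(h for _, h in father[gene])
            if not both_hypo:
                ar.add(gene)
        xl = {
            g for g in mother
            if g in xl_genes
            and any(p != "conditional" for p, _ in mother[g])
            and not all(h for _, h in mother[g])
        }
        result[row.couple_id] = AtRiskCouple(row.couple_id, ar, xl)
    return result


def _gene_variant_policy_map(qual: pd.DataFrame) -> dict:
    out: dict = {}
    for row in qual.itertuples(index=False):
        out.setdefault(row.sample_id, {}).setdefault(row.gene, []).append(
            (row.policy, bool(row.hypomorphic))
        )
    return out


# ---------------------------------------------------------------------------
# tier stratification

def tier_metrics(
    couples: pd.DataFrame,
    children: pd.DataFrame,
    diagnoses: pd.DataFrame,
    profiles: pd.DataFrame,
    xl_genes: set,
    tier_sets: dict,
    strata: dict,
    k: int = DEFAULT_K_MAX,
) -> pd.DataFrame:
    """At-risk frequency and RRP per tier and consanguinity stratum.

    ``tier_sets`` maps tier -> cumulative gene set (nested); ``strata``
    maps stratum name -> couple-id list.  Metrics on a tier are computed on
    the tier-restricted gene universe, so nesting of the tiers implies
    monotone metrics.
    """
    at_risk_full = find_at_risk_couples(couples, profiles, xl_genes, k)
    rows = []
    for tier in sorted(tier_sets):
        genes = tier_sets[tier]
        restricted = {
            cid: AtRiskCouple(cid, risk.ar_genes & genes, risk.xl_genes & genes)
            for cid, risk in at_risk_full.items()
        }
        for name, ids in strata.items():
            ids = list(ids)
            freq = at_risk_frequency(restricted, ids)
            rrp = risk_reduction_potential(
                couples, children, diagnoses, restricted, profiles, k,
                panel=genes, couple_ids=ids,
            )
            rows.append((tier, name, freq, rrp["total_rrp"], rrp["ar_rrp"], rrp["xl_rrp"]))
    return pd.DataFrame(
        rows, columns=["tier", "stratum", "at_risk_freq", "total_rrp", "ar_rrp", "xl_rrp"]
    )


# ---------------------------------------------------------------------------
# statistics

def fisher_test(table) -> dict:
    """Two-tailed Fisher's exact test on a 2x2 count table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher test needs a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        logger.warning("degenerate margin in contingency table")
        return {"odds_ratio": float("nan"), "p_value": float("nan")}
    odds, p = fisher_exact(arr, alternative="two-sided")
    return {"odds_ratio": float(odds), "p_value": float(p)}


def welch_test(x, y) -> dict:
    """Welch's unequal-variance t-test on two numeric vectors."""
    t, p = ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    if np.isnan(t):  # zero variance in both and equal means
        x, y = np.asarray(x, float), np.asarray(y, float)
        if np.allclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0
    return {"t": float(t), "p_value": float(p)}


# ---------------------------------------------------------------------------
# threshold sweep

def threshold_sweep(
    couples: pd.DataFrame,
    children: pd.DataFrame,
    diagnoses: pd.DataFrame,
    profiles: pd.DataFrame,
    individuals,
    xl_genes: set,
    ks=range(1, DEFAULT_K_MAX + 1),
) -> pd.DataFrame:
    """Cohort metrics as a function of the cumulative threshold k (tidy table)."""
    rows = []
    n = len(list(individuals))
    for k in ks:
        metrics = cumulative_carrier_metrics(profiles, individuals, k)
        at_risk = find_at_risk_couples(couples, profiles, xl_genes, k)
        rrp = risk_reduction_potential(couples, children, diagnoses, at_risk, profiles, k)
        cf = carrier_frequency_table(profiles, n, k)
        ar_counts = {g: int(round(f * n)) for g, f in cf.items() if g not in xl_genes}
        xl_counts = {g: int(round(f * n)) for g, f in cf.items() if g in xl_genes}
        virtual = estimate_virtual_at_risk(ar_counts, xl_counts, n)
        rows.append(
            {
                "k": k,
                "total_carrier_frequency": metrics["total_carrier_frequency"],
                "frac_ge1": metrics["frac_ge1"],
                "median_variants": metrics["median_variants"],
                "n_at_risk_couples": sum(r.at_risk for r in at_risk.values()),
                "n_ar_at_risk": sum(bool(r.ar_genes) for r in at_risk.values()),
                "n_xl_at_risk": sum(bool(r.xl_genes) for r in at_risk.values()),
                "at_risk_freq": at_risk_frequency(at_risk),
                "ar_rrp": rrp["ar_rrp"],
                "xl_rrp": rrp["xl_rrp"],
                "total_rrp": rrp["total_rrp"],
                "virtual_ar_rate": virtual["ar_rate"],
                "virtual_xl_rate": virtual["xl_rate"],
            }
        )
    return pd.DataFrame(rows)
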