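"""End-to-end cohort analysis: QC -> classification -> couple metrics.

:func:`analyze_cohort` runs the full screen on an in-memory bundle and
returns a :class:`CohortResult`; :func:`run_pipeline` is the disk-to-disk
driver behind the command line (bundle directory in, tidy TSV/JSON plus a
markdown report out).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import couples as cp
from .bundle import CohortBundle
from .catalog import assign_tiers, ndd_genes, tier_gene_sets, x_linked_genes
from .classify import (
    DEFAULT_K_MAX,
    ZERO_STAR_GROUPS,
    classify_fmr1_repeat,
    classify_variants,
    mark_hypomorphic,
)
from .qc import apply_qc, rare_missense_gate
from .roh import couple_consanguinity, f_roh_profiles
from .smn1 import call_carriers

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "sample_id", "gene", "variant_key", "group_index", "hypomorphic",
    "zygosity", "functional_class", "gnomad_maf",
]


def build_profiles(bundle: CohortBundle) -> pd.DataFrame:
    """QC + classification: the per-individual carrier profile table."""
    qc = apply_qc(bundle.calls, bundle.annotations, n_samples=bundle.n_individuals)
    retained = qc.retained.copy()
    retained["missense_eligible"] = rare_missense_gate(retained)
    classified = classify_variants(retained)
    classified = mark_hypomorphic(classified, bundle.registry)
    profiles = classified.loc[classified["group_index"].notna(), PROFILE_COLUMNS]
    return profiles.reset_index(drop=True)


@dataclass
class CohortResult:
    """All cohort-level outputs at one classification threshold."""

    k: int
    n_individuals: int
    n_couples: int
    carrier_metrics: dict
    carrier_freqs: pd.Series
    strata: dict                      # stratum -> list of couple ids
    at_risk: dict                     # couple_id -> AtRiskCouple
    at_risk_policy: dict
    virtual: dict
    rrp: dict
    rrp_no_zero_star: dict
    undetected: dict
    tier_table: pd.DataFrame
    smn1_calls: pd.DataFrame
    fmr1_classes: pd.Series
    sweep: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    # -- headline percentages (printed style, one decimal) ----------------
    def _stratum_freq(self, at_risk, stratum) -> float:
        ids = self.strata.get(stratum, [])
        return cp.at_risk_frequency(at_risk, ids) if ids else 0.0

    def summary(self) -> dict:
        smn_carriers = int(self.smn1_calls["potential_carrier"].sum())
        n_mothers = int((self.fmr1_classes.index.size))
        n_premut = int((self.fmr1_classes == "premutation").sum())
        # share of consanguineous couples among autosomal at-risk couples
        at_risk_ids = {c for c, r in self.at_risk.items() if r.ar_genes}
        cons = set(self.strata.get("consanguineous", []))
        tier4 = self.tier_table.loc[self.tier_table["tier"] == 4].set_index("stratum")
        return {
            "frac_ge1_pct": round(100 * self.carrier_metrics["frac_ge1"], 1),
            "median_variants_per_individual": self.carrier_metrics["median_variants"],
            "max_variants_per_individual": self.carrier_metrics["max_variants"],
            "ar_rrp_pct": round(100 * self.rrp["ar_rrp"], 1),
            "xl_rrp_pct": round(100 * self.rrp["xl_rrp"], 1),
            "total_rrp_pct": round(100 * self.rrp["total_rrp"], 1),
            "total_rrp_no_zero_star_pct": round(100 * self.rrp_no_zero_star["total_rrp"], 1),
            "ecs_sensitivity_pct": round(100 * self.undetected["sensitivity"], 1),
            "consanguineous_at_risk_pct": round(
                100 * self._stratum_freq(self.at_risk, "consanguineous"), 1),
            "consanguineous_at_risk_policy_pct": round(
                100 * self._stratum_freq(self.at_risk_policy, "consanguineous"), 1),
            "nonconsanguineous_at_risk_pct": round(
                100 * self._stratum_freq(self.at_risk, "nonconsanguineous"), 1),
            "nonconsanguineous_at_risk_policy_pct": round(
                100 * self._stratum_freq(self.at_risk_policy, "nonconsanguineous"), 1),
            "at_risk_consanguinity_share_pct": round(
                100 * len(at_risk_ids & cons) / len(at_risk_ids), 1) if at_risk_ids else 0.0,
            "tier4_rrp_consanguineous_pct": round(
                100 * tier4.loc["consanguineous", "total_rrp"], 1),
            "tier4_rrp_nonconsanguineous_pct": round(
                100 * tier4.loc["nonconsanguineous", "total_rrp"], 1),
            "filter_false_negative_pct": round(
                100 * (self.undetected["n_detectable"] - self.undetected["n_detected"])
                / self.n_couples, 1),
            "smn1_reciprocal_carrier_freq": round(self.n_individuals / smn_carriers)
            if smn_carriers else None,
            "fmr1_reciprocal_carrier_freq": round(n_mothers / n_premut) if n_premut else None,
        }


def analyze_cohort(
    bundle: CohortBundle,
    k: int = DEFAULT_K_MAX,
    seed: int = 0,
    with_sweep: bool = False,
) -> CohortResult:
    profiles = build_profiles(bundle)
    individuals = list(bundle.individuals["sample_id"])
    n = len(individuals)
    xl = x_linked_genes(bundle.catalog)

    carrier_metrics = cp.cumulative_carrier_metrics(profiles, individuals, k)
    carrier_freqs = cp.carrier_frequency_table(profiles, n, k)

    # consanguinity strata from the children's ROH profiles
    roh_profiles = f_roh_profiles(bundle.roh)
    child_f = dict(zip(roh_profiles["sample_id"], roh_profiles["f_roh"]))
    status = couple_consanguinity(bundle.couples, child_f)
    strata = {
        name: list(bundle.couples.loc[status == name, "couple_id"])
        for name in ("consanguineous", "nonconsanguineous", "uncertain")
    }

    at_risk = cp.find_at_risk_couples(bundle.couples, profiles, xl, k)
    at_risk_policy = cp.pragmatic_policy(bundle.couples, profiles, xl, k)

    carrier_counts = (carrier_freqs * n).round().astype(int)
    virtual = cp.estimate_virtual_at_risk(
        {g: c for g, c in carrier_counts.items() if g not in xl},
        {g: c for g, c in carrier_counts.items() if g in xl},
        n,
    )

    rrp = cp.risk_reduction_potential(
        bundle.couples, bundle.children, bundle.diagnoses, at_risk, profiles, k)
    at_risk_nz = cp.find_at_risk_couples(
        bundle.couples, profiles, xl, k, exclude_groups=ZERO_STAR_GROUPS)
    rrp_no_zero_star = cp.risk_reduction_potential(
        bundle.couples, bundle.children, bundle.diagnoses, at_risk_nz, profiles, k,
        exclude_groups=ZERO_STAR_GROUPS)
    undetected = cp.undetected_risk_accounting(
        bundle.couples, bundle.children, bundle.diagnoses, at_risk, profiles, k)

    tiers = assign_tiers(bundle.catalog, dict(carrier_freqs))
    tier_table = cp.tier_metrics(
        bundle.couples, bundle.children, bundle.diagnoses, profiles, xl,
        tier_gene_sets(tiers), strata, k)

    smn1_calls = call_carriers(bundle.smn1)
    fmr1 = bundle.fmr1.set_index("sample_id")["cgg"].map(classify_fmr1_repeat)

    sweep = None
    if with_sweep:
        sweep = cp.threshold_sweep(
            bundle.couples, bundle.children, bundle.diagnoses, profiles,
            individuals, xl, ks=range(1, k + 1))

    return CohortResult(
        k=k, n_individuals=n, n_couples=bundle.n_couples,
        carrier_metrics=carrier_metrics, carrier_freqs=carrier_freqs,
        strata=strata, at_risk=at_risk, at_risk_policy=at_risk_policy,
        virtual=virtual, rrp=rrp, rrp_no_zero_star=rrp_no_zero_star,
        undetected=undetected, tier_table=tier_table,
        smn1_calls=smn1_calls, fmr1_classes=fmr1, sweep=sweep,
        extras={"profiles": profiles, "roh_profiles": roh_profiles,
                "ndd_genes": ndd_genes(bundle.catalog)},
    )


def run_pipeline(bundle_dir, out_dir, k: int = DEFAULT_K_MAX, seed: int = 0) -> CohortResult:
    """Disk-to-disk driver: read a bundle directory, write results + report."""
    from .io import read_bundle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = read_bundle(bundle_dir)
    result = analyze_cohort(bundle, k=k, seed=seed, with_sweep=True)

    result.carrier_freqs.rename("carrier_frequency").to_csv(out / "carrier_frequencies.tsv", sep="\t")
    result.sweep.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
    result.tier_table.to_csv(out / "tier_metrics.tsv", sep="\t", index=False)
    result.undetected["table"].to_csv(out / "undetected_risk.tsv", sep="\t", index=False)
    result.smn1_calls.to_csv(out / "smn1_calls.tsv", sep="\t", index=False)
    summary = result.summary()
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    lines = [
        "# Carrier screening report",
        "",
        f"Cohort: {result.n_individuals} individuals, {result.n_couples} couples; "
        f"threshold k = {result.k}.",
        "",
        "## Headline metrics",
        "",
    ]
    lines += [f"- {key}: {value}" for key, value in summary.items()]
    lines += ["", "## Threshold sweep", "", result.sweep.to_markdown(index=False)]
    lines += ["", "## Tier metrics", "", result.tier_table.to_markdown(index=False)]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    logger.info("pipeline outputs written to %s", out)
    return result
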