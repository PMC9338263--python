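"""Synthetic cohort generation with known ground truth.

The generator emulates the statistical structure the analysis assumes:
Hardy-Weinberg carrier genotypes with per-gene pathogenic allele
frequencies q_g (log-uniform spectrum by default), elevated allele sharing
in consanguineous couples (a partner acquires the other's allele with
probability proportional to the child's target autozygosity), Mendelian
transmission to children plus de novo events at the stratum-specific
diagnosis rates reported for neurodevelopmental disorders (about 50% de
novo dominant in outbred couples, recessive inherited diagnoses dominating
in consanguineous ones), annotation attributes drawn from a configurable
archetype distribution, binomial SMN1/SMN2 read counts, and ROH segments
realizing each child's target F.

Ground truth (carrier status, at-risk couples, diagnoses) is recorded
exactly, so pipeline recovery can be asserted without tolerance for the
deterministic steps and within binomial error for sampled quantities.
No sequence-level realism is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import couples as cp
from .bundle import CohortBundle
from .catalog import DatabaseGeneEntry, apply_curation_overrides, merge_gene_databases
from .classify import HypomorphicRegistry
from .fixture import _KINDS, _roh_segments
from .qc import variant_key

#: annotation archetypes for true-pathogenic variants, with sampling weights
PATHOGENIC_KINDS = {
    "cv_plp_dm": 0.40,
    "cv_plp_nonhgmd": 0.20,
    "conf75_dm": 0.10,
    "cv_plp_dm_zero": 0.10,
    "noncv_trunc": 0.15,
    "noncv_hs_missense": 0.05,
}

_BENIGN_KINDS = {
    "noncv_fail_missense": (False, "none", 0, np.nan, "none", 1e-3, 0, "missense",
                            0.30, 8.0, 1, 8),
    "noncv_syn": (False, "none", 0, np.nan, "none", 1e-3, 0, "synonymous",
                  np.nan, np.nan, np.nan, np.nan),
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort (seed is mandatory)."""

    seed: int
    n_couples: int = 350
    n_genes: int = 120
    n_xl_genes: int = 10
    ndd_fraction: float = 0.33
    q_min: float = 5e-4          # log-uniform pathogenic allele frequency range
    q_max: float = 0.02
    frac_consanguineous: float = 23 / 350
    frac_uncertain: float = 34 / 350
    consanguineous_child_f: tuple = (0.0625, 0.125)
    uncertain_child_f: float = 0.03
    share_scale: float = 4.0     # P(partner shares allele) = share_scale * child F
    dn_dominant_rate_noncons: float = 0.50
    dn_dominant_rate_cons: float = 0.06
    benign_calls_per_individual: float = 1.0
    pathogenic_kind_weights: dict = field(default_factory=lambda: dict(PATHOGENIC_KINDS))
    smn1_depth: float = 100.0
    smn1_state_freqs: dict = field(
        default_factory=lambda: {(1, 2): 1 / 54, (2, 1): 0.04, (3, 2): 0.03}
    )
    fmr1_premutation_freq: float = 1 / 175

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("frac_consanguineous", "frac_uncertain", "fmr1_premutation_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of [0, 1]")
        if self.frac_consanguineous + self.frac_uncertain > 1:
            raise ValueError("consanguineous + uncertain fractions exceed 1")


def simulate_smn1_reads(copy_states, depth, seed=None, rng=None) -> pd.DataFrame:
    """Binomial SMN read counts for a list of (sample_id, run_id, c1, c2).

    Per position, the total SMN read count is Poisson with mean
    depth * (c1 + c2) / 4 and the SMN1 share is binomial with success
    probability c1 / (c1 + c2); 20 control genes are Poisson around
    5 * depth each.  A 0+0 state yields zero SMN reads.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    states = list(copy_states)
    c1 = np.array([s[2] for s in states], float)
    c2 = np.array([s[3] for s in states], float)
    total = c1 + c2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(total > 0, c1 / np.where(total > 0, total, 1.0), 0.0)
    df = pd.DataFrame({"sample_id": [s[0] for s in states],
                       "run_id": [s[1] for s in states]})
    for j in range(1, 4):
        tot = rng.poisson(depth * total / 4.0)
        s1 = rng.binomial(tot, p1)
        df[f"smn1_r{j}"] = s1
        df[f"smn2_r{j}"] = tot - s1
    for j in range(1, 21):
        df[f"ctrl_{j:02d}"] = rng.poisson(5.0 * depth, len(states))
    return df


def _sample_kind(rng, weights: dict) -> str:
    names = sorted(weights)
    p = np.array([weights[n] for n in names], float)
    return names[rng.choice(len(names), p=p / p.sum())]


def _annotation_row(gene, chrom, pos, kind) -> dict:
    spec = _KINDS.get(kind, _BENIGN_KINDS.get(kind))
    (in_cv, cls, stars, plp, hgmd, maf, homhemi, fc, vip, cadd, ndel, npred) = spec
    return dict(
        chrom=chrom, pos=pos, ref="A", alt="T", gene=gene, in_clinvar=in_cv,
        clinvar_class=cls, clinvar_stars=stars, plp_entry_fraction=plp,
        hgmd_class=hgmd, gnomad_maf=maf, gnomad_homhemi=homhemi,
        functional_class=fc, homology_region=False, vipur=vip, cadd=cadd,
        n_deleterious=ndel, n_predictors=npred,
    )


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    rng = np.random.default_rng(config.seed)
    nc = config.n_couples
    mothers = [f"s{i:05d}f" for i in range(1, nc + 1)]
    fathers = [f"s{i:05d}m" for i in range(1, nc + 1)]
    couple_ids = [f"s{i:05d}" for i in range(1, nc + 1)]
    children_ids = [f"k{i:05d}" for i in range(1, nc + 1)]

    # gene universe with log-uniform pathogenic allele frequencies
    ar_genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    xl_genes = [f"X{i:03d}" for i in range(1, config.n_xl_genes + 1)]
    genes = ar_genes + xl_genes
    q = np.exp(rng.uniform(np.log(config.q_min), np.log(config.q_max), len(genes)))
    n_ndd = int(round(config.ndd_fraction * len(genes)))
    ndd = set(rng.choice(genes, size=n_ndd, replace=False)) if n_ndd else set()

    ann_rows, key_of = [], {}
    for gi, gene in enumerate(genes):
        chrom = "X" if gene in xl_genes else str(1 + gi % 22)
        pos = 1_000_000 + gi * 1_000
        kind = _sample_kind(rng, config.pathogenic_kind_weights)
        ann_rows.append(_annotation_row(gene, chrom, pos, kind))
        key_of[gene] = (chrom, pos, "A", "T")

    is_xl = np.array([g in xl_genes for g in genes])
    # maternal/paternal copy counts under Hardy-Weinberg
    g_m = rng.binomial(2, q, size=(nc, len(genes)))
    g_f = rng.binomial(np.where(is_xl, 1, 2), q, size=(nc, len(genes)))

    # consanguinity strata and child target F
    n_cons = int(round(config.frac_consanguineous * nc))
    n_unc = int(round(config.frac_uncertain * nc))
    strata = (["consanguineous"] * n_cons + ["uncertain"] * n_unc
              + ["nonconsanguineous"] * (nc - n_cons - n_unc))
    child_f = np.where(
        np.array(strata) == "consanguineous",
        rng.uniform(*config.consanguineous_child_f, size=nc),
        np.where(np.array(strata) == "uncertain", config.uncertain_child_f, 0.0),
    )
    # shared ancestry: a consanguineous father acquires each maternal
    # autosomal carrier allele with probability ~ share_scale * F
    p_share = np.clip(config.share_scale * child_f, 0, 1)[:, None]
    share = (rng.random((nc, len(genes))) < p_share) & (g_m >= 1) & ~is_xl[None, :]
    g_f = np.where(share & (g_f == 0), 1, g_f)

    # Mendelian transmission (one variant per gene: two copies => homozygous)
    child_sex = np.where(rng.random(nc) < 0.5, "M", "F")
    t_m = rng.binomial(1, g_m / 2.0)
    t_f = rng.binomial(1, np.where(is_xl[None, :], g_f, g_f / 2.0) * 1.0
                       * np.where(is_xl[None, :], (child_sex == "F")[:, None], True))
    child_copies = t_m + np.where(is_xl[None, :], np.where((child_sex == "F")[:, None], t_f, 0), t_f)

    # variant calls for all carrier parents
    calls = []
    for samples, g_mat, parent_is_female in ((mothers, g_m, True), (fathers, g_f, False)):
        rows, cols = np.nonzero(g_mat)
        for r, c in zip(rows, cols):
            gene = genes[c]
            chrom, pos, ref, alt = key_of[gene]
            if gene in xl_genes and not parent_is_female:
                zyg = "hemi"
            else:
                zyg = "hom" if g_mat[r, c] == 2 else "het"
            calls.append(dict(
                sample_id=samples[r], gene=gene, chrom=chrom, pos=pos, ref=ref,
                alt=alt, zygosity=zyg, quality=50.0,
                alt_fraction=1.0 if zyg in ("hom", "hemi") else 0.5,
                forward_fraction=0.5,
            ))

    # benign noise calls, dropped by QC/classification
    n_benign = rng.poisson(config.benign_calls_per_individual, 2 * nc)
    all_parents = mothers + fathers
    benign_serial = 0
    for si, nb in enumerate(n_benign):
        for _ in range(nb):
            benign_serial += 1
            kind = "noncv_fail_missense" if rng.random() < 0.5 else "noncv_syn"
            gene = genes[int(rng.integers(len(genes)))]
            chrom = key_of[gene][0]
            pos = 90_000_000 + benign_serial
            ann_rows.append(_annotation_row(gene, chrom, pos, kind))
            calls.append(dict(
                sample_id=all_parents[si], gene=gene, chrom=chrom, pos=pos,
                ref="A", alt="T", zygosity="het", quality=50.0,
                alt_fraction=0.5, forward_fraction=0.5,
            ))

    # diagnoses: recessive/X-linked inherited where the child genotype
    # demands it, de novo dominant otherwise at the stratum rate
    children_modes: dict[int, str | None] = {}
    dx_rows = []
    truth_diagnosed = {}
    for i in range(nc):
        mode = None
        hom_genes = [genes[c] for c in np.nonzero((child_copies[i] == 2) & ~is_xl)[0]
                     if genes[c] in ndd]
        xl_hit = [genes[c] for c in np.nonzero((t_m[i] == 1) & is_xl)[0]
                  if genes[c] in ndd and child_sex[i] == "M"]
        if hom_genes:
            gene = hom_genes[0]
            key = variant_key(*key_of[gene])
            mode = cp.AR_HOM
            dx_rows.append(dict(couple_id=couple_ids[i], gene=gene,
                                variant_key=key, origin="maternal", is_cnv=False))
            dx_rows.append(dict(couple_id=couple_ids[i], gene=gene,
                                variant_key=key, origin="paternal", is_cnv=False))
        elif xl_hit:
            gene = xl_hit[0]
            mode = cp.XL_INHERITED
            dx_rows.append(dict(couple_id=couple_ids[i], gene=gene,
                                variant_key=variant_key(*key_of[gene]),
                                origin="maternal", is_cnv=False))
        else:
            rate = (config.dn_dominant_rate_cons if strata[i] == "consanguineous"
                    else config.dn_dominant_rate_noncons)
            if rng.random() < rate:
                mode = cp.AD_DENOVO
                dx_rows.append(dict(couple_id=couple_ids[i], gene=f"DN{i:05d}",
                                    variant_key=f"dn:{couple_ids[i]}",
                                    origin="denovo", is_cnv=False))
        children_modes[i] = mode
        if mode:
            truth_diagnosed[couple_ids[i]] = mode

    # ground-truth at-risk couples from genotypes
    ar_truth = {
        couple_ids[i]
        for i in range(nc)
        if np.any((g_m[i] >= 1) & (g_f[i] >= 1) & ~is_xl)
    }
    xl_truth = {couple_ids[i] for i in range(nc) if np.any((g_m[i] >= 1) & is_xl)}

    # ROH, SMN1, FMR1 side tables
    roh_rows = []
    for i in range(nc):
        f = float(child_f[i]) if child_f[i] > 0 else None
        roh_rows.extend(_roh_segments(children_ids[i], f))
    roh_df = pd.DataFrame(roh_rows, columns=["sample_id", "chrom", "start", "end"])

    states, state_truth = [], {}
    state_names = list(config.smn1_state_freqs)
    state_p = np.array([config.smn1_state_freqs[s] for s in state_names])
    for idx, sample in enumerate(all_parents):
        u = rng.random()
        acc = 0.0
        c1, c2 = 2, 2
        for sname, sp in zip(state_names, state_p):
            acc += sp
            if u < acc:
                c1, c2 = sname
                break
        states.append((sample, f"run{idx // 100}", c1, c2))
        state_truth[sample] = (c1, c2)
    smn_df = simulate_smn1_reads(states, config.smn1_depth, rng=rng)

    premut = rng.random(nc) < config.fmr1_premutation_freq
    fmr1_df = pd.DataFrame({
        "sample_id": mothers,
        "cgg": np.where(premut, 80, 30),
    })

    # catalog
    entries = []
    for gene in genes:
        inh = "XL" if gene in xl_genes else "AR"
        entries.append(DatabaseGeneEntry(gene, "OMIM", inh))
    catalog = apply_curation_overrides(merge_gene_databases(entries), ndd_genes=ndd)

    couples_df = pd.DataFrame({
        "couple_id": couple_ids, "mother_id": mothers, "father_id": fathers,
        "child_id": children_ids, "consanguinity": strata,
    })
    children_df = pd.DataFrame({
        "couple_id": couple_ids, "child_id": children_ids, "sex": child_sex,
        "mode": [children_modes[i] for i in range(nc)],
    })
    diagnoses_df = pd.DataFrame(
        dx_rows, columns=["couple_id", "gene", "variant_key", "origin", "is_cnv"])
    individuals_df = pd.DataFrame({
        "sample_id": all_parents,
        "sex": ["F"] * nc + ["M"] * nc,
    })

    truth = {
        "q": dict(zip(genes, q)),
        "ar_at_risk": ar_truth,
        "xl_at_risk": xl_truth,
        "diagnosed": truth_diagnosed,
        "smn1_states": state_truth,
        "child_f": dict(zip(children_ids, child_f)),
        "carrier_mothers": {mothers[i]: [genes[c] for c in np.nonzero(g_m[i])[0]]
                            for i in range(nc)},
        "carrier_fathers": {fathers[i]: [genes[c] for c in np.nonzero(g_f[i])[0]]
                            for i in range(nc)},
    }

    return CohortBundle(
        catalog=catalog, individuals=individuals_df,
        calls=pd.DataFrame(calls), annotations=pd.DataFrame(ann_rows),
        couples=couples_df, children=children_df, diagnoses=diagnoses_df,
        roh=roh_df, smn1=smn_df, fmr1=fmr1_df,
        registry=HypomorphicRegistry(), truth=truth,
    )
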