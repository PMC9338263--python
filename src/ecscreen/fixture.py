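"""Deterministic reference cohort (700 parents / 350 trios).

Builds, without any RNG, a complete :class:`~ecscreen.bundle.CohortBundle`
whose structure mirrors the evaluated NDD-trio cohort: 23 consanguineous,
293 nonconsanguineous and 34 uncertain couples; 52 autosomal-recessive
at-risk couples (13 consanguineous) and 20 X-linked carrier mothers at the
default threshold k = 14; 19 matched autosomal and 8 matched X-linked
transmissions (10 in consanguineous, 15 in nonconsanguineous and 2 in
uncertain couples); 4 matches that depend on zero-review-star ClinVar
variants (CRADD, DPYS, TRAPPC9, UFC1); 16 couples whose inherited causal
variants fail the screen (17 filtered missense variants); 2 de novo
hemizygous, 3 compound-het inherited+de novo and 3 CNV-involving
diagnoses; 675 of 700 individuals with >= 1 qualifying variant (median 4
per individual, range 0-12); 2 FMR1 premutation mothers; 13 SMN1
carriers; and 1 consanguineous plus 1 nonconsanguineous at-risk couple
whose status rests solely on in-silico missense modelling.

Counts that are only implied by published percentages are back-solved from
the percentage and its denominator and asserted in the test suite; every
percentage the analysis prints follows from the construction, never from a
lookup.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import couples as cp
from .bundle import CohortBundle
from .catalog import (
    DatabaseGeneEntry,
    apply_curation_overrides,
    merge_gene_databases,
)
from .classify import HypomorphicRegistry
from .qc import variant_key

N_COUPLES = 350
CONS = list(range(1, 24))           # 23 consanguineous couples
NONCONS = list(range(24, 317))      # 293 nonconsanguineous couples
UNCERTAIN = list(range(317, 351))   # 34 couples of uncertain relatedness

ZERO_STAR_GENES = ("CRADD", "DPYS", "TRAPPC9", "UFC1")
NON_CAPTURABLE = ("FMR1", "SMN1", "GBA", "HBA1", "HBA2", "CYP21A2")

HFE_SHARED_COUPLES = list(range(130, 157))   # 27 couples, both partners hypomorphic-only
HFE_SINGLE_MOTHERS = list(range(160, 297))   # 137 extra carriers -> 191 total (27.3%)
AD_DENOVO_COUPLES = list(range(200, 295))    # 95 de novo dominant diagnoses
FMR1_PREMUTATION = {157: 67, 158: 134}       # couple -> maternal CGG repeats
SMN1_CARRIER_SAMPLES = tuple(
    [f"p{i:03d}m" for i in range(15, 22)] + [f"p{i:03d}f" for i in range(230, 236)]
)  # 13 carriers -> 1/54

# per-individual qualifying-variant count distribution: 25 zeros (=> 675 with
# >= 1, i.e. 96.4%), median 4, range 0-12
_COUNT_DISTRIBUTION = (
    (0, 25), (1, 75), (2, 100), (3, 120), (4, 155), (5, 120), (6, 60),
    (7, 25), (8, 10), (9, 5), (10, 3), (11, 1), (12, 1),
)

# annotation archetypes -> (in_clinvar, clinvar_class, stars, plp_fraction,
# hgmd, gnomad_maf, homhemi, functional_class, vipur, cadd, n_del, n_pred)
_KINDS = {
    "cv_plp_dm": (True, "P", 2, np.nan, "DM", 1e-4, 0, "truncating", np.nan, np.nan, np.nan, np.nan),
    "cv_plp_nonhgmd": (True, "LP", 1, np.nan, "none", 1e-4, 0, "missense", np.nan, np.nan, np.nan, np.nan),
    "conf75_dm": (True, "conflicting", 1, 0.90, "DM", 5e-4, 0, "missense", np.nan, np.nan, np.nan, np.nan),
    "cv_plp_dm_zero": (True, "P", 0, np.nan, "DM", 1e-4, 0, "truncating", np.nan, np.nan, np.nan, np.nan),
    "noncv_trunc": (False, "none", 0, np.nan, "none", 1e-3, 0, "truncating", np.nan, np.nan, np.nan, np.nan),
    "noncv_hs_missense": (False, "none", 0, np.nan, "none", 1e-3, 0, "missense", 0.92, 27.0, 8, 8),
    "noncv_fail_missense": (False, "none", 0, np.nan, "none", 1e-3, 0, "missense", 0.40, 12.0, 2, 8),
    "hfe_hypo": (True, "conflicting", 1, 0.80, "DM", 0.14, 50, "missense", np.nan, np.nan, np.nan, np.nan),
    "mmachc_conf": (True, "conflicting", 1, 17 / 18, "DM", 4e-3, 0, "truncating", np.nan, np.nan, np.nan, np.nan),
}
_QUALIFYING_KINDS = set(_KINDS) - {"noncv_fail_missense"}
_AT_RISK_KIND_CYCLE = ("cv_plp_dm", "cv_plp_nonhgmd", "conf75_dm", "noncv_trunc")
_FILLER_KIND_CYCLE = ("cv_plp_dm", "cv_plp_nonhgmd", "noncv_trunc", "conf75_dm")


def mother_id(i: int) -> str:
    return f"p{i:03d}f"


def father_id(i: int) -> str:
    return f"p{i:03d}m"


def couple_id(i: int) -> str:
    return f"p{i:03d}"


def child_id(i: int) -> str:
    return f"c{i:03d}"


class _Builder:
    def __init__(self):
        self.calls: list[dict] = []
        self.ann: dict[str, dict] = {}
        self.genes: dict[str, dict] = {}
        self._serial = 0

    def gene(self, name: str, inh: str = "AR", ndd: bool = False) -> None:
        if name in self.genes:
            return
        self._serial += 1
        chrom = "X" if inh == "XL" else str(1 + (self._serial % 22))
        self.genes[name] = {
            "chrom": chrom, "base": 1_000_000 * self._serial,
            "inh": inh, "ndd": ndd, "n_variants": 0,
        }

    def new_key(self, gene: str) -> tuple:
        g = self.genes[gene]
        g["n_variants"] += 1
        return (g["chrom"], g["base"] + g["n_variants"], "A", "T")

    def add_call(self, sample: str, gene: str, kind: str, key: tuple | None = None,
                 zygosity: str = "het", quality: float = 50.0, alt_fraction: float = 0.5,
                 forward_fraction: float = 0.5, homology: bool = False) -> str:
        if key is None:
            key = self.new_key(gene)
        chrom, pos, ref, alt = key
        kstr = variant_key(chrom, pos, ref, alt)
        if kstr not in self.ann:
            (in_cv, cls, stars, plp, hgmd, maf, homhemi, fc, vip, cadd, ndel, npred) = _KINDS[kind]
            self.ann[kstr] = dict(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                in_clinvar=in_cv, clinvar_class=cls, clinvar_stars=stars,
                plp_entry_fraction=plp, hgmd_class=hgmd, gnomad_maf=maf,
                gnomad_homhemi=homhemi, functional_class=fc,
                homology_region=homology, vipur=vip, cadd=cadd,
                n_deleterious=ndel, n_predictors=npred,
            )
        survives_qc = (
            quality >= 12 and 0.28 <= alt_fraction and 0.2 <= forward_fraction <= 0.8
            and not homology
        )
        self.calls.append(dict(
            sample_id=sample, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
            zygosity=zygosity, quality=quality, alt_fraction=alt_fraction,
            forward_fraction=forward_fraction,
            _qualifies=(kind in _QUALIFYING_KINDS) and survives_qc,
        ))
        return kstr

    def add_shared(self, i: int, gene: str, kind: str) -> str:
        """Same variant in both partners of couple i (founder/IBD allele)."""
        key = self.new_key(gene)
        kstr = self.add_call(mother_id(i), gene, kind, key=key)
        self.add_call(father_id(i), gene, kind, key=key)
        return kstr

    def add_pair(self, i: int, gene: str, kind_m: str, kind_f: str) -> tuple[str, str]:
        """Distinct variants in the two partners of couple i (same gene)."""
        km = self.add_call(mother_id(i), gene, kind_m)
        kf = self.add_call(father_id(i), gene, kind_f)
        return km, kf


def _roh_segments(sample: str, f_target: float | None) -> list[tuple]:
    """Deterministic ROH segments for one child.

    ``f_target`` None emulates an outbred child: two sub-threshold runs and
    one 6.1 Mb run (F ~= 0.0023).  Otherwise segments of <= 60 Mb summing
    exactly to f_target * 2691 Mb are laid out over successive autosomes.
    """
    segs = [(sample, "1", 500_000, 3_500_000), (sample, "2", 500_000, 3_500_000)]
    if f_target is None:
        segs.append((sample, "3", 10_000_000, 16_100_000))
        return segs
    remaining = round(f_target * 2_691_000_000)
    chrom = 3
    while remaining > 0:
        piece = min(remaining, 60_000_000)
        if 0 < remaining - piece <= 5_000_000:  # keep every chunk above threshold
            piece = remaining - 5_000_001
        segs.append((sample, str(chrom), 10_000_000, 10_000_000 + piece))
        remaining -= piece
        chrom = 3 + (chrom - 2) % 20
    return segs


def _smn1_counts(sample: str, run_id: str, c1: int, c2: int) -> dict:
    """Noiseless SMN read counts proportional to the (c1, c2) copy state."""
    row = {"sample_id": sample, "run_id": run_id}
    for j in range(1, 4):
        row[f"smn1_r{j}"] = 24 * c1
        row[f"smn2_r{j}"] = 24 * c2
    for j in range(1, 21):
        row[f"ctrl_{j:02d}"] = 500
    return row


def paper_counts_fixture() -> CohortBundle:
    b = _Builder()

    # ---- gene universe -------------------------------------------------
    for g in ZERO_STAR_GENES:
        b.gene(g, ndd=True)
    b.gene("MMACHC", ndd=True)
    b.gene("MECP2", inh="XL", ndd=True)
    b.gene("HFE")
    for g in ("CFTR", "GBA", "HBA1", "HBA2", "CYP21A2"):
        b.gene(g)
    b.gene("SMN1")
    b.gene("FMR1", inh="XL", ndd=True)

    # ---- AR at-risk couples (52 = 13 consanguineous + 37 noncons + 2 uncertain)
    truth_ar_at_risk, truth_ar_matched = set(), set()
    diagnoses_rows, children_modes = [], {}

    def _dx(i, gene, key, origin, is_cnv=False):
        diagnoses_rows.append(dict(couple_id=couple_id(i), gene=gene,
                                   variant_key=key, origin=origin, is_cnv=is_cnv))

    # consanguineous matched couples 1-10 (homozygous children); couples
    # 7-10 carry the zero-star alleles whose exclusion drops total RRP
    # from 7.7% to 6.6%
    for n, i in enumerate(range(1, 7)):
        gene = f"ARG{i:02d}"
        b.gene(gene, ndd=True)
        key = b.add_shared(i, gene, _AT_RISK_KIND_CYCLE[n % 4])
        truth_ar_at_risk.add(couple_id(i)); truth_ar_matched.add(couple_id(i))
        children_modes[i] = cp.AR_HOM
        _dx(i, gene, key, "maternal"); _dx(i, gene, key, "paternal")
    for i, gene in zip(range(7, 11), ZERO_STAR_GENES):
        key = b.add_shared(i, gene, "cv_plp_dm_zero")
        truth_ar_at_risk.add(couple_id(i)); truth_ar_matched.add(couple_id(i))
        children_modes[i] = cp.AR_HOM
        _dx(i, gene, key, "maternal"); _dx(i, gene, key, "paternal")
    # consanguineous at-risk without transmission (11-12) and the
    # missense-modelling-dependent couple 13 (drops under the pragmatic policy)
    for n, i in enumerate((11, 12)):
        gene = f"ARG{i:02d}"
        b.gene(gene, ndd=(i == 11))
        b.add_shared(i, gene, _AT_RISK_KIND_CYCLE[n % 4])
        truth_ar_at_risk.add(couple_id(i))
    b.gene("ARG13")
    b.add_pair(13, "ARG13", "noncv_hs_missense", "noncv_hs_missense")
    truth_ar_at_risk.add(couple_id(13))

    # nonconsanguineous matched couples 24-30 (compound het children);
    # couple 28 carries the convincingly pathogenic conflicting-record allele
    for n, i in enumerate(range(24, 31)):
        gene = "MMACHC" if i == 28 else f"ARG{i:02d}"
        if i != 28:
            b.gene(gene, ndd=True)
        kind_m = "mmachc_conf" if i == 28 else _AT_RISK_KIND_CYCLE[n % 4]
        km, kf = b.add_pair(i, gene, kind_m, _AT_RISK_KIND_CYCLE[(n + 1) % 4])
        truth_ar_at_risk.add(couple_id(i)); truth_ar_matched.add(couple_id(i))
        children_modes[i] = cp.AR_COMPHET
        _dx(i, gene, km, "maternal"); _dx(i, gene, kf, "paternal")
    # nonconsanguineous at-risk without transmission (31-54), policy-dependent
    # couple 55, and couples 56-60 whose mothers additionally carry XL alleles
    for n, i in enumerate(range(31, 55)):
        gene = f"ARG{i:02d}"
        b.gene(gene, ndd=(n % 3 == 0))
        b.add_pair(i, gene, _AT_RISK_KIND_CYCLE[n % 4], _AT_RISK_KIND_CYCLE[(n + 2) % 4])
        truth_ar_at_risk.add(couple_id(i))
    b.gene("ARG55")
    b.add_pair(55, "ARG55", "noncv_hs_missense", "noncv_hs_missense")
    truth_ar_at_risk.add(couple_id(55))
    truth_xl_at_risk = set()
    for n, i in enumerate(range(56, 61)):
        gene = f"ARG{i:02d}"
        b.gene(gene)
        b.add_pair(i, gene, _AT_RISK_KIND_CYCLE[n % 4], _AT_RISK_KIND_CYCLE[(n + 1) % 4])
        truth_ar_at_risk.add(couple_id(i))
        xlg = f"XLG{11 + n + 1:02d}"
        b.gene(xlg, inh="XL", ndd=True)
        b.add_call(mother_id(i), xlg, "cv_plp_dm")
        truth_xl_at_risk.add(couple_id(i))
    # matched couples in the uncertain stratum (317-318)
    for n, i in enumerate((317, 318)):
        gene = f"ARG{i}"
        b.gene(gene, ndd=True)
        km, kf = b.add_pair(i, gene, _AT_RISK_KIND_CYCLE[n % 4], _AT_RISK_KIND_CYCLE[(n + 3) % 4])
        truth_ar_at_risk.add(couple_id(i)); truth_ar_matched.add(couple_id(i))
        children_modes[i] = cp.AR_COMPHET
        _dx(i, gene, km, "maternal"); _dx(i, gene, kf, "paternal")

    # second shared genes for the 13 couples at risk for > 1 autosomal gene
    # (4 consanguineous + 9 nonconsanguineous)
    for n, i in enumerate(list(range(1, 5)) + list(range(31, 40))):
        gene = f"ARX{n + 1:02d}"
        b.gene(gene)
        b.add_shared(i, gene, _AT_RISK_KIND_CYCLE[n % 4])

    # ---- X-linked carrier mothers (20 = 8 matched + 3 + 4 distinct + 5 above)
    truth_xl_matched = set()
    for n, i in enumerate(range(61, 69)):
        gene = "MECP2" if i == 61 else f"XLG{n + 1:02d}"
        if i != 61:
            b.gene(gene, inh="XL", ndd=True)
        key = b.add_call(mother_id(i), gene, "cv_plp_dm")
        truth_xl_at_risk.add(couple_id(i)); truth_xl_matched.add(couple_id(i))
        children_modes[i] = cp.XL_INHERITED
        _dx(i, gene, key, "maternal")
    for n, i in enumerate(list(range(69, 72)) + list(range(319, 323))):
        gene = f"XLG{16 + n + 1:02d}"
        b.gene(gene, inh="XL")
        b.add_call(mother_id(i), gene, "cv_plp_dm")
        truth_xl_at_risk.add(couple_id(i))

    # ---- filter false negatives (16 couples, 17 filtered missense variants)
    truth_fn = set()
    fn_couples = [14] + list(range(99, 112))  # autosomal (couple 99: both filtered)
    for n, i in enumerate(fn_couples):
        gene = f"FNG{n + 1:02d}"
        b.gene(gene, ndd=True)
        if i == 99:
            km = b.add_call(mother_id(i), gene, "noncv_fail_missense")
            kf = b.add_call(father_id(i), gene, "noncv_fail_missense")
        else:
            km = b.add_call(mother_id(i), gene, "noncv_trunc")
            kf = b.add_call(father_id(i), gene, "noncv_fail_missense")
        truth_fn.add(couple_id(i))
        children_modes[i] = cp.AR_COMPHET
        _dx(i, gene, km, "maternal"); _dx(i, gene, kf, "paternal")
    for n, i in enumerate((112, 113)):  # X-linked, maternal missense filtered
        gene = f"FNX{n + 1}"
        b.gene(gene, inh="XL", ndd=True)
        km = b.add_call(mother_id(i), gene, "noncv_fail_missense")
        truth_fn.add(couple_id(i))
        children_modes[i] = cp.XL_INHERITED
        _dx(i, gene, km, "maternal")

    # ---- intrinsically undetectable diagnoses (2 + 3 + 3 couples)
    for n, i in enumerate((120, 121)):
        gene = f"XDN{n + 1}"
        b.gene(gene, inh="XL", ndd=True)
        children_modes[i] = cp.XL_DENOVO
        _dx(i, gene, f"dn:{couple_id(i)}", "denovo")
    for n, i in enumerate((122, 123, 124)):
        gene = f"CDN{n + 1}"
        b.gene(gene, ndd=True)
        km = b.add_call(mother_id(i), gene, "cv_plp_dm")
        children_modes[i] = cp.COMPHET_INH_DENOVO
        _dx(i, gene, km, "maternal"); _dx(i, gene, f"dn:{couple_id(i)}", "denovo")
    for n, i in enumerate((125, 126, 127)):
        gene = f"CNV{n + 1}"
        b.gene(gene, inh="XL" if n < 2 else "AR", ndd=True)
        children_modes[i] = cp.CNV_INVOLVING
        _dx(i, gene, f"cnv:{couple_id(i)}", "maternal", is_cnv=True)
        if n == 2:  # compound het: inherited CNV plus paternal sequence variant
            kf = b.add_call(father_id(i), gene, "noncv_trunc")
            _dx(i, gene, kf, "paternal")

    # ---- hypomorphic HFE alleles (191 carriers = 27.3%) ----------------
    hfe_key = b.new_key("HFE")
    for i in HFE_SHARED_COUPLES:
        b.add_call(mother_id(i), "HFE", "hfe_hypo", key=hfe_key)
        b.add_call(father_id(i), "HFE", "hfe_hypo", key=hfe_key)
    for i in HFE_SINGLE_MOTHERS:
        b.add_call(mother_id(i), "HFE", "hfe_hypo", key=hfe_key)
    registry = HypomorphicRegistry(
        variant_keys={variant_key(*hfe_key)},
        keep_pathogenic={k for k, a in b.ann.items() if a["gene"] == "MMACHC"},
    )

    # ---- de novo dominant diagnoses ------------------------------------
    for n, i in enumerate(AD_DENOVO_COUPLES):
        gene = f"ADG{n % 30 + 1:02d}"
        b.gene(gene, ndd=True)
        children_modes[i] = cp.AD_DENOVO
        _dx(i, gene, f"dn:{couple_id(i)}", "denovo")

    # ---- a few calls removed by QC (funnel realism; never counted) -----
    qc_sample = father_id(340)
    for gene, kw in (
        ("QCG1", dict(kind="cv_plp_dm", quality=8.0)),
        ("QCG2", dict(kind="noncv_trunc", alt_fraction=0.20)),
        ("QCG3", dict(kind="noncv_trunc", forward_fraction=0.95)),
        ("QCG4", dict(kind="noncv_trunc", homology=True)),
    ):
        b.gene(gene)
        b.add_call(qc_sample, gene, **kw)

    # ---- filler variants: realise the per-individual count distribution
    individuals = [mother_id(i) for i in range(1, N_COUPLES + 1)] + [
        father_id(i) for i in range(1, N_COUPLES + 1)
    ]
    structured = {s: 0 for s in individuals}
    for call in b.calls:
        if call["_qualifies"]:
            structured[call["sample_id"]] += 1
    targets = [c for c, n in _COUNT_DISTRIBUTION for _ in range(n)]
    assert len(targets) == len(individuals)
    ordered = sorted(individuals, key=lambda s: (-structured[s], s))
    for g in range(60):  # disjoint pools keep partners from sharing filler genes
        b.gene(f"FILM{g + 1:02d}")
        b.gene(f"FILF{g + 1:02d}")
    for rank, (sample, target) in enumerate(zip(ordered, sorted(targets, reverse=True))):
        n_fill = target - structured[sample]
        assert n_fill >= 0
        pool = "FILM" if sample.endswith("f") else "FILF"
        for j in range(n_fill):
            gene = f"{pool}{(rank * 7 + j) % 60 + 1:02d}"
            b.add_call(sample, gene, _FILLER_KIND_CYCLE[(rank + j) % 4])

    # ---- catalog -------------------------------------------------------
    entries = []
    for name, info in b.genes.items():
        inh = "XL" if info["inh"] == "XL" else "AR"
        entries.append(DatabaseGeneEntry(name, "OMIM", inh))
        entries.append(DatabaseGeneEntry(name, "CGD", inh, frozenset({"neurologic"})))
    catalog = merge_gene_databases(entries)
    catalog = apply_curation_overrides(
        catalog,
        non_capturable=NON_CAPTURABLE,
        ndd_genes=[g for g, info in b.genes.items() if info["ndd"]],
    )

    # ---- trio tables ---------------------------------------------------
    strata = {i: "consanguineous" for i in CONS}
    strata.update({i: "nonconsanguineous" for i in NONCONS})
    strata.update({i: "uncertain" for i in UNCERTAIN})
    couples_df = pd.DataFrame(
        {
            "couple_id": [couple_id(i) for i in range(1, N_COUPLES + 1)],
            "mother_id": [mother_id(i) for i in range(1, N_COUPLES + 1)],
            "father_id": [father_id(i) for i in range(1, N_COUPLES + 1)],
            "child_id": [child_id(i) for i in range(1, N_COUPLES + 1)],
            "consanguinity": [strata[i] for i in range(1, N_COUPLES + 1)],
        }
    )
    children_df = pd.DataFrame(
        {
            "couple_id": [couple_id(i) for i in range(1, N_COUPLES + 1)],
            "child_id": [child_id(i) for i in range(1, N_COUPLES + 1)],
            "sex": ["F" if i == 61 else "M" for i in range(1, N_COUPLES + 1)],
            "mode": [children_modes.get(i) for i in range(1, N_COUPLES + 1)],
        }
    )
    diagnoses_df = pd.DataFrame(diagnoses_rows)

    # ---- child ROH segments --------------------------------------------
    child_f = {}
    for i in range(1, N_COUPLES + 1):
        if i in (1, 2):
            child_f[i] = 0.25       # first degree
        elif i in range(3, 9):
            child_f[i] = 0.125      # second degree
        elif i in CONS:
            child_f[i] = 0.0625     # third degree
        elif i in UNCERTAIN:
            child_f[i] = 0.03       # ambiguous band
        else:
            child_f[i] = None       # outbred
    roh_rows = []
    for i in range(1, N_COUPLES + 1):
        roh_rows.extend(_roh_segments(child_id(i), child_f[i]))
    roh_df = pd.DataFrame(roh_rows, columns=["sample_id", "chrom", "start", "end"])

    # ---- SMN1 read counts (13 single-copy carriers) ---------------------
    carrier_set = set(SMN1_CARRIER_SAMPLES)
    extra_states = {mother_id(i): (2, 1) for i in range(40, 60)}  # benign variation
    extra_states.update({father_id(i): (3, 2) for i in range(300, 310)})
    smn_rows = []
    for idx, sample in enumerate(individuals):
        run = f"run{idx // 100}"
        c1, c2 = (1, 2) if sample in carrier_set else extra_states.get(sample, (2, 2))
        smn_rows.append(_smn1_counts(sample, run, c1, c2))
    smn_df = pd.DataFrame(smn_rows)

    # ---- FMR1 repeats ---------------------------------------------------
    fmr1_df = pd.DataFrame(
        {
            "sample_id": [mother_id(i) for i in range(1, N_COUPLES + 1)],
            "cgg": [FMR1_PREMUTATION.get(i, 30) for i in range(1, N_COUPLES + 1)],
        }
    )

    calls_df = pd.DataFrame([{k: v for k, v in c.items() if k != "_qualifies"} for c in b.calls])
    ann_df = pd.DataFrame(list(b.ann.values()))
    individuals_df = pd.DataFrame(
        {"sample_id": individuals, "sex": ["F" if s.endswith("f") else "M" for s in individuals]}
    )

    truth = {
        "strata": {
            "consanguineous": [couple_id(i) for i in CONS],
            "nonconsanguineous": [couple_id(i) for i in NONCONS],
            "uncertain": [couple_id(i) for i in UNCERTAIN],
        },
        "ar_at_risk": truth_ar_at_risk,
        "xl_at_risk": truth_xl_at_risk,
        "ar_matched": truth_ar_matched,
        "xl_matched": truth_xl_matched,
        "zero_star_dependent": {couple_id(i) for i in range(7, 11)},
        "policy_dependent": {couple_id(13), couple_id(55)},
        "filter_false_negatives": truth_fn,
        "smn1_carriers": sorted(carrier_set),
        "fmr1_premutation_mothers": [mother_id(i) for i in FMR1_PREMUTATION],
    }

    return CohortBundle(
        catalog=catalog, individuals=individuals_df, calls=calls_df,
        annotations=ann_df, couples=couples_df, children=children_df,
        diagnoses=diagnoses_df, roh=roh_df, smn1=smn_df, fmr1=fmr1_df,
        registry=registry, truth=truth,
    )
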