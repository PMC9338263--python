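"""Readers and writers for the cohort artifact tables.

Variant calls travel either as a flat TSV or as a multi-sample VCF
(1-based, closed coordinates); ROH segments as BED (0-based, half-open).
`bed_to_1based` / `to_bed_interval` are the single conversion point
between the two coordinate conventions.

A cohort bundle on disk is a directory of plain-text tables
(``calls.tsv``, ``annotations.tsv``, ``couples.tsv``, ``children.tsv``,
``diagnoses.tsv``, ``roh.bed``, ``smn1.tsv``, ``fmr1.tsv``,
``individuals.tsv``, ``catalog.tsv``) plus ``registry.yaml``; writing and
re-reading a bundle is an identity round trip.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bundle import CohortBundle
from .catalog import catalog_to_frame, frame_to_catalog
from .classify import HypomorphicRegistry
from .qc import CALL_COLUMNS

logger = logging.getLogger(__name__)

_VCF_DP = 100  # synthetic read depth used to encode alt fractions in AD


def bed_to_1based(start: int, end: int) -> tuple[int, int]:
    """BED half-open [start, end) -> 1-based closed [start+1, end]."""
    return int(start) + 1, int(end)


def to_bed_interval(start1: int, end1: int) -> tuple[int, int]:
    """1-based closed [start1, end1] -> BED half-open [start1-1, end1)."""
    return int(start1) - 1, int(end1)


# ---------------------------------------------------------------------------
# variant calls

def read_variant_calls(path, fmt: str | None = None) -> pd.DataFrame:
    """Read per-sample variant calls from a TSV or a multi-sample VCF.

    The VCF dialect stores the gene in INFO/GENE and per-sample
    GT:AD:FF:VQ fields (alt fraction from AD, forward-read fraction FF,
    per-call quality VQ).  Malformed TSV rows abort with the line number;
    an empty file yields an empty frame with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        except pd.errors.EmptyDataError:
            logger.warning("empty call file %s", path)
            return pd.DataFrame(columns=CALL_COLUMNS)
        missing = set(CALL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"call table missing columns: {sorted(missing)}")
        return df
    if fmt == "vcf":
        return _read_vcf_calls(path)
    raise ValueError(f"unknown call format {fmt!r}")


def _read_vcf_calls(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for var in vcf:
        gene = var.INFO.get("GENE", "")
        ad = var.format("AD")
        ff = var.format("FF")
        vq = var.format("VQ")
        for si, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles or not any(a > 0 for a in alleles):
                continue
            if len(alleles) == 1:
                zyg = "hemi"
            else:
                zyg = "hom" if all(a > 0 for a in alleles) else "het"
            ref_n, alt_n = float(ad[si][0]), float(ad[si][1])
            rows.append(
                dict(
                    sample_id=samples[si], gene=gene, chrom=str(var.CHROM),
                    pos=int(var.POS), ref=var.REF, alt=var.ALT[0], zygosity=zyg,
                    quality=float(vq[si][0]),
                    alt_fraction=alt_n / (ref_n + alt_n),
                    forward_fraction=float(ff[si][0]),
                )
            )
    if not rows:
        logger.warning("no calls in VCF %s", path)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_vcf_calls(calls: pd.DataFrame, path) -> None:
    """Write calls as a minimal multi-sample VCFv4.2 (GT:AD:FF:VQ)."""
    samples = sorted(calls["sample_id"].unique())
    sample_idx = {s: i for i, s in enumerate(samples)}
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=FF,Number=1,Type=Float,Description="Forward-read fraction">',
        '##FORMAT=<ID=VQ,Number=1,Type=Float,Description="Call quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines = []
    keycols = ["chrom", "pos", "ref", "alt", "gene"]
    for (chrom, pos, ref, alt, gene), grp in calls.groupby(keycols, sort=True):
        cells = ["./.:.:.:."] * len(samples)
        for row in grp.itertuples(index=False):
            gt = {"het": "0/1", "hom": "1/1", "hemi": "1"}[row.zygosity]
            alt_n = int(round(row.alt_fraction * _VCF_DP))
            cells[sample_idx[row.sample_id]] = (
                f"{gt}:{_VCF_DP - alt_n},{alt_n}:{row.forward_fraction:g}:{row.quality:g}"
            )
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{grp['quality'].max():g}\tPASS\t"
            f"GENE={gene}\tGT:AD:FF:VQ\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(header + lines) + "\n")


# ---------------------------------------------------------------------------
# BED / misc tables

def read_bed(path, with_sample: bool = True) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (["sample_id"] if with_sample else [])
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        logger.warning("empty BED %s", path)
        return pd.DataFrame(columns=names)
    return df


def write_bed(segments: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["sample_id"] if "sample_id" in segments else [])
    segments[cols].to_csv(path, sep="\t", header=False, index=False)


def read_registry(path) -> HypomorphicRegistry:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return HypomorphicRegistry(
        variant_keys=set(data.get("variant_keys", [])),
        gene_wildcards=set(data.get("gene_wildcards", [])),
        keep_pathogenic=set(data.get("keep_pathogenic", [])),
    )


def write_registry(registry: HypomorphicRegistry, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "variant_keys": sorted(registry.variant_keys),
                "gene_wildcards": sorted(registry.gene_wildcards),
                "keep_pathogenic": sorted(registry.keep_pathogenic),
            }
        )
    )


# ---------------------------------------------------------------------------
# bundle round trip

_BUNDLE_TABLES = {
    "individuals": "individuals.tsv",
    "calls": "calls.tsv",
    "annotations": "annotations.tsv",
    "couples": "couples.tsv",
    "children": "children.tsv",
    "diagnoses": "diagnoses.tsv",
    "smn1": "smn1.tsv",
    "fmr1": "fmr1.tsv",
}


def write_bundle(bundle: CohortBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _BUNDLE_TABLES.items():
        getattr(bundle, attr).to_csv(directory / fname, sep="\t", index=False)
    catalog_to_frame(bundle.catalog).to_csv(directory / "catalog.tsv", sep="\t", index=False)
    roh = bundle.roh[["chrom", "start", "end", "sample_id"]]
    roh.to_csv(directory / "roh.bed", sep="\t", header=False, index=False)
    write_registry(bundle.registry, directory / "registry.yaml")


def read_bundle(directory) -> CohortBundle:
    directory = Path(directory)
    tables = {}
    for attr, fname in _BUNDLE_TABLES.items():
        tables[attr] = pd.read_csv(directory / fname, sep="\t", dtype={"chrom": str})
    roh = read_bed(directory / "roh.bed")
    catalog = frame_to_catalog(
        pd.read_csv(directory / "catalog.tsv", sep="\t", keep_default_na=False,
                    dtype={"categories": str, "exclusion_reason": str})
    )
    registry = read_registry(directory / "registry.yaml")
    children = tables["children"]
    children["mode"] = children["mode"].replace({np.nan: None})
    return CohortBundle(
        catalog=catalog, roh=roh[["sample_id", "chrom", "start", "end"]],
        registry=registry, **tables,
    )
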