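"""Curated catalog of recessive and X-linked disease genes.

Carrier screening starts from a gene list.  This module merges inheritance
annotations exported from several disease-gene databases (OMIM-, CGD-,
DDG2P- and ClinGen-style tables) into one catalog with a consensus
inheritance status per gene, clinical manifestation categories, and the
flags used downstream: neurodevelopmental-disorder (NDD) gene, severity
panel member, and whether the gene is reliably capturable by standard
exome kits (paralog- or repeat-confounded genes are not).

It also assigns the four nested carrier-screening tiers: Tier-1 is a
configured core set (CFTR and SMN1 by default), Tier-2 adds genes with
observed carrier frequency >= 1/100, Tier-3 adds genes >= 1/200 plus all
X-linked conditions, Tier-4 adds everything else.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

VALID_INHERITANCE = {"AR", "AD", "XL", "other"}

CONSENSUS_AR = "consensus_AR"
CONSENSUS_XL = "consensus_XL"
CONFLICTING = "conflicting"
NEEDS_CURATION = "needs_manual_curation"
EXCLUDED = "excluded"

#: Default Tier-1 content: the two genes every guideline names explicitly.
DEFAULT_TIER1 = frozenset({"CFTR", "SMN1"})

TIER2_MIN_FREQ = 1.0 / 100.0
TIER3_MIN_FREQ = 1.0 / 200.0


@dataclass(frozen=True)
class DatabaseGeneEntry:
    """One (gene, database, inheritance) annotation row from a source export."""

    gene_symbol: str
    source_db: str
    inheritance: str
    categories: frozenset = frozenset()


@dataclass
class GeneRecord:
    """A gene in the merged catalog."""

    gene_symbol: str
    consensus_status: str
    categories: set = field(default_factory=set)
    is_ndd: bool = False
    is_severe: bool = False
    capturable: bool = True
    exclusion_reason: str | None = None

    @property
    def active(self) -> bool:
        return self.consensus_status != EXCLUDED

    @property
    def x_linked(self) -> bool:
        return self.consensus_status == CONSENSUS_XL


@dataclass(frozen=True)
class TierAssignment:
    gene_symbol: str
    tier: int
    observed_carrier_freq: float


def normalize_symbol(symbol: str, alias_map: dict | None = None) -> str:
    """Upper-case a gene symbol and resolve it through an optional alias table."""
    sym = str(symbol).strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


def merge_gene_databases(entries, alias_map=None) -> list[GeneRecord]:
    """Merge per-database inheritance annotations into one record per gene.

    Any X-linked annotation makes the gene consensus X-linked.  An autosomal
    gene is consensus recessive when every database listing it annotates AR;
    mixed AR/AD annotations are conflicting; genes annotated AD-only by more
    than one database are flagged for manual curation (AD-only in a single
    database is kept as conflicting).  Rows with an unknown inheritance token
    are rejected with a warning.

    The result is sorted by symbol, so merging is order-independent.
    """
    per_gene: dict[str, dict] = {}
    for entry in entries:
        if entry.inheritance not in VALID_INHERITANCE:
            logger.warning(
                "rejecting %s/%s: unknown inheritance %r",
                entry.gene_symbol, entry.source_db, entry.inheritance,
            )
            continue
        sym = normalize_symbol(entry.gene_symbol, alias_map)
        info = per_gene.setdefault(sym, {"sources": defaultdict(set), "cats": set()})
        info["sources"][entry.source_db].add(entry.inheritance)
        info["cats"].update(entry.categories)

    records = []
    for sym in sorted(per_gene):
        sources = per_gene[sym]["sources"]
        all_inh = set().union(*sources.values())
        if "XL" in all_inh:
            status = CONSENSUS_XL
        else:
            n_sources = len(sources)
            n_with_ar = sum("AR" in inh for inh in sources.values())
            n_ad_only = sum(inh == {"AD"} for inh in sources.values())
            if n_with_ar == n_sources:
                status = CONSENSUS_AR
            elif n_ad_only == n_sources and n_sources > 1:
                status = NEEDS_CURATION
            else:
                status = CONFLICTING
        records.append(GeneRecord(sym, status, categories=set(per_gene[sym]["cats"])))
    return records


def apply_curation_overrides(
    catalog: list[GeneRecord],
    overrides: dict | None = None,
    non_capturable=(),
    ndd_genes=(),
    severe_genes=(),
) -> list[GeneRecord]:
    """Apply manual curation to a merged catalog.

    ``overrides`` maps gene symbol to either ``"keep"`` (force the gene to be
    treated as consensus recessive) or ``("exclude", reason)``.  Excluded
    genes are retained in the catalog with their reason but drop out of every
    downstream metric.  ``non_capturable`` flags genes that cannot reliably
    be assessed from exome data (paralogs, repeat expansions); ``ndd_genes``
    and ``severe_genes`` set the panel-membership flags.
    """
    overrides = dict(overrides or {})
    non_capturable = {normalize_symbol(g) for g in non_capturable}
    ndd_genes = {normalize_symbol(g) for g in ndd_genes}
    severe_genes = {normalize_symbol(g) for g in severe_genes}
    known = {r.gene_symbol for r in catalog}
    for gene in overrides:
        if normalize_symbol(gene) not in known:
            logger.warning("curation override for unknown gene %s", gene)

    out = []
    for rec in catalog:
        rec = GeneRecord(
            rec.gene_symbol,
            rec.consensus_status,
            categories=set(rec.categories),
            is_ndd=rec.gene_symbol in ndd_genes,
            is_severe=rec.gene_symbol in severe_genes,
            capturable=rec.gene_symbol not in non_capturable,
            exclusion_reason=rec.exclusion_reason,
        )
        action = overrides.get(rec.gene_symbol)
        if action is not None:
            if action == "keep":
                if rec.consensus_status in (NEEDS_CURATION, CONFLICTING):
                    rec.consensus_status = CONSENSUS_AR
            else:  # ("exclude", reason) or {"action": "exclude", "reason": ...}
                if isinstance(action, dict):
                    reason = action.get("reason", "excluded by curation")
                else:
                    reason = action[1]
                rec.consensus_status = EXCLUDED
                rec.exclusion_reason = reason
        out.append(rec)
    return out


def active_genes(catalog) -> set:
    return {r.gene_symbol for r in catalog if r.active}


def x_linked_genes(catalog) -> set:
    return {r.gene_symbol for r in catalog if r.active and r.x_linked}


def ndd_genes(catalog) -> set:
    return {r.gene_symbol for r in catalog if r.active and r.is_ndd}


def assign_tiers(catalog, carrier_freqs: dict, tier1_genes=None) -> list[TierAssignment]:
    """Assign every active gene to the smallest tier that contains it.

    Tier sets are nested by construction: a gene of tier t belongs to every
    tier >= t (see :func:`tier_gene_sets`).
    """
    tier1 = {normalize_symbol(g) for g in (tier1_genes if tier1_genes is not None else DEFAULT_TIER1)}
    known = {r.gene_symbol for r in catalog if r.active}
    for gene in tier1 - known:
        logger.warning("Tier-1 gene %s not in catalog", gene)

    assignments = []
    for rec in catalog:
        if not rec.active:
            continue
        freq = float(carrier_freqs.get(rec.gene_symbol, 0.0))
        if rec.gene_symbol in tier1:
            tier = 1
        elif freq >= TIER2_MIN_FREQ:
            tier = 2
        elif freq >= TIER3_MIN_FREQ or rec.x_linked:
            tier = 3
        else:
            tier = 4
        assignments.append(TierAssignment(rec.gene_symbol, tier, freq))
    return assignments


def tier_gene_sets(assignments) -> dict[int, set]:
    """Cumulative (nested) gene sets per tier: Tier-k = all genes of tier <= k."""
    sets: dict[int, set] = {}
    for t in (1, 2, 3, 4):
        sets[t] = {a.gene_symbol for a in assignments if a.tier <= t}
    return sets


def restrict_to_panel(catalog, panel) -> list[GeneRecord]:
    """Subset a catalog to a gene panel (set intersection on symbols)."""
    panel = {normalize_symbol(g) for g in panel}
    return [r for r in catalog if r.gene_symbol in panel]


# ---------------------------------------------------------------------------
# tabular round trip

def catalog_to_frame(catalog) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_symbol for r in catalog],
            "consensus_status": [r.consensus_status for r in catalog],
            "categories": [";".join(sorted(r.categories)) for r in catalog],
            "is_ndd": [r.is_ndd for r in catalog],
            "is_severe": [r.is_severe for r in catalog],
            "capturable": [r.capturable for r in catalog],
            "exclusion_reason": [r.exclusion_reason or "" for r in catalog],
        }
    )


def frame_to_catalog(df: pd.DataFrame) -> list[GeneRecord]:
    records = []
    for row in df.itertuples(index=False):
        cats = {c for c in str(row.categories).split(";") if c} if row.categories else set()
        records.append(
            GeneRecord(
                row.gene,
                row.consensus_status,
                categories=cats,
                is_ndd=bool(row.is_ndd),
                is_severe=bool(row.is_severe),
                capturable=bool(row.capturable),
                exclusion_reason=(row.exclusion_reason or None),
            )
        )
    return records
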