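"""The in-memory cohort bundle passed between pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalog import GeneRecord
from .classify import HypomorphicRegistry


@dataclass
class CohortBundle:
    """Everything the analysis consumes for one cohort.

    ``calls`` and ``annotations`` feed QC/classification; ``couples``,
    ``children`` and ``diagnoses`` define the trio structure; ``roh``,
    ``smn1`` and ``fmr1`` feed the special-gene callers.  ``individuals``
    lists every screened sample with its sex (so zero-carrier samples are
    represented).  ``truth`` carries generator ground truth for synthetic
    cohorts (empty for real data).
    """

    catalog: list  # list[GeneRecord]
    individuals: pd.DataFrame  # sample_id, sex
    calls: pd.DataFrame
    annotations: pd.DataFrame
    couples: pd.DataFrame  # couple_id, mother_id, father_id, child_id, consanguinity
    children: pd.DataFrame  # couple_id, child_id, sex, mode (diagnosis mode or NA)
    diagnoses: pd.DataFrame  # couple_id, gene, variant_key, origin, is_cnv
    roh: pd.DataFrame  # sample_id, chrom, start, end (BED convention)
    smn1: pd.DataFrame  # sample_id, run_id, smn read counts, control columns
    fmr1: pd.DataFrame  # sample_id, cgg
    registry: HypomorphicRegistry = field(default_factory=HypomorphicRegistry)
    truth: dict = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_couples(self) -> int:
        return len(self.couples)
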