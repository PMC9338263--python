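"""Runs-of-homozygosity inbreeding coefficient and consanguinity classes.

F_ROH is the fraction of the autosomal genome covered by long runs of
homozygosity: overlapping segments are merged per chromosome, segments
strictly longer than 5 Mb (a length compatible with identity by descent)
are summed, and the total is divided by the autosomal genome length
(2691 Mb for GRCh37/hg19).  ROH segments themselves are inputs (BED-style,
0-based half-open); detecting them from genotypes is out of scope.

Degrees of relationship are read off F against bins placed at the
geometric midpoints around the expected autozygosity of first- (0.25),
second- (0.125) and third-degree (0.0625) unions, with an "uncertain"
band below the third degree.  A couple's consanguinity is classified from
their child's F_ROH (parental relatedness manifests as child
autozygosity); a parental-profile fallback can be supplied.
"""
from __future__ import annotations

import pandas as pd

AUTOSOMAL_GENOME_BP = 2_691_000_000  # GRCh37/hg19
MIN_SEGMENT_BP = 5_000_000  # strict: a segment must exceed 5 Mb to qualify

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

FIRST_DEGREE_MIN = 0.177     # geometric midpoint of 0.25 and 0.125
SECOND_DEGREE_MIN = 0.0884   # geometric midpoint of 0.125 and 0.0625
THIRD_DEGREE_MIN = 0.0442    # geometric midpoint of 0.0625 and 0.03125
UNCERTAIN_MIN = 0.022        # band of ambiguous background autozygosity

CONSANGUINEOUS_DEGREES = frozenset({"first", "second", "third"})


def merge_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent segments per chromosome (sweep line)."""
    rows = []
    for chrom, grp in segments.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        for start, end in zip(grp["start"], grp["end"]):
            if end <= start:
                raise ValueError(f"segment with end <= start on {chrom}")
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                rows.append((chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def f_roh(segments: pd.DataFrame) -> float:
    """Inbreeding coefficient from one sample's ROH segments.

    Non-autosomal segments are ignored; overlaps are merged before the
    strict > 5 Mb length threshold is applied.  An empty set gives 0.
    """
    if len(segments) == 0:
        return 0.0
    auto = segments.loc[segments["chrom"].astype(str).isin(AUTOSOMES)]
    if len(auto) == 0:
        return 0.0
    merged = merge_segments(auto)
    lengths = merged["end"] - merged["start"]
    qualifying = lengths[lengths > MIN_SEGMENT_BP]
    return float(qualifying.sum()) / AUTOSOMAL_GENOME_BP


def consanguinity_degree(f: float) -> str:
    """Step-function mapping of F onto a degree-of-relationship class."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("F_ROH must lie in [0, 1]")
    if f >= FIRST_DEGREE_MIN:
        return "first"
    if f >= SECOND_DEGREE_MIN:
        return "second"
    if f >= THIRD_DEGREE_MIN:
        return "third"
    if f >= UNCERTAIN_MIN:
        return "uncertain"
    return "not_consanguineous"


def degree_to_status(degree: str) -> str:
    if degree in CONSANGUINEOUS_DEGREES:
        return "consanguineous"
    if degree == "uncertain":
        return "uncertain"
    return "nonconsanguineous"


def f_roh_profiles(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample F_ROH and degree from a combined segment table.

    ``segments`` must carry a ``sample_id`` column next to chrom/start/end.
    """
    rows = []
    for sample_id, grp in segments.groupby("sample_id", sort=True):
        f = f_roh(grp)
        degree = consanguinity_degree(f)
        rows.append((sample_id, f, degree, degree_to_status(degree)))
    return pd.DataFrame(rows, columns=["sample_id", "f_roh", "degree", "status"])


def couple_consanguinity(
    couples: pd.DataFrame,
    child_f_roh: dict,
    fallback: dict | None = None,
) -> pd.Series:
    """Couple-level consanguinity status from each child's F_ROH.

    ``child_f_roh`` maps child_id -> F.  Couples without child data fall
    back to ``fallback`` (couple_id -> status) or "uncertain".
    """
    fallback = fallback or {}
    status = []
    for row in couples.itertuples(index=False):
        f = child_f_roh.get(row.child_id) if hasattr(row, "child_id") else None
        if f is None:
            status.append(fallback.get(row.couple_id, "uncertain"))
        else:
            status.append(degree_to_status(consanguinity_degree(f)))
    return pd.Series(status, index=couples.index, name="consanguinity")
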