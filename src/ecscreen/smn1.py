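"""SMN1 copy-number and carrier calling from exome read depth.

SMN1 and its near-identical paralog SMN2 differ at a handful of
paralog-differentiating positions; exome reads aligning to either copy can
be counted per position.  For each sample the caller computes the raw
proportion of SMN1 reads over total SMN1+SMN2 reads at three such
positions (SMN1 chr5:70247724/70247773/70247921 vs SMN2
chr5:69372304/69372353/69372501, GRCh37), averages them, and rescales by a
per-sample depth factor derived from 20 control genes within the same
sequencing run:

    d_s  = (sum SMN1_s + sum SMN2_s) / (sum control reads_s)
    f_s  = d_s / median_run(d)
    scaled_s = f_s * p_bar_s

With four total SMN copies as the run norm, ``4*f`` estimates total SMN
copies and ``4*f*p_bar`` estimates SMN1 copies; a scaled proportion below
1/3 (the natural boundary between one and two SMN1 copies) flags a
potential carrier.  Median normalization is robust as long as carriers are
a minority of the run.  A PCA + 2-means step provides the candidate/
non-candidate triage view.

Silent (2+0) carriers and SMN2-dependent phenotype interpretation are out
of scope, as is any wet-lab confirmation.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CARRIER_THRESHOLD = 1.0 / 3.0

SMN1_POSITIONS = (70247724, 70247773, 70247921)
SMN2_POSITIONS = (69372304, 69372353, 69372501)

SMN1_COLS = ["smn1_r1", "smn1_r2", "smn1_r3"]
SMN2_COLS = ["smn2_r1", "smn2_r2", "smn2_r3"]


def raw_proportions(smn1_reads, smn2_reads):
    """Per-position SMN1 read proportions and their unweighted mean.

    Positions with zero total reads are dropped with a warning; a sample
    with zero totals at all three positions yields NaN (no-call).
    Accepts 1-D (one sample) or 2-D (samples x 3) arrays.
    """
    s1 = np.asarray(smn1_reads, dtype=float)
    s2 = np.asarray(smn2_reads, dtype=float)
    total = s1 + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, s1 / np.where(total > 0, total, 1.0), np.nan)
    if np.isnan(p).any():
        logger.warning("SMN position(s) with zero total reads dropped")
    valid = np.isfinite(p)
    n_valid = valid.sum(axis=-1)
    sums = np.where(valid, p, 0.0).sum(axis=-1)
    pbar = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    return p, pbar


def scale_factors(run_df: pd.DataFrame) -> pd.Series:
    """Per-sample depth scale factor f within one sequencing run.

    ``run_df`` needs the six SMN read columns plus either 20 ``ctrl_*``
    columns or a precomputed ``control_total``.  A run of a single sample
    gets f = 1 with a warning (no within-run norm available).
    """
    smn_total = run_df[SMN1_COLS + SMN2_COLS].sum(axis=1).astype(float)
    ctrl_cols = [c for c in run_df.columns if c.startswith("ctrl_")]
    if ctrl_cols:
        control_total = run_df[ctrl_cols].sum(axis=1).astype(float)
    else:
        control_total = run_df["control_total"].astype(float)
    if (control_total <= 0).any():
        raise ValueError("non-positive control read total")
    d = smn_total / control_total
    if len(run_df) < 2:
        logger.warning("run with a single sample: scale factor fixed at 1")
        return pd.Series(1.0, index=run_df.index)
    return d / d.median()


def call_carriers(samples: pd.DataFrame, weighted_mean: bool = False) -> pd.DataFrame:
    """SMN1 carrier calls for a table of samples (grouped by ``run_id``).

    Returns one row per sample with the three raw proportions, their mean
    p_bar, the scale factor f, the scaled proportion f*p_bar, continuous and
    nearest-integer copy estimates, and the flags ``potential_carrier``
    (scaled proportion < 1/3), ``affected_range`` (estimated SMN1 copies
    < 0.5) and ``no_call``.  ``weighted_mean`` switches p_bar to a
    read-count-weighted mean over positions.
    """
    out = []
    for run_id, run_df in samples.groupby("run_id", sort=False):
        s1 = run_df[SMN1_COLS].to_numpy(float)
        s2 = run_df[SMN2_COLS].to_numpy(float)
        p, pbar = raw_proportions(s1, s2)
        if weighted_mean:
            tot = s1 + s2
            with np.errstate(invalid="ignore", divide="ignore"):
                pbar = np.where(tot.sum(axis=1) > 0, s1.sum(axis=1) / tot.sum(axis=1), np.nan)
        f = scale_factors(run_df).to_numpy()
        scaled = f * pbar
        res = pd.DataFrame(
            {
                "sample_id": run_df["sample_id"].to_numpy(),
                "run_id": run_id,
                "p1": p[:, 0], "p2": p[:, 1], "p3": p[:, 2],
                "mean_raw_proportion": pbar,
                "scale_factor": f,
                "scaled_proportion": scaled,
                "est_total_smn_copies": 4.0 * f,
                "est_smn1_copies": 4.0 * f * pbar,
            }
        )
        res["smn1_copies_int"] = np.round(res["est_smn1_copies"]).astype("Int64")
        res["no_call"] = ~np.isfinite(scaled)
        res["potential_carrier"] = (scaled < CARRIER_THRESHOLD) & np.isfinite(scaled)
        res["affected_range"] = (res["est_smn1_copies"] < 0.5) & np.isfinite(scaled)
        out.append(res)
    return pd.concat(out, ignore_index=True)


def cluster_candidates(calls: pd.DataFrame, seed: int = 0):
    """PCA + 2-means triage of carrier candidates.

    The feature vector is (f, p1, p2, p3), standardized.  Returns the calls
    table with top-2 principal-component scores and a cluster label in
    which 1 marks the candidate (lower scaled proportion) cluster, or None
    when fewer than 3 callable samples or zero-variance features make the
    projection degenerate.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    usable = calls.loc[~calls["no_call"]].copy()
    if len(usable) < 3:
        logger.warning("PCA skipped: fewer than 3 callable samples")
        return None
    feats = usable[["scale_factor", "p1", "p2", "p3"]].to_numpy(float)
    sd = feats.std(axis=0)
    if np.any(sd == 0):
        logger.warning("PCA skipped: zero-variance feature(s)")
        return None
    z = (feats - feats.mean(axis=0)) / sd
    pcs = PCA(n_components=2, random_state=seed).fit_transform(z)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pcs)
    labels = km.labels_
    # label 1 = candidate cluster (lower mean scaled proportion)
    mean0 = usable["scaled_proportion"].to_numpy()[labels == 0].mean()
    mean1 = usable["scaled_proportion"].to_numpy()[labels == 1].mean()
    candidate = labels == (0 if mean0 < mean1 else 1)
    usable["pc1"] = pcs[:, 0]
    usable["pc2"] = pcs[:, 1]
    usable["cluster"] = np.where(candidate, 1, 0)
    return usable
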