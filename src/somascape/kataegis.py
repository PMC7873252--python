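"""Intermutation distances (rainfall) and kataegis detection.

Kataegis — localized hypermutation — appears on a rainfall plot as a run
of SNVs with very small intermutation distances (IMDs). Detection here
follows the community convention: any window of ``min_count`` consecutive
SNVs on one chromosome whose mean internal IMD is at most ``max_mean_imd``
(defaults 6 and 1000 bp) qualifies, and overlapping qualifying windows are
merged into maximal regions. Runs are evaluated on consecutive SNVs, not
fixed genomic windows, matching rainfall-plot semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectrum import substitution_class


@dataclass(frozen=True)
class KataegisParams:
    min_count: int = 6
    max_mean_imd: float = 1000.0

    def __post_init__(self):
        if self.min_count < 2:
            raise ValueError("min_count must be >= 2")
        if self.max_mean_imd <= 0:
            raise ValueError("max_mean_imd must be positive")


def intermutation_distances(snvs: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome sorted SNVs with distance to the previous SNV.

    The first SNV of each chromosome has IMD NaN (undefined); duplicated
    positions yield IMD 0. Input order is irrelevant.
    """
    cols = ["chrom", "pos"]
    df = snvs.copy()
    if "ref" in df.columns and "alt" in df.columns:
        mask = (df["ref"].astype(str).str.len() == 1) & (df["alt"].astype(str).str.len() == 1)
        df = df[mask]
        df["sub_class"] = [substitution_class(r, a) for r, a in zip(df["ref"], df["alt"])]
        cols = ["chrom", "pos", "sub_class"]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    imd = df.groupby("chrom")["pos"].diff().astype(float)
    out = df[cols].copy()
    out["imd"] = imd
    return out


def detect_kataegis(points: pd.DataFrame, params: KataegisParams = KataegisParams()) -> pd.DataFrame:
    """Merge qualifying sliding windows into maximal hypermutation regions.

    Returns one row per region: chrom, start, end, n_mutations, mean_imd
    (recomputed over the merged members) and member row positions into the
    sorted ``points`` frame.
    """
    regions = []
    w = params.min_count
    for chrom, grp in points.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        if len(pos) < w:
            continue
        d = np.diff(pos).astype(float)
        # mean of the (w-1) internal IMDs of each window of w consecutive SNVs
        kernel = np.ones(w - 1) / (w - 1)
        win_mean = np.convolve(d, kernel, mode="valid")
        ok = win_mean <= params.max_mean_imd
        if not ok.any():
            continue
        # merge overlapping qualifying windows [i, i+w-1]
        start_i = None
        last_end = None
        for i in np.flatnonzero(ok):
            if start_i is None:
                start_i, last_end = i, i + w - 1
            elif i <= last_end:  # overlaps or abuts the current merge
                last_end = i + w - 1
            else:
                regions.append(_region(chrom, pos, idx, start_i, last_end))
                start_i, last_end = i, i + w - 1
        regions.append(_region(chrom, pos, idx, start_i, last_end))
    cols = ["chrom", "start", "end", "n_mutations", "mean_imd", "members"]
    return pd.DataFrame(regions, columns=cols)


def _region(chrom, pos, idx, i, j):
    members = idx[i: j + 1]
    span = pos[i: j + 1]
    return {
        "chrom": chrom,
        "start": int(span[0]),
        "end": int(span[-1]),
        "n_mutations": int(j - i + 1),
        "mean_imd": float(np.diff(span).mean()),
        "members": list(members),
    }


def annotate_regions(regions: pd.DataFrame, gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """Attach overlapping gene symbols to each region.

    ``gene_intervals`` uses BED convention (0-based half-open: gene, chrom,
    start, end); regions use 1-based variant positions. A gene is attached
    iff its interval intersects the region's [start, end].
    """
    out = regions.copy()
    genes_col = []
    for reg in out.itertuples(index=False):
        hits = gene_intervals[
            (gene_intervals["chrom"] == reg.chrom)
            & (gene_intervals["start"] + 1 <= reg.end)   # BED start -> 1-based
            & (gene_intervals["end"] >= reg.start)
        ]
        genes_col.append(sorted(hits["gene"].unique()))
    out["genes"] = genes_col
    return out
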