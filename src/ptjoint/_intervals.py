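"""Vectorized interval overlap primitives shared across modules.

Interval queries here come in two flavours: membership of query ranges in a
merged interval set (FRiP-style, each query counted once) and per-interval
overlap counts against a large sorted range set (RPKM-style).  Both reduce
to searchsorted on sorted endpoint arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenomicInterval


def intervals_to_frame(intervals) -> pd.DataFrame:
    """Normalize a list of GenomicInterval (or a frame) to a DataFrame."""
    if isinstance(intervals, pd.DataFrame):
        return intervals
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.name for iv in intervals],
        }
    )


def merge_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping intervals; returns per-chrom (starts, ends) sorted."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        out_s, out_e = [], []
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:
                cur_e = max(cur_e, e[i])
            else:
                out_s.append(cur_s)
                out_e.append(cur_e)
                cur_s, cur_e = s[i], e[i]
        out_s.append(cur_s)
        out_e.append(cur_e)
        merged[chrom] = (np.asarray(out_s), np.asarray(out_e))
    return merged


def ranges_overlap_any(
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    intervals,
) -> np.ndarray:
    """For each query range, whether it intersects >=1 bp of the interval set."""
    df = intervals_to_frame(intervals)
    hit = np.zeros(len(chroms), dtype=bool)
    if df.empty or len(chroms) == 0:
        return hit
    merged = merge_intervals(df)
    chroms = np.asarray(chroms)
    for chrom, (ms, me) in merged.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        qs = np.asarray(starts)[mask]
        qe = np.asarray(ends)[mask]
        # first merged interval with end > query start; overlap iff its
        # start < query end
        idx = np.searchsorted(me, qs, side="right")
        ok = idx < len(ms)
        sub = np.zeros(len(qs), dtype=bool)
        sub[ok] = ms[idx[ok]] < qe[ok]
        hit[mask] = sub
    return hit


def count_range_overlaps(
    intervals,
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """For each interval, count query ranges intersecting it (>=1 bp).

    A range [s, e) overlaps [S, E) iff s < E and e > S, so the count is
    #(s < E) - #(e <= S) over the per-chromosome sorted endpoint arrays.
    """
    df = intervals_to_frame(intervals).reset_index(drop=True)
    counts = np.zeros(len(df), dtype=np.int64)
    chroms = np.asarray(chroms)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        by_chrom[chrom] = (
            np.sort(np.asarray(starts)[mask]),
            np.sort(np.asarray(ends)[mask]),
        )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        s_sorted, e_sorted = by_chrom[chrom]
        n_start = np.searchsorted(s_sorted, sub["end"].to_numpy(), side="left")
        n_end = np.searchsorted(e_sorted, sub["start"].to_numpy(), side="right")
        counts[sub.index.to_numpy()] = n_start - n_end
    return counts


def interval_list(df: pd.DataFrame) -> list[GenomicInterval]:
    names = df["name"] if "name" in df.columns else [None] * len(df)
    summits = df["summit"] if "summit" in df.columns else [None] * len(df)
    return [
        GenomicInterval(c, int(s), int(e), nm, None if sm is None else int(sm))
        for c, s, e, nm, sm in zip(
            df["chrom"], df["start"], df["end"], names, summits
        )
    ]
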