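"""Pseudo-bulk chromatin-signal quantification and peak calling.

The caller emulates the shift/extension smoothing of Tn5 insertion data:
each fragment end is an insertion site, extended to a fixed-size window
(default shift -75, extsize 150, i.e. a 150-bp window centered on the
site), accumulated on a step grid.  Candidate windows are scored with a
one-sided Poisson upper tail against the larger of the genome-wide rate
and a local 10-kb background, corrected by Benjamini-Hochberg, and merged
into peaks.  Replicate-level calls are merged by the
retained-in->=2-replicates rule with summits extended to a fixed 500-bp
width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import (
    count_range_overlaps,
    intervals_to_frame,
    ranges_overlap_any,
)
from .io import FragmentSet, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-chromosome smoothed insertion coverage on a step grid.

    Values are mean per-base depth within each step bin, so the total mass
    sums to 2 x n_fragments x extsize / step up to boundary clipping.
    """

    step: int
    values: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    total_insertions: int
    extsize: int

    @property
    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


@dataclass
class PeakCall:
    """Called peaks for one track: intervals with summit and q-value."""

    peaks: pd.DataFrame  # chrom, start, end, summit, qvalue
    mode: str
    replicate: int | str | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), summit=int(r.summit))
            for r in self.peaks.itertuples(index=False)
        ]


@dataclass
class SaturationCurve:
    table: pd.DataFrame  # n_nuclei, n_peaks, fraction_recovered
    cutoff_nuclei: int | None
    recovery_target: float


# ---------------------------------------------------------------------------
# pseudo-bulk
# ---------------------------------------------------------------------------

def pseudobulk(
    frags: FragmentSet, groups: Mapping[str, str] | Iterable[str]
) -> dict[str, FragmentSet]:
    """Partition fragments by barcode group.

    ``groups`` is either a barcode -> group label mapping or a plain
    barcode collection (one group named "all").  Fragments from unlabeled
    barcodes are dropped.
    """
    if not frags.deduplicated:
        raise ValueError("pseudobulk requires deduplicated fragments")
    if not isinstance(groups, Mapping):
        groups = {bc: "all" for bc in groups}
    labels = frags.data["barcode"].map(groups)
    out: dict[str, FragmentSet] = {}
    for group in sorted(set(groups.values())):
        sub = frags.data.loc[labels == group].reset_index(drop=True)
        out[group] = FragmentSet(sub, dict(frags.chrom_sizes), True)
    return out


# ---------------------------------------------------------------------------
# coverage and peak calling
# ---------------------------------------------------------------------------

def insertion_coverage(
    frags: FragmentSet,
    extsize: int = 150,
    shift: int = -75,
    step: int = 10,
) -> CoverageTrack:
    """Smoothed insertion coverage.

    Each fragment contributes two insertion events (start and end-1); each
    is extended to [site+shift, site+shift+extsize) and accumulated at
    base resolution, then averaged over the step grid.
    """
    values: dict[str, np.ndarray] = {}
    df = frags.data
    total_insertions = 0
    for chrom, size in frags.chrom_sizes.items():
        n_bins = -(-size // step)
        sub = df.loc[df["chrom"] == chrom]
        if sub.empty:
            values[chrom] = np.zeros(n_bins)
            continue
        sites = np.concatenate(
            [sub["start"].to_numpy(), sub["end"].to_numpy() - 1]
        )
        total_insertions += len(sites)
        a = np.clip(sites + shift, 0, size)
        b = np.clip(sites + shift + extsize, 0, size)
        diff = np.zeros(size + 1, dtype=np.int32)
        np.add.at(diff, a, 1)
        np.add.at(diff, b, -1)
        depth = np.cumsum(diff[:-1])
        pad = n_bins * step - size
        if pad:
            depth = np.concatenate([depth, np.zeros(pad, dtype=depth.dtype)])
        values[chrom] = depth.reshape(n_bins, step).sum(axis=1) / step
    return CoverageTrack(
        step=step,
        values=values,
        chrom_sizes=dict(frags.chrom_sizes),
        total_insertions=total_insertions,
        extsize=extsize,
    )


def call_peaks(
    track: CoverageTrack,
    mode: str = "narrow",
    q_cutoff: float = 0.01,
    broad_merge_gap: int = 1000,
    local_background_bp: int = 10_000,
    replicate: int | str | None = None,
) -> PeakCall:
    """Poisson window caller with BH correction.

    Per step bin, the insertion depth is tested against
    lambda = max(genome-wide expected depth, local 10-kb mean); bins with
    BH q < q_cutoff are merged into peaks when separated by at most 100 bp
    (narrow) or ``broad_merge_gap`` (broad).  Deterministic.
    """
    if mode not in ("narrow", "broad"):
        raise ValueError("mode must be 'narrow' or 'broad'")
    genome_len = sum(track.chrom_sizes.values())
    if genome_len == 0:
        raise ValueError("empty track")
    lam_global = 2.0 * (track.total_insertions / 2) * track.extsize / genome_len
    merge_gap = 100 if mode == "narrow" else broad_merge_gap

    chroms, counts, lams = [], [], []
    for chrom, vals in track.values.items():
        k = np.rint(vals).astype(np.int64)
        w = max(1, local_background_bp // track.step)
        local = _centered_mean(vals, w)
        lam = np.maximum(lam_global, local)
        chroms.append(chrom)
        counts.append(k)
        lams.append(lam)

    pvals = np.concatenate(
        [stats.poisson.sf(k - 1, lam) for k, lam in zip(counts, lams)]
    )
    qvals = _bh(pvals)

    rows = []
    offset = 0
    for chrom, k in zip(chroms, counts):
        n = len(k)
        q = qvals[offset : offset + n]
        vals = track.values[chrom]
        offset += n
        sig = np.where((q < q_cutoff) & (k > 0))[0]
        if len(sig) == 0:
            continue
        gap_bins = max(1, merge_gap // track.step)
        breaks = np.where(np.diff(sig) > gap_bins)[0]
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [len(sig) - 1]])
        for rs, re in zip(run_starts, run_ends):
            bins = sig[rs : re + 1]
            start = int(bins[0]) * track.step
            end = min(
                (int(bins[-1]) + 1) * track.step, track.chrom_sizes[chrom]
            )
            summit_bin = bins[np.argmax(vals[bins])]
            summit = min(
                int(summit_bin) * track.step + track.step // 2, end - 1
            )
            rows.append(
                dict(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    qvalue=float(q[bins].min()),
                )
            )
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit", "qvalue"]
    )
    return PeakCall(peaks=peaks, mode=mode, replicate=replicate)


def _centered_mean(vals: np.ndarray, w: int) -> np.ndarray:
    """Mean over a centered window of ~w bins (edges shrink)."""
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    n = len(vals)
    idx = np.arange(n)
    lo = np.maximum(idx - w // 2, 0)
    hi = np.minimum(idx + w // 2 + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# replicate-reproducible merging
# ---------------------------------------------------------------------------

def merge_reproducible(
    calls: list[PeakCall],
    min_replicates: int = 2,
    width: int = 500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Keep peaks reproduced in >= min_replicates replicates; fix width.

    A peak is retained iff its interval overlaps peaks from at least
    ``min_replicates`` distinct replicates (itself included).  Retained
    summits are extended to ``width`` bp; overlapping extended intervals
    are collapsed keeping the summit of the call with the smallest
    q-value.  Output intervals are exactly ``width`` wide except where
    clipped at chromosome edges.
    """
    if len(calls) < min_replicates:
        raise ValueError(
            f"need >= {min_replicates} replicate calls, got {len(calls)}"
        )
    frames = []
    for i, call in enumerate(calls):
        df = call.peaks.copy()
        df["replicate"] = call.replicate if call.replicate is not None else i
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        return []

    support = np.zeros(len(pooled), dtype=int)
    for rep, sub in pooled.groupby("replicate"):
        support += ranges_overlap_any(
            pooled["chrom"].to_numpy(),
            pooled["start"].to_numpy(),
            pooled["end"].to_numpy(),
            sub[["chrom", "start", "end"]],
        ).astype(int)
    retained = pooled.loc[support >= min_replicates].copy()
    if retained.empty:
        return []

    half = width // 2
    retained["ext_start"] = retained["summit"] - half
    retained["ext_end"] = retained["summit"] + (width - half)
    retained["ext_start"] = retained["ext_start"].clip(lower=0)
    if chrom_sizes:
        caps = retained["chrom"].map(chrom_sizes)
        retained["ext_end"] = np.minimum(retained["ext_end"], caps)

    # collapse: best q first, greedily reject overlaps with accepted peaks
    retained = retained.sort_values(
        ["qvalue", "chrom", "ext_start"], kind="mergesort"
    )
    accepted: dict[str, list[tuple[int, int, int]]] = {}
    for row in retained.itertuples(index=False):
        bucket = accepted.setdefault(row.chrom, [])
        if any(s < row.ext_end and e > row.ext_start for s, e, _ in bucket):
            continue
        bucket.append((int(row.ext_start), int(row.ext_end), int(row.summit)))
    out: list[GenomicInterval] = []
    i = 0
    for chrom in sorted(accepted):
        for s, e, summit in sorted(accepted[chrom]):
            out.append(
                GenomicInterval(chrom, s, e, name=f"peak_{i:05d}", summit=summit)
            )
            i += 1
    return out


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify_rpkm(
    frags_by_group: Mapping[str, FragmentSet], intervals
) -> pd.DataFrame:
    """RPKM matrix (intervals x groups).

    RPKM[i, g] = overlapping-fragment count / (interval kb x group
    fragments / 1e6).  A fragment counts once per interval it intersects.
    """
    df = intervals_to_frame(intervals)
    if "name" in df.columns and df["name"].notna().all():
        index = pd.Index(df["name"], name="interval")
    else:
        index = pd.Index(
            [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)],
            name="interval",
        )
    len_kb = (df["end"] - df["start"]).to_numpy() / 1_000.0
    out = {}
    for group, frags in frags_by_group.items():
        if not frags.deduplicated:
            raise ValueError("quantify_rpkm requires deduplicated fragments")
        total = len(frags)
        if total == 0:
            logger.warning("group %s has no fragments; RPKM column is zero", group)
            out[group] = np.zeros(len(df))
            continue
        counts = count_range_overlaps(
            df,
            frags.data["chrom"].to_numpy(),
            frags.data["start"].to_numpy(),
            frags.data["end"].to_numpy(),
        )
        out[group] = counts / (len_kb * (total / 1e6))
    return pd.DataFrame(out, index=index)


def profile_matrix(
    frags: FragmentSet,
    anchors,
    flank: int = 2000,
    bin_size: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Insertion counts in bins of +/-flank around anchor centers.

    Anchors are GenomicIntervals (center used) or GeneRecords (TSS used,
    profile flipped for - strand).  Returns (anchors x bins matrix, mean
    profile normalized by the flank-edge background).
    """
    positions: dict[str, np.ndarray] = {}
    for chrom, sub in frags.data.groupby("chrom", sort=False):
        sites = np.concatenate(
            [sub["start"].to_numpy(), sub["end"].to_numpy() - 1]
        )
        positions[chrom] = np.sort(sites)
    n_bins = 2 * flank // bin_size
    mat = np.zeros((len(anchors), n_bins))
    for i, anchor in enumerate(anchors):
        if hasattr(anchor, "tss"):
            chrom, center, flip = anchor.chrom, anchor.tss, anchor.strand == "-"
        else:
            chrom, center, flip = anchor.chrom, anchor.center, False
        sites = positions.get(chrom)
        if sites is None:
            continue
        edges = center - flank + bin_size * np.arange(n_bins + 1)
        counts = np.diff(np.searchsorted(sites, edges))
        mat[i] = counts[::-1] if flip else counts
    mean = mat.mean(axis=0) if len(anchors) else np.zeros(n_bins)
    edge = max(1, n_bins // 20)
    background = np.concatenate([mean[:edge], mean[-edge:]]).mean()
    norm = mean / background if background > 0 else mean
    return mat, norm


NUCLEOSOME_BANDS = {
    "subnucleosomal": (0, 147),
    "mono": (147, 295),
    "di": (295, 442),
    "tri": (442, 736),
    "longer": (736, np.inf),
}


def fragment_size_stats(
    frags: FragmentSet, max_length: int = 1000, hist_bin: int = 10
) -> dict:
    """Fragment-length histogram and nucleosomal band fractions.

    Bands at multiples of the 147-bp nucleosomal unit: subnucleosomal
    (<147), mono (147-294), di (295-441), tri (442-735, covering the
    ~600-bp trinucleosome mode), longer.
    """
    if len(frags) == 0:
        raise ValueError("fragment_size_stats requires a nonempty FragmentSet")
    lengths = (frags.data["end"] - frags.data["start"]).to_numpy()
    fractions = {
        band: float(((lengths >= lo) & (lengths < hi)).mean())
        for band, (lo, hi) in NUCLEOSOME_BANDS.items()
    }
    counts, edges = np.histogram(
        lengths, bins=np.arange(0, max_length + hist_bin, hist_bin)
    )
    return {"fractions": fractions, "histogram": (counts, edges)}


def peak_overlap(a, b) -> tuple[float, int, int]:
    """Fraction and count of a-peaks intersecting >=1 bp of any b-peak."""
    df = intervals_to_frame(a)
    if df.empty:
        return 0.0, 0, 0
    hits = ranges_overlap_any(
        df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy(), b
    )
    return float(hits.mean()), int(hits.sum()), len(df)


def downsample_saturation(
    frags: FragmentSet,
    full_peaks,
    n_grid: Iterable[int],
    recovery_target: float = 0.85,
    seed: int = 0,
    mode: str = "narrow",
    q_cutoff: float = 0.01,
    step: int = 10,
) -> SaturationCurve:
    """Peak recovery as a function of sampled nuclei.

    For each grid size, sample barcodes without replacement, re-call peaks
    on their fragments and record the fraction of ``full_peaks``
    overlapped.  ``cutoff_nuclei`` is the smallest grid point reaching the
    recovery target.
    """
    rng = np.random.default_rng(seed)
    barcodes = np.sort(frags.data["barcode"].unique())
    full_df = intervals_to_frame(full_peaks)
    rows = []
    for n in n_grid:
        n_eff = int(min(n, len(barcodes)))
        if n_eff < n:
            logger.warning(
                "grid point %d exceeds %d available nuclei; clipped",
                n,
                len(barcodes),
            )
        chosen = rng.choice(barcodes, size=n_eff, replace=False)
        sub = frags.subset_barcodes(chosen)
        track = insertion_coverage(sub, step=step)
        called = call_peaks(track, mode=mode, q_cutoff=q_cutoff)
        if len(full_df):
            hit = ranges_overlap_any(
                full_df["chrom"].to_numpy(),
                full_df["start"].to_numpy(),
                full_df["end"].to_numpy(),
                called.peaks[["chrom", "start", "end"]],
            )
            frac = float(hit.mean())
        else:
            frac = 0.0
        rows.append(
            dict(n_nuclei=n_eff, n_peaks=len(called), fraction_recovered=frac)
        )
    table = pd.DataFrame(rows)
    qualifying = table.loc[table["fraction_recovered"] >= recovery_target]
    cutoff = int(qualifying["n_nuclei"].min()) if len(qualifying) else None
    return SaturationCurve(table, cutoff, recovery_target)
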