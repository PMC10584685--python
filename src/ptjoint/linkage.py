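"""Linking distal cCREs to putative target genes.

Candidate pairs are distal cCREs within 500 kb of a gene's TSS.  A
transparent co-occupancy prefilter (metacell correlation of binarized
per-cell signal at the distal cCRE and at the gene's proximal anchor,
threshold 0.1) removes pairs with no evidence of joint activity.  The
linkage statistic is Spearman's correlation (SCC) between the mark's
signal at the cCRE and the gene's expression across pseudo-bulk columns.
The null is built by shuffling cell identities: cluster labels are
permuted across cells, both cluster-level matrices are rebuilt and SCCs
recomputed.  A normal distribution fitted to the pooled background sets
the SCC cutoff at the requested FDR; the Kolmogorov-Smirnov D statistic
summarizes how far observed links sit from the background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import CountMatrix, FragmentSet, GeneRecord


@dataclass
class NullFit:
    """Fitted-normal FDR threshold for one direction."""

    mu0: float
    sigma0: float
    cutoff: float | None  # None when no threshold achieves the FDR
    significant: np.ndarray  # bool per observed value (NaN -> False)
    fdr_curve: pd.DataFrame  # columns: score, fdr (monotone non-increasing)
    min_fdr: float
    direction: str


# ---------------------------------------------------------------------------
# candidates and co-occupancy
# ---------------------------------------------------------------------------

def candidate_pairs(
    ccres: pd.DataFrame,
    genes: Sequence[GeneRecord],
    max_dist: int = 500_000,
) -> pd.DataFrame:
    """All (distal cCRE, gene) pairs with center-to-TSS distance <= max_dist.

    ``ccres`` needs columns chrom/start/end and ccre_class; only distal
    cCREs are paired (distal-to-proximal comparisons only).
    """
    distal = ccres.loc[ccres["ccre_class"] == "distal"]
    centers = ((distal["start"] + distal["end"]) // 2).to_numpy()
    chroms = distal["chrom"].to_numpy()
    names = distal.index.to_numpy()
    rows = []
    for g in genes:
        mask = chroms == g.chrom
        dist = np.abs(centers - g.tss)
        hit = mask & (dist <= max_dist)
        for name, d in zip(names[hit], dist[hit]):
            rows.append(dict(ccre=name, gene=g.gene_id, distance=int(d)))
    return pd.DataFrame(rows, columns=["ccre", "gene", "distance"])


def cell_interval_counts(frags: FragmentSet, intervals) -> CountMatrix:
    """Cells x intervals fragment-overlap counts (one count per interval)."""
    from ._intervals import intervals_to_frame

    if not frags.deduplicated:
        raise ValueError("cell_interval_counts requires deduplicated fragments")
    ivals = intervals_to_frame(intervals)
    df = frags.data
    barcodes = sorted(df["barcode"].unique())
    bc_codes = {b: i for i, b in enumerate(barcodes)}
    names = (
        list(ivals["name"])
        if "name" in ivals.columns and ivals["name"].notna().all()
        else [f"{c}:{s}-{e}" for c, s, e in zip(ivals.chrom, ivals.start, ivals.end)]
    )
    mat = sp.lil_matrix((len(barcodes), len(ivals)), dtype=np.int64)
    max_len = int((df["end"] - df["start"]).max()) if len(df) else 0
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        codes = sub["barcode"].map(bc_codes).to_numpy()
        here = ivals.index[ivals["chrom"] == chrom]
        for col in here:
            s, e = int(ivals.at[col, "start"]), int(ivals.at[col, "end"])
            lo = np.searchsorted(starts, s - max_len)
            hi = np.searchsorted(starts, e)
            if hi <= lo:
                continue
            cand = slice(lo, hi)
            keep = ends[cand] > s
            if not keep.any():
                continue
            counted = np.bincount(codes[cand][keep], minlength=len(barcodes))
            col_pos = ivals.index.get_loc(col)
            nz = np.nonzero(counted)[0]
            mat[nz, col_pos] = counted[nz]
    return CountMatrix(mat.tocsr(), barcodes, names)


def cooccupancy_filter(
    pairs: pd.DataFrame,
    cell_by_ccre: CountMatrix,
    cell_by_gene: CountMatrix,
    labels: Mapping[str, str],
    threshold: float = 0.1,
    group_size: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Retain pairs whose metacell co-occupancy correlation exceeds threshold.

    Cells are grouped into within-cluster metacells of ``group_size``
    (seeded); per metacell the binarized (count > 0) signal is averaged,
    and the score is the Pearson correlation across metacells between the
    distal cCRE and the gene's proximal anchor.  ``threshold=-1`` disables
    the prefilter (all pairs pass, scores still reported).
    """
    if list(cell_by_ccre.row_labels) != list(cell_by_gene.row_labels):
        raise ValueError("cell_by_ccre and cell_by_gene must share barcodes")
    groups = _metacell_groups(cell_by_ccre.row_labels, labels, group_size, seed)
    if len(groups) < 3:
        raise ValueError("need >= 3 metacells for co-occupancy correlation")
    ccre_frac = _metacell_binary_fraction(cell_by_ccre, groups)
    gene_frac = _metacell_binary_fraction(cell_by_gene, groups)
    ccre_idx = {n: i for i, n in enumerate(cell_by_ccre.col_labels)}
    gene_idx = {n: i for i, n in enumerate(cell_by_gene.col_labels)}

    x = ccre_frac - ccre_frac.mean(axis=0)
    y = gene_frac - gene_frac.mean(axis=0)
    x_norm = np.sqrt((x**2).sum(axis=0))
    y_norm = np.sqrt((y**2).sum(axis=0))
    scores = np.full(len(pairs), np.nan)
    for k, row in enumerate(pairs.itertuples(index=False)):
        i, j = ccre_idx[row.ccre], gene_idx[row.gene]
        denom = x_norm[i] * y_norm[j]
        if denom > 0:
            scores[k] = float((x[:, i] * y[:, j]).sum() / denom)
    out = pairs.copy()
    out["cooccupancy"] = scores
    keep = np.where(np.isnan(scores), False, scores > threshold)
    if threshold <= -1:
        keep = np.ones(len(pairs), dtype=bool)
    return out.loc[keep].reset_index(drop=True)


def _metacell_groups(
    barcodes: Sequence[str],
    labels: Mapping[str, str],
    group_size: int,
    seed: int,
) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    by_cluster: dict[str, list[int]] = {}
    for i, bc in enumerate(barcodes):
        lab = labels.get(bc)
        if lab is not None:
            by_cluster.setdefault(lab, []).append(i)
    groups = []
    for lab in sorted(by_cluster):
        idx = np.array(by_cluster[lab])
        rng.shuffle(idx)
        for k in range(0, len(idx), group_size):
            chunk = idx[k : k + group_size]
            if len(chunk) >= max(2, group_size // 2):
                groups.append(chunk)
    return groups


def _metacell_binary_fraction(
    matrix: CountMatrix, groups: list[np.ndarray]
) -> np.ndarray:
    binary = (matrix.values > 0).astype(float)
    out = np.empty((len(groups), binary.shape[1]))
    for gi, idx in enumerate(groups):
        out[gi] = np.asarray(binary[idx].mean(axis=0)).ravel()
    return out


# ---------------------------------------------------------------------------
# Spearman statistics
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    NaN when either vector is constant (reported missing downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need >= 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman between paired rows of two matrices."""
    rx = stats.rankdata(x, axis=1).astype(float)
    ry = stats.rankdata(y, axis=1).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / denom, np.nan)
    return out


def observed_linkage(
    pairs: pd.DataFrame,
    ccre_signal: pd.DataFrame,
    expr_signal: pd.DataFrame,
) -> pd.Series:
    """SCC per candidate pair over shared pseudo-bulk columns.

    Both matrices must share the same column set (clusters, or cluster x
    replicate pseudo-bulks); pairs with a constant vector get NaN.
    """
    cols = [c for c in ccre_signal.columns if c in set(expr_signal.columns)]
    if len(cols) < 3:
        raise ValueError("need >= 3 shared signal columns")
    x = ccre_signal.loc[pairs["ccre"], cols].to_numpy()
    y = expr_signal.loc[pairs["gene"], cols].to_numpy()
    return pd.Series(_spearman_rows(x, y), index=pairs.index, name="scc")


# ---------------------------------------------------------------------------
# shuffled-identity background
# ---------------------------------------------------------------------------

def cluster_signals(
    cell_by_ccre: CountMatrix,
    ccre_len_kb: np.ndarray,
    cell_frag_totals: np.ndarray,
    expr_norm: np.ndarray,
    gene_ids: Sequence[str],
    group_of_cell: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate cell-level matrices to group-level (RPKM, mean expression).

    ``group_of_cell`` is a label per cell (aligned to the matrix rows);
    cells with empty labels are excluded.
    """
    keep = group_of_cell != ""
    groups = np.unique(group_of_cell[keep])
    indicator = sp.csr_matrix(
        (
            np.ones(int(keep.sum())),
            (
                pd.Categorical(group_of_cell[keep], categories=groups).codes,
                np.where(keep)[0],
            ),
        ),
        shape=(len(groups), len(group_of_cell)),
    )
    ccre_counts = np.asarray((indicator @ cell_by_ccre.values).todense())
    totals = indicator @ cell_frag_totals
    with np.errstate(invalid="ignore", divide="ignore"):
        rpkm = ccre_counts / (totals[:, None] / 1e6) / ccre_len_kb[None, :]
    rpkm = np.nan_to_num(rpkm)
    sizes = np.asarray(indicator.sum(axis=1)).ravel()
    expr_mean = (indicator @ expr_norm) / sizes[:, None]
    ccre_signal = pd.DataFrame(
        rpkm.T, index=cell_by_ccre.col_labels, columns=groups
    )
    expr_signal = pd.DataFrame(expr_mean.T, index=list(gene_ids), columns=groups)
    return ccre_signal, expr_signal


def shuffled_background(
    pairs: pd.DataFrame,
    cell_by_ccre: CountMatrix,
    ccre_len_kb: np.ndarray,
    cell_frag_totals: np.ndarray,
    expr_counts: np.ndarray,
    gene_ids: Sequence[str],
    group_of_cell: np.ndarray,
    n_shuffles: int = 10,
    seed: int = 0,
    scale: float = 1e4,
) -> np.ndarray:
    """Pooled background SCC sample from shuffled read identities.

    Cell identities are shuffled at the read level: each shuffle
    reallocates every cCRE's fragment count across pseudo-bulk groups by a
    multinomial proportional to group sequencing depth (the exact
    aggregate of assigning each read a random cell), and every gene's UMI
    total across cells proportional to library size, then rebuilds both
    group-level matrices and recomputes the SCC for every pair.  The
    pooled sample has ~n_shuffles x n_pairs values (NaNs dropped).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    keep = group_of_cell != ""
    groups = np.unique(group_of_cell[keep])
    group_codes = pd.Categorical(
        group_of_cell[keep], categories=groups
    ).codes
    n_groups = len(groups)

    dna = np.asarray(cell_by_ccre.values[keep].todense(), dtype=np.int64)
    ccre_totals = dna.sum(axis=0)  # reads per cCRE
    group_depth = np.bincount(
        group_codes, weights=cell_frag_totals[keep], minlength=n_groups
    )
    p_group = group_depth / group_depth.sum()

    counts = np.asarray(expr_counts[keep], dtype=np.int64)
    libs = counts.sum(axis=1).astype(float)
    p_cell = libs / libs.sum()
    gene_totals = counts.sum(axis=0)
    indicator = np.zeros((n_groups, int(keep.sum())))
    indicator[group_codes, np.arange(int(keep.sum()))] = 1.0
    group_sizes = indicator.sum(axis=1)

    pooled = []
    for _ in range(n_shuffles):
        # DNA: reads at each cCRE scattered over groups by depth share
        dna_shuf = rng.multinomial(ccre_totals, p_group)  # ccres x groups
        with np.errstate(invalid="ignore", divide="ignore"):
            rpkm = dna_shuf / (group_depth[None, :] / 1e6) / ccre_len_kb[:, None]
        ccre_sig = pd.DataFrame(
            np.nan_to_num(rpkm), index=cell_by_ccre.col_labels, columns=groups
        )
        # RNA: each gene's UMIs scattered over cells by library share
        rna_shuf = rng.multinomial(gene_totals, p_cell).T  # cells x genes
        norm = np.log1p(scale * rna_shuf / np.maximum(libs, 1.0)[:, None])
        expr_mean = (indicator @ norm) / group_sizes[:, None]
        expr_sig = pd.DataFrame(expr_mean.T, index=list(gene_ids), columns=groups)
        scc = observed_linkage(pairs, ccre_sig, expr_sig)
        pooled.append(scc.to_numpy())
    out = np.concatenate(pooled)
    return out[~np.isnan(out)]


# ---------------------------------------------------------------------------
# fitted-normal FDR threshold and KS separation
# ---------------------------------------------------------------------------

def fit_null_threshold(
    observed: Sequence[float],
    background: Sequence[float],
    fdr: float = 0.05,
    direction: str = "positive",
) -> NullFit:
    """Empirical significance cutoff from a normal fit to the background.

    mu0/sigma0 are background moments.  For the positive direction, the
    estimated FDR at score s is
    n_obs * P_N(mu0,sigma0)(X >= s) / #{observed >= s}, monotonized to be
    non-increasing in s; the cutoff is the smallest observed s with
    FDR < fdr and significance means observed >= cutoff.  The negative
    direction mirrors with the lower tail.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    observed = np.asarray(observed, dtype=float)
    background = np.asarray(background, dtype=float)
    background = background[~np.isnan(background)]
    if len(background) < 100:
        raise ValueError("background sample too small (< 100)")
    mu0 = float(background.mean())
    sigma0 = float(background.std(ddof=1))
    if sigma0 <= 0:
        raise ValueError("degenerate background (zero variance)")

    sign = 1.0 if direction == "positive" else -1.0
    obs = sign * observed
    mu_t = sign * mu0
    valid = ~np.isnan(obs)
    vals = np.sort(obs[valid])  # ascending
    n_obs = len(vals)
    if n_obs == 0:
        raise ValueError("no valid observed values")
    # candidates are the observed values; exceed counts by position
    n_exceed = n_obs - np.arange(n_obs)
    tail = stats.norm.sf((vals - mu_t) / sigma0)
    raw = np.minimum(n_obs * tail / n_exceed, 1.0)
    # monotonize: estimated FDR never increases as the threshold rises
    mono = np.minimum.accumulate(raw)

    passing = np.where(mono < fdr)[0]
    if len(passing):
        cutoff_t = float(vals[passing[0]])
        cutoff = sign * cutoff_t
        significant = np.where(valid, obs >= cutoff_t, False)
    else:
        cutoff = None
        significant = np.zeros(len(obs), dtype=bool)
    curve = pd.DataFrame({"score": sign * vals, "fdr": mono})
    return NullFit(
        mu0=mu0,
        sigma0=sigma0,
        cutoff=cutoff,
        significant=significant,
        fdr_curve=curve,
        min_fdr=float(mono.min()),
        direction=direction,
    )


def ks_separation(
    observed: Sequence[float], background: Sequence[float]
) -> float:
    """Two-sample Kolmogorov-Smirnov D between observed and background."""
    observed = np.asarray(observed, dtype=float)
    background = np.asarray(background, dtype=float)
    observed = observed[~np.isnan(observed)]
    background = background[~np.isnan(background)]
    if len(observed) == 0 or len(background) == 0:
        raise ValueError("both samples must be nonempty")
    return float(stats.ks_2samp(observed, background).statistic)
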