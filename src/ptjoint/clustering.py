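"""Modality-specific normalization, clustering and concordance statistics.

Chromatin cells are represented as cell x 5-kb-bin matrices (midpoint
assignment, so row sums equal per-cell fragment counts), depth-normalized
with a two-step TF-IDF, restricted to the top 85% of bins by total count
and reduced by truncated SVD (the first, depth-correlated component is
dropped for the histone modality).  RNA cells are depth-normalized
(log1p of counts-per-scale), restricted to the most dispersed genes and
reduced by PCA-style SVD.  Clustering defaults to k-means on the
embedding for determinism.  Concordance between modalities is summarized
by per-cluster overlap coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD

from ._intervals import count_range_overlaps
from .io import CountMatrix, FragmentSet, GeneRecord

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Cells x components scores from a linear reduction."""

    scores: np.ndarray
    row_labels: list[str]
    method: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores).all():
            raise ValueError("embedding contains non-finite values")


# ---------------------------------------------------------------------------
# bin matrix and TF-IDF
# ---------------------------------------------------------------------------

def build_bin_matrix(frags: FragmentSet, bin_size: int = 5000) -> CountMatrix:
    """Cell x bin counts with midpoint assignment.

    Each fragment lands once in the bin containing floor((start+end)/2),
    so per-cell row sums equal the cell's fragment count exactly.
    """
    if not frags.deduplicated:
        raise ValueError("build_bin_matrix requires deduplicated fragments")
    chroms = sorted(frags.chrom_sizes)
    bin_offsets = {}
    col_labels: list[str] = []
    offset = 0
    for chrom in chroms:
        n_bins = -(-frags.chrom_sizes[chrom] // bin_size)
        bin_offsets[chrom] = offset
        col_labels.extend(
            f"{chrom}:{i * bin_size}-{min((i + 1) * bin_size, frags.chrom_sizes[chrom])}"
            for i in range(n_bins)
        )
        offset += n_bins
    df = frags.data
    barcodes = sorted(df["barcode"].unique())
    if not barcodes:
        return CountMatrix(sp.csr_matrix((0, len(col_labels)), dtype=np.int64), [], col_labels)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    cols = (
        df["chrom"].map(bin_offsets).to_numpy() + mid // bin_size
    )
    rows = df["barcode"].map(bc_index).to_numpy()
    mat = sp.coo_matrix(
        (np.ones(len(df), dtype=np.int64), (rows, cols)),
        shape=(len(barcodes), len(col_labels)),
    ).tocsr()
    return CountMatrix(mat, barcodes, col_labels)


def tfidf(bins: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Two-step TF-IDF depth normalization.

    TF is the within-cell frequency, IDF = n_cells / (1 + document
    frequency); the output is log(1 + scale * TF * IDF), invariant to
    scaling any cell's counts by a positive constant.
    """
    mat = bins.values.astype(float)
    row_totals = np.asarray(mat.sum(axis=1)).ravel()
    if (row_totals == 0).any():
        raise ValueError(
            "all-zero cells present; filter cells before TF-IDF"
        )
    tf = sp.diags(1.0 / row_totals) @ mat
    df_counts = np.asarray((mat > 0).sum(axis=0)).ravel()
    idf = mat.shape[0] / (1.0 + df_counts)
    out = tf.multiply(idf).toarray()
    return np.log1p(scale * out)


def select_top_bins(bins: CountMatrix, fraction: float = 0.85) -> np.ndarray:
    """Indices of the top ``ceil(fraction * n_bins)`` bins by total count.

    Ties break by genomic order (lower column index first) so the
    selection is deterministic.
    """
    totals = np.asarray(bins.values.sum(axis=0)).ravel()
    n_keep = int(np.ceil(fraction * len(totals)))
    order = np.lexsort((np.arange(len(totals)), -totals))
    return np.sort(order[:n_keep])


# ---------------------------------------------------------------------------
# reduction and clustering
# ---------------------------------------------------------------------------

def reduce_dimensions(
    matrix: np.ndarray,
    n_components: int = 35,
    drop_first: bool = False,
    seed: int = 0,
    row_labels: list[str] | None = None,
    method: str = "svd",
) -> Embedding:
    """Truncated SVD scores, optionally dropping the first component.

    The first singular component of TF-IDF chromatin matrices tracks
    sequencing depth and is dropped for the histone modality.  Rank
    deficiency yields a reduced-rank embedding with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_ask = n_components + (1 if drop_first else 0)
    max_rank = min(matrix.shape) - 1
    if n_ask > max_rank:
        logger.warning(
            "requested %d components but rank allows %d; reducing", n_ask, max_rank
        )
        n_ask = max_rank
    svd = TruncatedSVD(n_components=n_ask, random_state=seed)
    scores = svd.fit_transform(matrix)
    if drop_first and scores.shape[1] > 1:
        scores = scores[:, 1:]
    if row_labels is None:
        row_labels = [str(i) for i in range(matrix.shape[0])]
    return Embedding(scores, list(row_labels), method)


def cluster_cells(
    embedding: Embedding,
    k: int,
    method: str = "kmeans",
    seed: int = 0,
) -> dict[str, str]:
    """Cluster the embedding into k groups; labels are "c0", "c1", ...

    K-means on the reduced space is the tested, deterministic default; a
    graph-based option can be layered on externally via the LabelMap
    interface.
    """
    if k > len(embedding.row_labels):
        raise ValueError("k exceeds the number of cells")
    if method != "kmeans":
        raise ValueError(f"unsupported clustering method: {method}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        assignments = km.fit_predict(embedding.scores)
    return {
        bc: f"c{a}" for bc, a in zip(embedding.row_labels, assignments)
    }


# ---------------------------------------------------------------------------
# RNA normalization and markers
# ---------------------------------------------------------------------------

def normalize_select_rna(
    counts: CountMatrix, n_top: int = 2500, scale: float = 1e4
) -> tuple[np.ndarray, list[str]]:
    """Depth-normalized log expression and the most variable genes.

    Normalized value = log(1 + scale * count / cell total); variable genes
    are the top ``n_top`` by variance-to-mean dispersion of the normalized
    values (ties by column order).
    """
    mat = counts.values.astype(float).toarray()
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero cells present; filter cells first")
    norm = np.log1p(scale * mat / totals[:, None])
    mean = norm.mean(axis=0)
    var = norm.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    n_keep = min(n_top, norm.shape[1])
    order = np.lexsort((np.arange(len(dispersion)), -dispersion))
    keep = np.sort(order[:n_keep])
    return norm, [counts.col_labels[i] for i in keep]


def marker_genes(
    norm: np.ndarray,
    gene_ids: list[str],
    labels: dict[str, str],
    row_labels: list[str],
    log2fc_min: float = 0.25,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-cluster marker genes by fold change + rank-sum ranking.

    A gene is a marker of cluster c when log2(mean_in + eps) -
    log2(mean_out + eps) >= log2fc_min; candidates are ranked by the
    Mann-Whitney U statistic of in- versus out-of-cluster normalized
    expression.
    """
    label_arr = np.array([labels.get(bc, "") for bc in row_labels])
    clusters = sorted(set(label_arr) - {""})
    if len(clusters) < 2:
        raise ValueError("marker_genes requires >= 2 clusters")
    rows = []
    for cl in clusters:
        mask = label_arr == cl
        mean_in = norm[mask].mean(axis=0)
        mean_out = norm[~mask].mean(axis=0)
        with np.errstate(invalid="ignore"):
            log2fc = np.log2(mean_in + eps) - np.log2(mean_out + eps)
        candidates = np.where(log2fc >= log2fc_min)[0]
        for gi in candidates:
            stat, pval = stats.mannwhitneyu(
                norm[mask, gi], norm[~mask, gi], alternative="greater"
            )
            # scale U to [0, 1] (AUC) so ranking is size-independent
            auc = stat / (mask.sum() * (~mask).sum())
            rows.append(
                dict(
                    cluster=cl,
                    gene=gene_ids[gi],
                    log2fc=float(log2fc[gi]),
                    auc=float(auc),
                    pvalue=float(pval),
                )
            )
    out = pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "auc", "pvalue"])
    return out.sort_values(
        ["cluster", "auc", "log2fc"], ascending=[True, False, False]
    ).reset_index(drop=True)


def gene_activity(
    frags: FragmentSet,
    genes: list[GeneRecord],
    promoter_upstream: int = 2000,
) -> CountMatrix:
    """Cell x gene fragment counts over promoter + gene body.

    The scored window is [body_start - promoter_upstream, body_end) for +
    strand genes, mirrored for - strand; a fragment counts once per gene
    window it intersects.
    """
    if not frags.deduplicated:
        raise ValueError("gene_activity requires deduplicated fragments")
    df = frags.data
    barcodes = sorted(df["barcode"].unique())
    bc_index = {b: i for i, b in enumerate(barcodes)}
    mat = sp.lil_matrix((len(barcodes), len(genes)), dtype=np.int64)
    by_chrom = {
        chrom: sub.sort_values("start")
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    for gi, gene in enumerate(genes):
        if gene.strand == "+":
            w_start, w_end = gene.body_start - promoter_upstream, gene.body_end
        else:
            w_start, w_end = gene.body_start, gene.body_end + promoter_upstream
        w_start = max(w_start, 0)
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cand = (starts < w_end) & (ends > w_start)
        if not cand.any():
            continue
        hit_barcodes = sub["barcode"].to_numpy()[cand]
        for bc, cnt in pd.Series(hit_barcodes).value_counts().items():
            mat[bc_index[bc], gi] += int(cnt)
    return CountMatrix(mat.tocsr(), barcodes, [g.gene_id for g in genes])


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def annotate_epigenome_clusters(
    epi: dict[str, str], rna: dict[str, str]
) -> dict[str, str]:
    """Relabel each epigenome cluster by its plurality transcriptome type.

    Ties break toward the larger transcriptome cluster overall, then
    lexicographically; epigenome clusters sharing no barcodes with the
    transcriptome labeling are "unassigned".
    """
    shared = sorted(set(epi) & set(rna))
    rna_sizes = pd.Series(list(rna.values())).value_counts()
    table = pd.DataFrame(
        {"epi": [epi[b] for b in shared], "rna": [rna[b] for b in shared]}
    )
    mapping: dict[str, str] = {}
    for cl in sorted(set(epi.values())):
        sub = table.loc[table["epi"] == cl, "rna"]
        if sub.empty:
            mapping[cl] = "unassigned"
            continue
        counts = sub.value_counts()
        best = counts.max()
        tied = sorted(
            counts.index[counts == best],
            key=lambda t: (-rna_sizes.get(t, 0), t),
        )
        mapping[cl] = tied[0]
    return mapping


def overlap_two_modality(
    a: dict[str, str], b: dict[str, str]
) -> pd.Series:
    """Per-cluster overlap coefficient between two labelings of one dataset.

    For each cluster A_i of labeling ``a`` (transcriptome), O_i is the
    largest fraction of A_i's cells captured by a single cluster of ``b``
    (epigenome), computed over the common barcode set:
    O_i = max_x |A_i intersect B_x| / |A_i|.
    """
    shared = sorted(set(a) & set(b))
    table = pd.crosstab(
        pd.Series([a[x] for x in shared], name="a"),
        pd.Series([b[x] for x in shared], name="b"),
    )
    sizes = table.sum(axis=1)
    out = table.max(axis=1) / sizes
    out.name = "O_i"
    # clusters of `a` absent from the common set are reported missing
    missing = sorted(set(a.values()) - set(table.index))
    if missing:
        out = pd.concat(
            [out, pd.Series([np.nan] * len(missing), index=missing, name="O_i")]
        )
    return out.sort_index()


def overlap_integration(
    a: dict[str, str], b: dict[str, str], c: dict[str, str]
) -> pd.DataFrame:
    """Query x reference overlap coefficients through a coembedding.

    O_ij = max over coembedding clusters k of
    min(|A_i intersect C_k| / |A_i|, |B_j intersect C_k| / |B_j|): the two
    datasets agree on (i, j) to the extent both concentrate in one shared
    coembedding cluster.
    """
    if set(a) & set(b):
        raise ValueError("query and reference barcode sets must be disjoint")
    a_frac = _cluster_fractions(a, c)
    b_frac = _cluster_fractions(b, c)
    ks = sorted(set(a_frac.columns) | set(b_frac.columns))
    a_frac = a_frac.reindex(columns=ks, fill_value=0.0)
    b_frac = b_frac.reindex(columns=ks, fill_value=0.0)
    out = pd.DataFrame(
        np.max(
            np.minimum(
                a_frac.to_numpy()[:, None, :], b_frac.to_numpy()[None, :, :]
            ),
            axis=2,
        ),
        index=a_frac.index,
        columns=b_frac.index,
    )
    out.index.name = "query"
    out.columns.name = "reference"
    return out


def _cluster_fractions(
    labels: dict[str, str], c: dict[str, str]
) -> pd.DataFrame:
    """Fraction of each labeled cluster falling in each coembedding cluster."""
    shared = sorted(set(labels) & set(c))
    if not shared:
        raise ValueError("labeling shares no barcodes with the coembedding")
    table = pd.crosstab(
        pd.Series([labels[x] for x in shared]),
        pd.Series([c[x] for x in shared]),
    )
    return table.div(table.sum(axis=1), axis=0)
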