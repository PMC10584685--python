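"""Synthetic droplet joint histone + transcriptome data with planted truth.

The generator emulates the data model of a droplet-based joint
histone-modification / RNA assay on a desk-scale genome:

* K cell types, each with marker genes and a cell-type-specific regulatory
  program over candidate cis-regulatory elements (cCREs);
* R biological replicates (round-robin barcode assignment, optional
  per-replicate depth factors);
* per-cell DNA fragments with a configurable fraction-of-fragments-in-cCREs
  (FRiP) target and a nucleosomal fragment-length mixture (subnucleosomal /
  mono / di / trinucleosome modes near 60, 200, 400, 600 bp);
* an "active" mark whose intensity at a planted distal cCRE tracks the
  linked gene's per-type expression, and a "repressive" mark whose
  intensity anti-tracks it (rank correlation -1 across types by
  construction);
* negative-binomial transcriptomes with per-cell log-normal library sizes;
* doublet barcodes merging two singlet profiles.

Every random draw flows from a single seed through named
``numpy.random.Generator`` streams; same config + seed reproduces the data
byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CountMatrix,
    FragmentSet,
    GeneRecord,
    FRAGMENT_COLUMNS,
    write_gene_annotation,
)

ACTIVE = "active"
REPRESSIVE = "repressive"

NUCLEOSOME_MODES = (60, 200, 400, 600)


class ConfigurationError(ValueError):
    """The simulation request is infeasible (placement, counts...)."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic joint-profiling experiment."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    n_cell_types: int = 8
    cells_per_type: int = 100
    n_replicates: int = 3
    n_genes: int = 50
    n_ccres: int = 240
    frac_proximal_ccres: float = 0.3
    planted_links: int = 40
    frip_target: float = 0.5
    fragments_per_cell_median: float = 2000.0
    fragments_per_cell_dispersion: float = 0.35
    umis_per_cell_median: float = 2000.0
    umis_per_cell_dispersion: float = 0.35
    nb_dispersion: float = 0.15
    marker_fold_change: float = 8.0
    markers_per_type: int = 3
    type_variation_sigma: float = 1.0
    link_profile_ratio: float = 2.0
    distal_background_sigma: float = 0.0
    profile_decorrelation_cap: float = 0.4
    doublet_rate: float = 0.05
    duplicate_rate: float = 0.05
    repressive_mode: bool = False
    background_uniform_rate: float = 0.05
    ccre_width: int = 500
    min_link_distance: int = 5_000
    max_link_distance: int = 500_000
    replicate_depth_factors: tuple[float, ...] | None = None
    active_length_weights: tuple[float, float, float, float] = (
        0.45,
        0.35,
        0.15,
        0.05,
    )
    repressive_length_weights: tuple[float, float, float, float] = (
        0.10,
        0.40,
        0.30,
        0.20,
    )

    def __post_init__(self) -> None:
        for name in (
            "n_cell_types",
            "cells_per_type",
            "n_replicates",
            "n_genes",
            "n_ccres",
            "ccre_width",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 < self.frip_target < 1.0:
            raise ConfigurationError("frip_target must be in (0, 1)")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ConfigurationError("doublet_rate must be in [0, 1)")
        if self.planted_links < 0:
            raise ConfigurationError("planted_links must be >= 0")

    @property
    def type_names(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_cell_types)]

    def depth_factor(self, replicate: int) -> float:
        if self.replicate_depth_factors is None:
            return 1.0
        return float(self.replicate_depth_factors[replicate])


@dataclass
class GroundTruth:
    """Planted configuration of a simulated dataset.

    cells: one row per barcode (cell_type, replicate, is_doublet,
    partner_type).  ccres: one row per cCRE with class, linked gene and
    link sign.  expr_means: genes x types relative abundance (columns sum
    to 1).  activity[mark]: cCREs x types sampling weight of the mark.
    """

    cells: pd.DataFrame
    ccres: pd.DataFrame
    expr_means: pd.DataFrame
    activity: dict[str, pd.DataFrame]
    markers: dict[str, list[str]]
    links: pd.DataFrame

    @property
    def barcodes(self) -> list[str]:
        return list(self.cells.index)

    def active_ccres(self, cell_type: str, mark: str = ACTIVE) -> list[str]:
        """cCREs with above-median weight for the type under the mark."""
        col = self.activity[mark][cell_type]
        return list(col.index[col > col.median()])

    def expressed_genes(self, cell_type: str) -> list[str]:
        col = self.expr_means[cell_type]
        return list(col.index[col > col.median()])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneRecord], pd.DataFrame, pd.DataFrame]:
    """Place genes and cCREs on the synthetic genome.

    Returns (genes, ccre table, planted-link table).  Proximal cCREs sit
    inside +/-2 kb of a TSS; distal cCREs are >=2 kb from every TSS;
    planted-link cCREs lie 5-500 kb from their target gene's TSS.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_prox = int(round(config.frac_proximal_ccres * config.n_ccres))
    n_distal = config.n_ccres - n_prox
    if config.planted_links > n_distal:
        raise ConfigurationError(
            f"planted_links={config.planted_links} exceeds the "
            f"{n_distal} distal cCREs available"
        )
    if config.planted_links > config.n_genes:
        raise ConfigurationError(
            "planted_links exceeds n_genes (one link per target gene)"
        )

    genes = _place_genes(config, rng)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    half = config.ccre_width // 2
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_sizes}

    def free(chrom: str, start: int, end: int) -> bool:
        return all(e <= start or s >= end for s, e in placed[chrom])

    def near_tss(chrom: str, start: int, end: int) -> bool:
        tss = tss_by_chrom.get(chrom)
        if tss is None or len(tss) == 0:
            return False
        # cCRE intersects [tss-2000, tss+2000] for some TSS
        i = np.searchsorted(tss, start - 2000)
        return bool(i < len(tss) and tss[i] <= end - 1 + 2000)

    # planted-link target genes chosen up front: each is guaranteed a
    # proximal cCRE (a detectable link needs a marked promoter anchor)
    link_gene_idx = rng.choice(len(genes), size=config.planted_links, replace=False)
    if n_prox < config.planted_links:
        raise ConfigurationError(
            "need at least one proximal cCRE per planted link; "
            "increase frac_proximal_ccres"
        )

    rows: list[dict] = []
    # proximal cCREs inside the +/-2 kb promoter window of a gene: linked
    # genes first, then random genes
    for i in range(n_prox):
        for _ in range(1000):
            if i < config.planted_links:
                g = genes[int(link_gene_idx[i])]
            else:
                g = genes[int(rng.integers(len(genes)))]
            center = g.tss + int(rng.integers(-2000 + half, 2001 - half))
            start, end = center - half, center + half
            if start < 0 or end > config.chrom_sizes[g.chrom]:
                continue
            if free(g.chrom, start, end):
                placed[g.chrom].append((start, end))
                rows.append(
                    dict(
                        name=f"ccre_p{i:04d}",
                        chrom=g.chrom,
                        start=start,
                        end=end,
                        ccre_class="proximal",
                        nearest_gene=g.gene_id,
                        linked_gene="",
                        link_sign=0,
                    )
                )
                break
        else:
            raise ConfigurationError("cannot place proximal cCREs; genome full")

    # planted-link distal cCREs at 5-500 kb from their target gene's TSS
    link_rows = []
    for j, gi in enumerate(link_gene_idx):
        g = genes[int(gi)]
        chrom_len = config.chrom_sizes[g.chrom]
        for _ in range(2000):
            dist = int(
                rng.integers(config.min_link_distance, config.max_link_distance - half)
            )
            center = g.tss + dist * (1 if rng.random() < 0.5 else -1)
            start, end = center - half, center + half
            if start < 0 or end > chrom_len:
                continue
            if near_tss(g.chrom, start, end) or not free(g.chrom, start, end):
                continue
            placed[g.chrom].append((start, end))
            name = f"ccre_d{j:04d}"
            rows.append(
                dict(
                    name=name,
                    chrom=g.chrom,
                    start=start,
                    end=end,
                    ccre_class="distal",
                    nearest_gene=g.gene_id,
                    linked_gene=g.gene_id,
                    link_sign=1,
                )
            )
            link_rows.append(
                dict(ccre=name, gene=g.gene_id, distance=abs(center - g.tss))
            )
            break
        else:
            raise ConfigurationError(
                "cannot place planted-link cCREs; genome too crowded"
            )

    # remaining distal cCREs anywhere >=2 kb from every TSS
    chrom_names = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_p = sizes / sizes.sum()
    for j in range(n_distal - config.planted_links):
        for _ in range(2000):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
            center = int(rng.integers(half, config.chrom_sizes[chrom] - half))
            start, end = center - half, center + half
            if near_tss(chrom, start, end) or not free(chrom, start, end):
                continue
            placed[chrom].append((start, end))
            rows.append(
                dict(
                    name=f"ccre_d{config.planted_links + j:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    ccre_class="distal",
                    nearest_gene="",
                    linked_gene="",
                    link_sign=0,
                )
            )
            break
        else:
            raise ConfigurationError("cannot place distal cCREs; genome full")

    ccres = pd.DataFrame(rows).set_index("name", drop=False)
    ccres.index.name = "ccre"
    links = pd.DataFrame(link_rows, columns=["ccre", "gene", "distance"])
    return genes, ccres, links


def _place_genes(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GeneRecord]:
    """Non-overlapping gene bodies in equal slots along each chromosome."""
    chrom_names = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chrom_names], dtype=float)
    per_chrom = np.maximum(
        1, np.round(config.n_genes * sizes / sizes.sum()).astype(int)
    )
    # adjust to hit exactly n_genes
    while per_chrom.sum() > config.n_genes:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < config.n_genes:
        per_chrom[np.argmax(sizes / per_chrom)] += 1

    genes: list[GeneRecord] = []
    gi = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        slot = config.chrom_sizes[chrom] // int(n_here)
        max_body = min(20_000, slot // 2)
        if max_body < 2_000:
            raise ConfigurationError(
                f"chromosome {chrom} too small for {n_here} gene bodies"
            )
        for k in range(int(n_here)):
            body_len = int(rng.integers(2_000, max_body + 1))
            lo = k * slot
            start = lo + int(rng.integers(0, slot - body_len))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(f"gene{gi:04d}", chrom, strand, start, start + body_len)
            )
            gi += 1
    return genes


# ---------------------------------------------------------------------------
# cells and expression programs
# ---------------------------------------------------------------------------

def simulate_cells(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Assign barcodes to cell types, replicates and doublet status.

    Returns one row per barcode: cell_type, replicate (round-robin over
    singlet order), is_doublet and, for doublets, the partner type whose
    profile is merged in.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_singlets = config.n_cell_types * config.cells_per_type
    types = np.repeat(config.type_names, config.cells_per_type)
    barcodes = [f"BC{i:05d}" for i in range(n_singlets)]
    replicates = np.arange(n_singlets) % config.n_replicates
    cells = pd.DataFrame(
        {
            "cell_type": types,
            "replicate": replicates,
            "is_doublet": False,
            "partner_type": "",
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    n_doublets = math.floor(config.doublet_rate * n_singlets)
    if n_doublets:
        first = rng.integers(0, n_singlets, size=n_doublets)
        second = rng.integers(0, n_singlets, size=n_doublets)
        doublets = pd.DataFrame(
            {
                "cell_type": types[first],
                "replicate": replicates[first],
                "is_doublet": True,
                "partner_type": types[second],
            },
            index=pd.Index(
                [f"DB{i:05d}" for i in range(n_doublets)], name="barcode"
            ),
        )
        cells = pd.concat([cells, doublets])
    return cells


def _expression_program(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: list[GeneRecord],
    linked_genes: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-type relative gene abundances and the marker-gene sets.

    Every gene varies across types (log-normal multipliers).  Planted-link
    target genes get a graded cross-type profile (a permuted geometric
    ladder with ratio link_profile_ratio), the strong-coupling condition
    the linkage stage is meant to recover: every pair of types differs by
    at least the ladder ratio, so cross-type ranks are unambiguous.  Each
    type additionally owns markers_per_type genes whose own-type
    multiplier is marker_fold_change times the gene's largest other-type
    multiplier, guaranteeing the marker fold change regardless of the
    random draws.
    """
    gene_ids = [g.gene_id for g in genes]
    n_genes, k = len(gene_ids), config.n_cell_types
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    linked_set = set(linked_genes)
    ladder = config.link_profile_ratio ** np.arange(k)

    # marker roles decided first so profile proposals include the boost
    order = rng.permutation(n_genes)
    order = np.concatenate(
        [
            [i for i in order if gene_ids[i] not in linked_set],
            [i for i in order if gene_ids[i] in linked_set],
        ]
    ).astype(int)
    markers: dict[str, list[str]] = {}
    marker_type: dict[int, int] = {}
    needed = config.markers_per_type * k
    if needed > n_genes:
        raise ConfigurationError("markers_per_type * n_cell_types exceeds n_genes")
    for t in range(k):
        idx = order[t * config.markers_per_type : (t + 1) * config.markers_per_type]
        markers[config.type_names[t]] = [gene_ids[i] for i in idx]
        for i in idx:
            marker_type[int(i)] = t

    # profiles assigned in genomic order with a mutual-decorrelation cap:
    # genes whose TSSs lie within twice the link window share candidate
    # cCREs, so chance profile alignment between them would create
    # cCRE-gene correlations indistinguishable from planted links; capping
    # pairwise |Spearman| keeps the planted links identifiable.
    window = 2 * config.max_link_distance
    # rank correlations over k points are quantized (granularity ~1/(k-1)),
    # so the cap cannot bind below the smallest nonzero achievable value;
    # with few types the constraint is weak (or infeasible in dense
    # neighborhoods), so the search budget shrinks accordingly
    cap = max(config.profile_decorrelation_cap, 1.6 / (config.n_cell_types - 1))
    n_tries = 20_000 if cap < 0.6 else 300
    mult = np.empty((n_genes, k))
    tss = np.array([g.tss for g in genes])
    chroms = np.array([g.chrom for g in genes])

    def propose(gi: int) -> np.ndarray:
        if gene_ids[gi] in linked_set:
            row = rng.permutation(ladder).astype(float)
        else:
            row = rng.lognormal(0.0, config.type_variation_sigma, size=k)
        t = marker_type.get(gi)
        if t is not None:
            others = np.delete(np.arange(k), t)
            row = row.copy()
            row[t] = config.marker_fold_change * row[others].max()
        return row

    # the cap must hold for the FINAL per-type relative abundances
    # (shape / per-type total), since the per-type normalization imprints
    # a shared inverse-total mode on every profile; the normalizer is
    # estimated from a first pass and refined in a second sweep
    rank_norm2 = float(np.sum(_rank(ladder) ** 2))
    for gi in range(n_genes):
        mult[gi] = propose(gi)
    shapes = mult / mult.sum(axis=1, keepdims=True)
    for _sweep in range(10):
        colsum = base @ shapes
        rank_rows = np.stack([_rank(row / colsum) for row in shapes])

        def max_rho(row: np.ndarray, nb: np.ndarray) -> float:
            if len(nb) == 0:
                return 0.0
            r = _rank(row / colsum)
            return float(np.max(np.abs(rank_rows[nb] @ r)) / rank_norm2)

        changed = 0
        for gi in range(n_genes):
            nb = np.where(
                (chroms == chroms[gi])
                & (np.abs(tss - tss[gi]) <= window)
                & (np.arange(n_genes) != gi)
            )[0]
            best_row, best_rho = shapes[gi], max_rho(shapes[gi], nb)
            if best_rho <= cap:
                continue
            for _ in range(n_tries):
                row = propose(gi)
                row = row / row.sum()
                rho = max_rho(row, nb)
                if rho < best_rho:
                    best_row, best_rho = row, rho
                if rho <= cap:
                    break
            shapes[gi] = best_row
            rank_rows[gi] = _rank(best_row / colsum)
            if best_rho <= cap:
                changed += 1
        if changed == 0:
            break

    weights = base[:, None] * shapes
    probs = weights / weights.sum(axis=0, keepdims=True)
    expr_means = pd.DataFrame(
        probs, index=pd.Index(gene_ids, name="gene"), columns=config.type_names
    )
    return expr_means, markers


def _rank(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    ranks[order] = np.arange(len(v), dtype=float)
    return ranks - ranks.mean()


def _ccre_activity(
    config: SimulationConfig,
    rng: np.random.Generator,
    ccres: pd.DataFrame,
    expr_means: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Per-mark cCRE x type sampling weights.

    Linked cCREs copy their target gene's cross-type profile (linear
    coupling); proximal cCREs copy their nearest gene; unlinked distal
    cCREs are type-uniform (optionally with a weak log-normal wobble),
    so the planted links are the only systematic distal-cCRE-to-gene
    covariation and false-discovery accounting downstream is well
    defined.  The repressive mark is the rowwise reflection
    (max + min - w), so its rank correlation with the active profile is
    exactly -1 across types.
    """
    k = config.n_cell_types
    act = np.empty((len(ccres), k))
    strong = np.zeros(len(ccres), dtype=bool)
    for i, row in enumerate(ccres.itertuples(index=False)):
        if row.linked_gene:
            prof = expr_means.loc[row.linked_gene].to_numpy()
            strong[i] = True
        elif row.ccre_class == "proximal" and row.nearest_gene:
            prof = expr_means.loc[row.nearest_gene].to_numpy()
            strong[i] = True
        elif config.distal_background_sigma > 0:
            prof = rng.lognormal(0.0, config.distal_background_sigma, size=k)
            strong[i] = True
        else:
            prof = np.ones(k)
        act[i] = prof / prof.sum()
    rep = (act.max(axis=1) + act.min(axis=1))[:, None] - act
    rep = rep / rep.sum(axis=1, keepdims=True)
    act = _balance_columns(act, strong)
    rep = _balance_columns(rep, strong)
    index = ccres.index
    return {
        ACTIVE: pd.DataFrame(act, index=index, columns=config.type_names),
        REPRESSIVE: pd.DataFrame(rep, index=index, columns=config.type_names),
    }


def _balance_columns(
    act: np.ndarray, strong: np.ndarray, n_iter: int = 100
) -> np.ndarray:
    """Rescale type-specific rows so per-type total activity is equal.

    Per-type read allocation normalizes each type's column to 1; if the
    type-specific rows left the column totals unequal, every type-uniform
    cCRE would inherit a shared inverse-total-activity profile — a common
    mode that masquerades as cross-type signal.  Row rescaling (which
    changes only a cCRE's overall strength, never its cross-type shape)
    removes it.
    """
    if not strong.any():
        return act
    out = act.copy()
    p = out[strong]  # rows sum to 1
    scale = np.ones(p.shape[0])
    for _ in range(n_iter):
        u = scale @ p  # strong mass per type
        factor = u / u.mean()
        # divide each row by its exposure to over-weighted types
        exposure = p @ factor
        scale = scale / np.maximum(exposure, 1e-12)
    out[strong] = scale[:, None] * p
    return out


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """Negative-binomial cells x genes counts.

    Per-cell library size is log-normal; per-gene mean is library size
    times the type's relative abundance; overdispersion is gamma-Poisson
    with the configured nb_dispersion.  Doublet rows are sums of two
    independent singlet draws (one per merged type).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cells = truth.cells
    gene_ids = list(truth.expr_means.index)
    probs = truth.expr_means.to_numpy()  # genes x types
    type_idx = {t: j for j, t in enumerate(config.type_names)}

    draws: list[tuple[int, int]] = []  # (row, type index) one per component
    for row, (_, rec) in enumerate(cells.iterrows()):
        draws.append((row, type_idx[rec.cell_type]))
        if rec.is_doublet:
            draws.append((row, type_idx[rec.partner_type]))
    rows = np.array([d[0] for d in draws])
    tcols = np.array([d[1] for d in draws])

    if config.umis_per_cell_median <= 0:
        counts = np.zeros((len(cells), len(gene_ids)), dtype=np.int64)
    else:
        lib = rng.lognormal(
            mean=np.log(config.umis_per_cell_median),
            sigma=config.umis_per_cell_dispersion,
            size=len(draws),
        )
        mu = lib[:, None] * probs[:, tcols].T  # draws x genes
        phi = config.nb_dispersion
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        else:
            lam = mu
        component = rng.poisson(lam)
        counts = np.zeros((len(cells), len(gene_ids)), dtype=np.int64)
        np.add.at(counts, rows, component)
    return CountMatrix(sp.csr_matrix(counts), list(cells.index), gene_ids)


# ---------------------------------------------------------------------------
# DNA fragments
# ---------------------------------------------------------------------------

def simulate_fragments(
    config: SimulationConfig,
    truth: GroundTruth,
    mark: str = ACTIVE,
    rng: np.random.Generator | None = None,
) -> dict[int, FragmentSet]:
    """Per-replicate fragment sets for one histone mark.

    A frip_target fraction of each cell's fragments is placed uniformly
    within cCREs sampled proportionally to the mark's type-specific
    activity (mixed with a small uniform component); the remainder is
    uniform on the genome.  Fragment lengths follow the nucleosomal
    mixture; repressive mode uses heavier mono/di/tri weights.  A
    duplicate_rate fraction of records is emitted twice to exercise
    barcode-aware deduplication downstream.
    """
    if mark not in (ACTIVE, REPRESSIVE):
        raise ValueError(f"mark must be '{ACTIVE}' or '{REPRESSIVE}'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cells = truth.cells
    weights = truth.activity[mark].to_numpy()  # ccres x types
    bg = config.background_uniform_rate
    weights = (1.0 - bg) * weights / weights.sum(axis=0, keepdims=True) + (
        bg / weights.shape[0]
    )
    ccre_start = truth.ccres["start"].to_numpy()
    ccre_width = (truth.ccres["end"] - truth.ccres["start"]).to_numpy()
    ccre_chrom = truth.ccres["chrom"].to_numpy()
    type_idx = {t: j for j, t in enumerate(config.type_names)}

    # emission components: singlets contribute one, doublets two
    comp_barcode: list[str] = []
    comp_type: list[int] = []
    comp_rep: list[int] = []
    for bc, rec in cells.iterrows():
        comp_barcode.append(bc)
        comp_type.append(type_idx[rec.cell_type])
        comp_rep.append(int(rec.replicate))
        if rec.is_doublet:
            comp_barcode.append(bc)
            comp_type.append(type_idx[rec.partner_type])
            comp_rep.append(int(rec.replicate))
    comp_type_arr = np.array(comp_type)
    comp_rep_arr = np.array(comp_rep)
    n_comp = len(comp_barcode)

    depth = np.array([config.depth_factor(r) for r in comp_rep_arr])
    totals = np.round(
        rng.lognormal(
            mean=np.log(max(config.fragments_per_cell_median, 1e-12)),
            sigma=config.fragments_per_cell_dispersion,
            size=n_comp,
        )
        * depth
    ).astype(np.int64)
    if config.fragments_per_cell_median <= 0:
        totals[:] = 0
    n_in = rng.binomial(totals, config.frip_target)
    n_bg = totals - n_in

    # in-cCRE fragment midpoints, sampled per type
    in_ccre_idx = np.empty(int(n_in.sum()), dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(n_in)])
    for t in range(config.n_cell_types):
        rows = np.where(comp_type_arr == t)[0]
        total_t = int(n_in[rows].sum())
        if total_t == 0:
            continue
        picks = rng.choice(len(ccre_start), size=total_t, p=weights[:, t])
        pos = 0
        for r in rows:
            k = int(n_in[r])
            in_ccre_idx[offsets[r] : offsets[r] + k] = picks[pos : pos + k]
            pos += k
    in_mid = ccre_start[in_ccre_idx] + np.floor(
        rng.random(len(in_ccre_idx)) * ccre_width[in_ccre_idx]
    ).astype(np.int64)
    in_chrom = ccre_chrom[in_ccre_idx]
    in_barcode = np.repeat(np.array(comp_barcode, dtype=object), n_in)
    in_rep = np.repeat(comp_rep_arr, n_in)

    # genome-wide background midpoints
    chrom_names = np.array(list(config.chrom_sizes))
    sizes = np.array([config.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_p = sizes / sizes.sum()
    n_bg_total = int(n_bg.sum())
    bg_chrom_i = rng.choice(len(chrom_names), size=n_bg_total, p=chrom_p)
    bg_mid = np.floor(rng.random(n_bg_total) * sizes[bg_chrom_i]).astype(np.int64)
    bg_chrom = chrom_names[bg_chrom_i]
    bg_barcode = np.repeat(np.array(comp_barcode, dtype=object), n_bg)
    bg_rep = np.repeat(comp_rep_arr, n_bg)

    chrom = np.concatenate([in_chrom, bg_chrom])
    mid = np.concatenate([in_mid, bg_mid])
    barcode = np.concatenate([in_barcode, bg_barcode])
    rep = np.concatenate([in_rep, bg_rep])

    lengths = _fragment_lengths(config, mark, rng, len(mid))
    start = np.maximum(mid - lengths // 2, 0)
    chrom_len = np.array([config.chrom_sizes[c] for c in chrom])
    end = np.minimum(start + lengths, chrom_len)
    start = np.minimum(start, end - 1)

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "barcode": barcode,
            "count": 1,
            "replicate": rep,
        }
    )
    if config.duplicate_rate > 0 and len(df):
        n_dup = int(round(config.duplicate_rate * len(df)))
        dup_rows = rng.choice(len(df), size=n_dup, replace=False)
        df = pd.concat([df, df.iloc[dup_rows]], ignore_index=True)

    out: dict[int, FragmentSet] = {}
    for r in range(config.n_replicates):
        sub = df.loc[df["replicate"] == r, FRAGMENT_COLUMNS].reset_index(drop=True)
        out[r] = FragmentSet(sub, dict(config.chrom_sizes), False)
    return out


def _fragment_lengths(
    config: SimulationConfig, mark: str, rng: np.random.Generator, n: int
) -> np.ndarray:
    weights = (
        config.repressive_length_weights
        if mark == REPRESSIVE
        else config.active_length_weights
    )
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(len(NUCLEOSOME_MODES), size=n, p=w)
    modes = np.asarray(NUCLEOSOME_MODES, dtype=float)
    lengths = rng.normal(loc=modes[comp], scale=0.15 * modes[comp])
    return np.maximum(np.round(lengths).astype(np.int64), 25)


# ---------------------------------------------------------------------------
# whole-dataset driver and truth round-trip
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[GeneRecord]
    truth: GroundTruth
    rna: CountMatrix
    fragments: dict[str, dict[int, FragmentSet]]  # mark -> replicate -> set


def simulate_dataset(
    config: SimulationConfig, marks: tuple[str, ...] = (ACTIVE, REPRESSIVE)
) -> SimulatedDataset:
    """Generate annotation, truth, RNA counts and fragments for all marks."""
    root = np.random.default_rng(config.seed)
    streams = root.spawn(5)
    genes, ccres, links = simulate_annotation(config, streams[0])
    cells = simulate_cells(config, streams[1])
    expr_means, markers = _expression_program(
        config, streams[2], genes, linked_genes=list(links["gene"])
    )
    activity = _ccre_activity(config, streams[2], ccres, expr_means)
    truth = GroundTruth(
        cells=cells,
        ccres=ccres,
        expr_means=expr_means,
        activity=activity,
        markers=markers,
        links=links,
    )
    rna = simulate_expression(config, truth, streams[3])
    frag_streams = streams[4].spawn(len(marks))
    fragments = {
        mark: simulate_fragments(config, truth, mark, frag_streams[i])
        for i, mark in enumerate(marks)
    }
    return SimulatedDataset(config, genes, truth, rna, fragments)


def write_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write every ground-truth table as TSV under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(out / "cells.tsv", sep="\t")
    truth.ccres.drop(columns=["name"]).to_csv(out / "ccres.tsv", sep="\t")
    truth.expr_means.to_csv(out / "expr_means.tsv", sep="\t")
    for mark, df in truth.activity.items():
        df.to_csv(out / f"activity_{mark}.tsv", sep="\t")
    pd.DataFrame(
        [(t, g) for t, gs in truth.markers.items() for g in gs],
        columns=["cell_type", "gene"],
    ).to_csv(out / "markers.tsv", sep="\t", index=False)
    truth.links.to_csv(out / "links.tsv", sep="\t", index=False)


def read_truth(in_dir: str | Path) -> GroundTruth:
    """Inverse of :func:`write_truth`."""
    d = Path(in_dir)
    cells = pd.read_csv(
        d / "cells.tsv", sep="\t", index_col=0, keep_default_na=False
    )
    cells["is_doublet"] = cells["is_doublet"].astype(bool)
    ccres = pd.read_csv(
        d / "ccres.tsv", sep="\t", index_col=0, keep_default_na=False
    )
    ccres.insert(0, "name", ccres.index)
    expr_means = pd.read_csv(d / "expr_means.tsv", sep="\t", index_col=0)
    activity = {}
    for mark in (ACTIVE, REPRESSIVE):
        p = d / f"activity_{mark}.tsv"
        if p.exists():
            activity[mark] = pd.read_csv(p, sep="\t", index_col=0)
    mdf = pd.read_csv(d / "markers.tsv", sep="\t")
    markers = {
        t: list(sub["gene"]) for t, sub in mdf.groupby("cell_type", sort=False)
    }
    links = pd.read_csv(d / "links.tsv", sep="\t")
    if links.empty:
        links = pd.DataFrame(columns=["ccre", "gene", "distance"])
    return GroundTruth(cells, ccres, expr_means, activity, markers, links)


def write_dataset(data: SimulatedDataset, out_dir: str | Path) -> None:
    """Write annotation, truth, RNA MTX trio and per-replicate fragments."""
    from .io import write_bed, write_count_matrix, write_fragments
    from ._intervals import interval_list

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_annotation(data.genes, out / "genes.tsv")
    write_bed(interval_list(data.truth.ccres), out / "ccres.bed")
    write_count_matrix(
        data.rna,
        out / "rna.mtx",
        out / "rna_barcodes.tsv",
        out / "rna_features.tsv",
    )
    for mark, reps in data.fragments.items():
        for r, frags in reps.items():
            write_fragments(frags, out / f"fragments_{mark}_rep{r}.tsv")
    write_truth(data.truth, out / "truth")
    with open(out / "config.yaml", "w") as fh:
        import yaml

        cfg = asdict(data.config)
        yaml.safe_dump(cfg, fh, sort_keys=True)
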