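"""End-to-end orchestration: simulate/load -> QC -> cluster -> peaks ->
modules -> linkage, with a hashed artifact manifest.

Stage order mirrors the analysis workflow: an initial pooled peak call
provides the FRiP reference for per-cell QC; pass-filtered nuclei are
paired across modalities and doublet-flagged; transcriptome clustering
drives the joint analyses; per-replicate pseudo-bulk peak calls are
merged by the >=2-replicate rule; cluster-level RPKM at cCREs feeds
module discovery and cCRE-gene linkage with a shuffled-identity null.

Linkage SCCs are computed across cluster x replicate pseudo-bulk columns
by default: with a small number of cell types the per-replicate columns
triple the rank resolution of the correlation while leaving the
cluster-only mode available (``linkage_by_replicate=False``).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, cre_modules, linkage, qc, signal
from .io import (
    CountMatrix,
    FragmentSet,
    GeneRecord,
    deduplicate,
    write_bed,
    write_labels,
)
from .simulate import (
    ACTIVE,
    REPRESSIVE,
    SimulationConfig,
    SimulatedDataset,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

MARK_DIRECTION = {ACTIVE: "positive", REPRESSIVE: "negative"}


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed and stage toggles."""

    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    doublet_factor: float = 2.0
    bin_size: int = 5000
    top_bin_fraction: float = 0.85
    n_components_rna: int = 35
    n_components_dna: int = 20
    n_clusters: int | None = None  # default: simulated n_cell_types
    n_top_genes: int = 2500
    peak_q: float = 0.01
    peak_step: int = 10
    min_replicates: int = 2
    peak_width: int = 500
    rpkm_min: float = 1.0
    min_cluster_cells: int = 100
    n_modules: int = 8
    link_max_dist: int = 500_000
    cooccupancy_threshold: float = 0.1
    metacell_size: int = 20
    n_shuffles: int = 10
    link_fdr: float = 0.05
    linkage_by_replicate: bool = True
    run_saturation: bool = False
    saturation_grid: tuple[int, ...] = (50, 100, 200, 400, 800)
    marks: tuple[str, ...] = (ACTIVE, REPRESSIVE)

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)
        if isinstance(self.thresholds, dict):
            self.thresholds = qc.QcThresholds(**self.thresholds)
        self.sim.seed = self.seed


@dataclass
class LinkOutcome:
    pairs: pd.DataFrame  # ccre, gene, distance, cooccupancy, scc, significant
    null: linkage.NullFit
    ks_d: float
    background: np.ndarray


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SimulatedDataset | None
    dna_metrics: dict[str, pd.DataFrame]
    rna_metrics: pd.DataFrame
    paired: dict[str, set[str]]
    doublet_flags: set[str]
    rna_labels: dict[str, str]
    dna_labels: dict[str, dict[str, str]]
    concordance: dict[str, pd.Series]
    merged_peaks: dict[str, list]
    cluster_rpkm: dict[str, pd.DataFrame]
    ccre_classes: pd.Series
    module_results: dict[str, cre_modules.NmfResult]
    links: dict[str, LinkOutcome]
    saturation: signal.SaturationCurve | None
    manifest: dict[str, str]


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full workflow; optionally write artifacts + manifest."""
    if not config.simulate:
        raise NotImplementedError(
            "file-driven runs go through the CLI stage commands; "
            "run_pipeline currently drives the synthetic workflow"
        )
    data = simulate_dataset(config.sim, marks=config.marks)
    genes = data.genes
    truth = data.truth
    rep_of_barcode = truth.cells["replicate"].to_dict()

    # deduplicated fragments, pooled and per replicate, per mark
    frags_all: dict[str, FragmentSet] = {}
    frags_rep: dict[str, dict[int, FragmentSet]] = {}
    for mark in config.marks:
        reps = {
            r: deduplicate(fs) for r, fs in data.fragments[mark].items()
        }
        frags_rep[mark] = reps
        pooled = pd.concat([fs.data for fs in reps.values()], ignore_index=True)
        frags_all[mark] = FragmentSet(
            pooled, dict(config.sim.chrom_sizes), True
        )

    # ---- QC: initial pooled peak call provides the FRiP reference ----
    dna_metrics: dict[str, pd.DataFrame] = {}
    initial_peaks: dict[str, list] = {}
    for mark in config.marks:
        track = signal.insertion_coverage(frags_all[mark], step=config.peak_step)
        mode = "narrow" if MARK_DIRECTION[mark] == "positive" else "broad"
        call = signal.call_peaks(track, mode=mode, q_cutoff=config.peak_q)
        initial_peaks[mark] = call.intervals()
        dna_metrics[mark] = qc.dna_metrics(frags_all[mark], initial_peaks[mark])

    rna_met = qc.rna_metrics(data.rna)
    paired: dict[str, set[str]] = {}
    doublet_flags = qc.flag_doublets(rna_met, factor=config.doublet_factor)
    for mark in config.marks:
        dna_pass, rna_pass = qc.filter_cells(
            dna_metrics[mark], rna_met, config.thresholds
        )
        paired[mark] = qc.pair_modalities(dna_pass, rna_pass) - doublet_flags

    # ---- transcriptome clustering (drives all joint analyses) ----
    rna_cells = sorted(set().union(*paired.values()))
    rna_sub = _subset_rows(data.rna, rna_cells)
    norm, _variable = clustering.normalize_select_rna(
        rna_sub, n_top=config.n_top_genes
    )
    k = config.n_clusters or config.sim.n_cell_types
    emb = clustering.reduce_dimensions(
        norm,
        n_components=min(config.n_components_rna, norm.shape[1] - 1),
        seed=config.seed,
        row_labels=rna_cells,
    )
    rna_labels = clustering.cluster_cells(emb, k=k, seed=config.seed)

    # ---- histone clustering per mark + concordance ----
    dna_labels: dict[str, dict[str, str]] = {}
    concordance: dict[str, pd.Series] = {}
    for mark in config.marks:
        sub = frags_all[mark].subset_barcodes(paired[mark])
        bins = clustering.build_bin_matrix(sub, bin_size=config.bin_size)
        keep = clustering.select_top_bins(bins, config.top_bin_fraction)
        mat = clustering.tfidf(bins)[:, keep]
        demb = clustering.reduce_dimensions(
            mat,
            n_components=config.n_components_dna,
            drop_first=True,
            seed=config.seed,
            row_labels=bins.row_labels,
        )
        labels = clustering.cluster_cells(demb, k=k, seed=config.seed)
        dna_labels[mark] = labels
        concordance[mark] = clustering.overlap_two_modality(rna_labels, labels)

    # ---- replicate pseudo-bulk peaks and reproducible merging ----
    merged_peaks: dict[str, list] = {}
    for mark in config.marks:
        calls = []
        for r, fs in sorted(frags_rep[mark].items()):
            sub = fs.subset_barcodes(paired[mark])
            track = signal.insertion_coverage(sub, step=config.peak_step)
            mode = "narrow" if MARK_DIRECTION[mark] == "positive" else "broad"
            calls.append(
                signal.call_peaks(
                    track, mode=mode, q_cutoff=config.peak_q, replicate=r
                )
            )
        merged_peaks[mark] = signal.merge_reproducible(
            calls,
            min_replicates=config.min_replicates,
            width=config.peak_width,
            chrom_sizes=config.sim.chrom_sizes,
        )

    # ---- cluster-level cCRE signal, classification, modules ----
    ccre_classes = cre_modules.classify_ccres(truth.ccres, genes)
    cluster_rpkm: dict[str, pd.DataFrame] = {}
    cluster_cell_counts: dict[str, int] = {}
    for label in sorted(set(rna_labels.values())):
        cluster_cell_counts[label] = sum(
            1 for v in rna_labels.values() if v == label
        )
    for mark in config.marks:
        groups = {
            bc: lab for bc, lab in rna_labels.items() if bc in paired[mark]
        }
        by_cluster = signal.pseudobulk(
            frags_all[mark].subset_barcodes(paired[mark]), groups
        )
        cluster_rpkm[mark] = signal.quantify_rpkm(by_cluster, truth.ccres)

    retention = cre_modules.filter_ccres(
        cluster_rpkm,
        cluster_cell_counts,
        rpkm_min=config.rpkm_min,
        min_cluster_cells=min(
            config.min_cluster_cells, max(cluster_cell_counts.values())
        ),
    )
    module_results: dict[str, cre_modules.NmfResult] = {}
    for mark in config.marks:
        for cls in ("proximal", "distal"):
            mask = retention[mark] & (ccre_classes == cls)
            mat = cluster_rpkm[mark].loc[mask[mask].index]
            if len(mat) < config.n_modules:
                logger.warning(
                    "%s/%s: %d retained cCREs < n_modules; skipping NMF",
                    mark,
                    cls,
                    len(mat),
                )
                continue
            module_results[f"{mark}_{cls}"] = cre_modules.nmf_modules(
                mat, n_modules=config.n_modules, seed=config.seed
            )

    # ---- cCRE-gene linkage per mark ----
    links: dict[str, LinkOutcome] = {}
    ccres_with_class = truth.ccres.copy()
    ccres_with_class["ccre_class"] = ccre_classes
    gene_by_id = {g.gene_id: g for g in genes}
    for mark in config.marks:
        links[mark] = _link_mark(
            config,
            mark,
            frags_all[mark].subset_barcodes(paired[mark]),
            ccres_with_class,
            genes,
            rna_sub,
            norm,
            rna_labels,
            rep_of_barcode,
        )

    saturation = None
    if config.run_saturation:
        saturation = signal.downsample_saturation(
            frags_all[ACTIVE].subset_barcodes(paired[ACTIVE]),
            merged_peaks[ACTIVE],
            n_grid=config.saturation_grid,
            seed=config.seed,
            step=config.peak_step,
        )

    result = PipelineResult(
        config=config,
        dataset=data,
        dna_metrics=dna_metrics,
        rna_metrics=rna_met,
        paired=paired,
        doublet_flags=doublet_flags,
        rna_labels=rna_labels,
        dna_labels=dna_labels,
        concordance=concordance,
        merged_peaks=merged_peaks,
        cluster_rpkm=cluster_rpkm,
        ccre_classes=ccre_classes,
        module_results=module_results,
        links=links,
        saturation=saturation,
        manifest={},
    )
    if out_dir is not None:
        result.manifest = write_artifacts(result, out_dir)
    return result


def _link_mark(
    config: PipelineConfig,
    mark: str,
    frags: FragmentSet,
    ccres: pd.DataFrame,
    genes: list[GeneRecord],
    rna_sub: CountMatrix,
    norm: np.ndarray,
    rna_labels: dict[str, str],
    rep_of_barcode: dict[str, int],
) -> LinkOutcome:
    pairs = linkage.candidate_pairs(ccres, genes, max_dist=config.link_max_dist)
    cell_by_ccre = linkage.cell_interval_counts(frags, ccres)
    anchors = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [max(g.tss - 2000, 0) for g in genes],
            "end": [g.tss + 2001 for g in genes],
            "name": [g.gene_id for g in genes],
        }
    )
    cell_by_anchor = linkage.cell_interval_counts(frags, anchors)
    pairs = linkage.cooccupancy_filter(
        pairs,
        cell_by_ccre,
        cell_by_anchor,
        rna_labels,
        threshold=config.cooccupancy_threshold,
        group_size=config.metacell_size,
        seed=config.seed,
    )
    barcodes = cell_by_ccre.row_labels
    if config.linkage_by_replicate:
        group_of_cell = np.array(
            [
                f"{rna_labels.get(bc, '')}|r{rep_of_barcode.get(bc, 0)}"
                if rna_labels.get(bc)
                else ""
                for bc in barcodes
            ]
        )
    else:
        group_of_cell = np.array(
            [rna_labels.get(bc, "") for bc in barcodes]
        )
    ccre_len_kb = (
        (ccres["end"] - ccres["start"]).to_numpy() / 1000.0
    )
    totals = frags.data["barcode"].value_counts()
    cell_totals = np.array([totals.get(bc, 0) for bc in barcodes], dtype=float)
    # expression matrix rows aligned to the DNA barcode order
    rna_index = {bc: i for i, bc in enumerate(rna_sub.row_labels)}
    expr_rows = np.array([rna_index[bc] for bc in barcodes])
    expr_norm = norm[expr_rows]

    ccre_sig, expr_sig = linkage.cluster_signals(
        cell_by_ccre,
        ccre_len_kb,
        cell_totals,
        expr_norm,
        rna_sub.col_labels,
        group_of_cell,
    )
    scc = linkage.observed_linkage(pairs, ccre_sig, expr_sig)
    expr_counts = np.asarray(rna_sub.values[expr_rows].todense())
    background = linkage.shuffled_background(
        pairs,
        cell_by_ccre,
        ccre_len_kb,
        cell_totals,
        expr_counts,
        rna_sub.col_labels,
        group_of_cell,
        n_shuffles=config.n_shuffles,
        seed=config.seed + 1,
    )
    observed = scc.to_numpy()
    valid = ~np.isnan(observed)
    fit = linkage.fit_null_threshold(
        observed[valid],
        background,
        fdr=config.link_fdr,
        direction=MARK_DIRECTION[mark],
    )
    significant = np.zeros(len(pairs), dtype=bool)
    significant[np.where(valid)[0]] = fit.significant
    out_pairs = pairs.copy()
    out_pairs["scc"] = observed
    out_pairs["significant"] = significant
    out_pairs["direction"] = MARK_DIRECTION[mark]
    ks_d = linkage.ks_separation(observed[valid], background)
    return LinkOutcome(out_pairs, fit, ks_d, background)


def _subset_rows(matrix: CountMatrix, barcodes: list[str]) -> CountMatrix:
    index = {bc: i for i, bc in enumerate(matrix.row_labels)}
    rows = [index[bc] for bc in barcodes]
    return CountMatrix(matrix.values[rows], list(barcodes), matrix.col_labels)


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def write_artifacts(result: PipelineResult, out_dir: str | Path) -> dict[str, str]:
    """Write stage outputs and return a path -> sha256 manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labels(result.rna_labels, out / "rna_labels.tsv")
    for mark, labels in result.dna_labels.items():
        write_labels(labels, out / f"dna_labels_{mark}.tsv")
    for mark, metrics in result.dna_metrics.items():
        metrics.to_csv(out / f"dna_metrics_{mark}.tsv", sep="\t")
    result.rna_metrics.to_csv(out / "rna_metrics.tsv", sep="\t")
    for mark, peaks in result.merged_peaks.items():
        write_bed(peaks, out / f"merged_peaks_{mark}.bed")
    for mark, rpkm in result.cluster_rpkm.items():
        rpkm.to_csv(out / f"cluster_rpkm_{mark}.tsv", sep="\t")
    for key, res in result.module_results.items():
        res.modules.to_csv(out / f"modules_{key}.tsv", sep="\t")
        res.cluster_profiles.to_csv(out / f"module_profiles_{key}.tsv", sep="\t")
    for mark, link in result.links.items():
        link.pairs.to_csv(out / f"links_{mark}.tsv", sep="\t", index=False)
        summary = {
            "mu0": link.null.mu0,
            "sigma0": link.null.sigma0,
            "cutoff": link.null.cutoff,
            "min_fdr": link.null.min_fdr,
            "direction": link.null.direction,
            "ks_d": link.ks_d,
            "n_significant": int(link.pairs["significant"].sum()),
        }
        with open(out / f"link_summary_{mark}.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        _write_bedpe(result, mark, out / f"links_{mark}.bedpe")
    if result.saturation is not None:
        result.saturation.table.to_csv(out / "saturation.tsv", sep="\t", index=False)
    manifest = {}
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_bedpe(result: PipelineResult, mark: str, path: Path) -> None:
    if result.dataset is None:
        return
    ccres = result.dataset.truth.ccres
    genes = {g.gene_id: g for g in result.dataset.genes}
    link = result.links[mark]
    with open(path, "w") as fh:
        for row in link.pairs.loc[link.pairs["significant"]].itertuples(index=False):
            c = ccres.loc[row.ccre]
            g = genes[row.gene]
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            c["chrom"],
                            c["start"],
                            c["end"],
                            g.chrom,
                            max(g.tss - 2000, 0),
                            g.tss + 2001,
                            f"{row.ccre}--{row.gene}",
                            f"{row.scc:.4f}",
                        ],
                    )
                )
                + "\n"
            )


def config_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("saturation_grid", "marks"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    if "sim" in raw and isinstance(raw["sim"], dict):
        for key in (
            "replicate_depth_factors",
            "active_length_weights",
            "repressive_length_weights",
        ):
            if raw["sim"].get(key) is not None and isinstance(raw["sim"][key], list):
                raw["sim"][key] = tuple(raw["sim"][key])
    return PipelineConfig(**raw)
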