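"""Per-cell quality control for both modalities and barcode pairing.

DNA-side metrics are the unique fragment count and FRiP (fraction of a
cell's deduplicated fragments overlapping at least one peak, each fragment
counted once however many peaks it touches).  RNA-side metrics are UMI
totals, detected genes and mitochondrial / ribosomal fractions.  Cells
passing both modality filters are paired by barcode intersection; a
transparent count-based heuristic flags likely doublets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import ranges_overlap_any
from .io import CountMatrix, FragmentSet

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    """Pass-filter bounds; the defaults are deliberately permissive and
    every bound is configurable (set max bounds to ``inf`` to disable)."""

    min_fragments: int = 200
    max_fragments: float = float("inf")
    min_frip: float = 0.1
    min_umis: int = 200
    max_umis: float = float("inf")
    max_mito: float = 0.2
    max_ribo: float = 0.2
    min_genes: int = 0

    def __post_init__(self) -> None:
        if self.min_fragments > self.max_fragments:
            raise ValueError("min_fragments > max_fragments")
        if self.min_umis > self.max_umis:
            raise ValueError("min_umis > max_umis")


def dna_metrics(frags: FragmentSet, peaks) -> pd.DataFrame:
    """Per-barcode unique fragment count and FRiP against a peak set.

    Requires deduplicated input so that "unique fragments" and the FRiP
    numerator are well defined.
    """
    if not frags.deduplicated:
        raise ValueError("dna_metrics requires a deduplicated FragmentSet")
    df = frags.data
    if df.empty:
        return pd.DataFrame(columns=["unique_fragments", "frip"]).rename_axis(
            "barcode"
        )
    in_peak = ranges_overlap_any(
        df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy(), peaks
    )
    grouped = pd.DataFrame(
        {"barcode": df["barcode"].to_numpy(), "in_peak": in_peak}
    ).groupby("barcode")
    out = grouped.agg(unique_fragments=("in_peak", "size"), frip=("in_peak", "mean"))
    return out


def rna_metrics(
    counts: CountMatrix,
    mito_genes=(),
    ribo_genes=(),
) -> pd.DataFrame:
    """Per-barcode UMIs, detected genes and mito/ribo fractions.

    Fractions are 0 for zero-UMI cells by convention.  Unknown gene ids in
    either set raise.
    """
    col_index = {g: i for i, g in enumerate(counts.col_labels)}
    for name, genes in (("mito", mito_genes), ("ribo", ribo_genes)):
        unknown = [g for g in genes if g not in col_index]
        if unknown:
            raise ValueError(f"unknown {name} genes: {unknown}")
    mat = counts.values
    umis = np.asarray(mat.sum(axis=1)).ravel()
    genes_detected = np.asarray((mat > 0).sum(axis=1)).ravel()

    def _set_fraction(genes) -> np.ndarray:
        if not genes:
            return np.zeros(mat.shape[0])
        idx = [col_index[g] for g in genes]
        subtotal = np.asarray(mat[:, idx].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(umis > 0, subtotal / np.maximum(umis, 1), 0.0)
        return frac

    return pd.DataFrame(
        {
            "umis": umis.astype(np.int64),
            "genes_detected": genes_detected.astype(np.int64),
            "mito_fraction": _set_fraction(list(mito_genes)),
            "ribo_fraction": _set_fraction(list(ribo_genes)),
        },
        index=pd.Index(counts.row_labels, name="barcode"),
    )


def filter_cells(
    dna: pd.DataFrame, rna: pd.DataFrame, thresholds: QcThresholds
) -> tuple[set[str], set[str]]:
    """Apply the per-modality thresholds; returns (dna_pass, rna_pass)."""
    dna_pass = set(
        dna.index[
            (dna["unique_fragments"] >= thresholds.min_fragments)
            & (dna["unique_fragments"] <= thresholds.max_fragments)
            & (dna["frip"] >= thresholds.min_frip)
        ]
    )
    rna_pass = set(
        rna.index[
            (rna["umis"] >= thresholds.min_umis)
            & (rna["umis"] <= thresholds.max_umis)
            & (rna["mito_fraction"] <= thresholds.max_mito)
            & (rna["ribo_fraction"] <= thresholds.max_ribo)
            & (rna["genes_detected"] >= thresholds.min_genes)
        ]
    )
    return dna_pass, rna_pass


def pair_modalities(dna_pass: set[str], rna_pass: set[str]) -> set[str]:
    """Barcodes passing both modalities (set intersection)."""
    paired = set(dna_pass) & set(rna_pass)
    if not paired and (dna_pass or rna_pass):
        logger.warning("no barcodes pass both modalities")
    return paired


def flag_doublets(
    rna: pd.DataFrame,
    factor: float = 2.0,
    median_ref: float | None = None,
) -> set[str]:
    """Flag barcodes whose UMI total exceeds ``factor`` x the median.

    A deliberately transparent stand-in for simulation-based doublet
    scoring: droplet doublets carry roughly twice the median library.
    ``median_ref`` overrides the median (e.g. a pre-filter estimate).
    """
    if rna.empty:
        return set()
    med = float(rna["umis"].median()) if median_ref is None else float(median_ref)
    return set(rna.index[rna["umis"] > factor * med])
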