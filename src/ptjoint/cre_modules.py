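"""cCRE filtering, distal/proximal classification and NMF module discovery.

A cCRE is proximal when it intersects the +/-2-kb window around any TSS,
distal otherwise.  Retention requires a mark RPKM strictly above 1 in at
least one cluster with >= 100 nuclei.  Retained cCREs of one class are
grouped into modules by non-negative matrix factorization of the
row-normalized cluster-signal matrix; a cCRE's module is the argmax of
its loading row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from ._intervals import intervals_to_frame
from .io import GeneRecord


@dataclass
class NmfResult:
    modules: pd.Series  # cCRE -> 1-based module id
    loadings: pd.DataFrame  # cCREs x modules (W)
    cluster_profiles: pd.DataFrame  # modules x clusters (H)
    reconstruction_error: float


def classify_ccres(
    ccres, genes: list[GeneRecord], window: int = 2000
) -> pd.Series:
    """"proximal" iff a cCRE intersects [tss-window, tss+window] of any gene."""
    df = intervals_to_frame(ccres)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    classes = []
    for row in df.itertuples(index=False):
        tss = tss_by_chrom.get(row.chrom)
        proximal = False
        if tss is not None and len(tss):
            i = np.searchsorted(tss, row.start - window)
            proximal = bool(i < len(tss) and tss[i] <= row.end - 1 + window)
        classes.append("proximal" if proximal else "distal")
    index = (
        df["name"]
        if "name" in df.columns and df["name"].notna().all()
        else pd.RangeIndex(len(df))
    )
    return pd.Series(classes, index=index, name="ccre_class")


def filter_ccres(
    signal_by_mark: Mapping[str, pd.DataFrame],
    cell_counts: Mapping[str, int],
    rpkm_min: float = 1.0,
    min_cluster_cells: int = 100,
) -> dict[str, pd.Series]:
    """Per-mark retention flags plus the shared (both-marks) set.

    Clusters with fewer than ``min_cluster_cells`` nuclei are excluded
    before thresholding; a cCRE is retained for a mark iff its RPKM is
    strictly greater than ``rpkm_min`` in at least one remaining cluster.
    """
    keep_clusters = [c for c, n in cell_counts.items() if n >= min_cluster_cells]
    if not keep_clusters:
        raise ValueError("all clusters fall below min_cluster_cells")
    out: dict[str, pd.Series] = {}
    shared: pd.Series | None = None
    for mark, signal in signal_by_mark.items():
        cols = [c for c in signal.columns if c in keep_clusters]
        retained = (signal[cols] > rpkm_min).any(axis=1)
        retained.name = f"retained_{mark}"
        out[mark] = retained
        shared = retained if shared is None else (shared & retained)
    if shared is not None:
        shared.name = "retained_shared"
        out["shared"] = shared
    return out


def nmf_modules(
    signal: pd.DataFrame,
    n_modules: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> NmfResult:
    """Group cCREs into modules by NMF of the cluster-signal matrix.

    Rows are normalized to unit sum before factorization so modules
    reflect cell-type specificity rather than absolute signal.  Module of
    a cCRE = argmax of its W row, 1-based; ties break toward the lower
    module id.
    """
    if len(signal) < n_modules:
        raise ValueError(
            f"{len(signal)} cCREs < n_modules={n_modules}; reduce n_modules"
        )
    mat = signal.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("signal matrix must be nonnegative")
    row_sums = mat.sum(axis=1)
    keep_rows = row_sums > 0
    norm = np.zeros_like(mat)
    norm[keep_rows] = mat[keep_rows] / row_sums[keep_rows, None]
    model = NMF(
        n_components=n_modules,
        init="nndsvda" if n_modules <= min(norm.shape) else "random",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = model.fit_transform(norm)
    h = model.components_
    modules = pd.Series(
        np.argmax(w, axis=1) + 1, index=signal.index, name="module"
    )
    loadings = pd.DataFrame(
        w, index=signal.index, columns=[f"m{i + 1}" for i in range(n_modules)]
    )
    profiles = pd.DataFrame(
        h, index=loadings.columns, columns=signal.columns
    )
    return NmfResult(modules, loadings, profiles, float(model.reconstruction_err_))
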