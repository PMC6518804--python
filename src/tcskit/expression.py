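"""Heat-map normalization, hierarchical clustering, core-module extraction.

Expression matrices from different platforms (microarray atlas, nodule-zone
RNAseq, epidermis RNAseq) are never directly comparable, so each dataset
block is rescaled independently: a piecewise-linear map sends the block's
(min, median, max) to (0, 0.5, 1).  Genes are then clustered by
average-linkage agglomeration on Euclidean row distances, and the "core"
signaling module is defined, per family, as the gene with the highest
median expression across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .seqio import ExpressionMatrix

__all__ = [
    "HeatmapMatrix",
    "Dendrogram",
    "normalize_heatmap",
    "cluster_genes",
    "cut_largest_gap",
    "identify_core_module",
]


@dataclass
class HeatmapMatrix:
    """Per-dataset-block [0,1]-rescaled values; block median maps to 0.5."""

    values: pd.DataFrame
    dataset_ids: dict[str, str]
    anchor: float = 0.5


@dataclass
class Dendrogram:
    """A merge sequence over genes with non-decreasing heights."""

    labels: list[str]
    linkage_matrix: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, n_clusters: int) -> dict[str, int]:
        assignment = fcluster(self.linkage_matrix, n_clusters,
                              criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))


def _rescale_block(block: np.ndarray) -> np.ndarray:
    """Piecewise-linear (min, median, max) -> (0, 0.5, 1) on finite values."""
    finite = block[np.isfinite(block)]
    if finite.size == 0:
        raise ValueError("dataset block contains no values")
    lo, med, hi = finite.min(), float(np.median(finite)), finite.max()
    out = np.full_like(block, np.nan, dtype=float)
    mask = np.isfinite(block)
    if lo == hi:  # constant block
        out[mask] = 0.5
        return out
    v = block[mask]
    scaled = np.empty_like(v)
    low = v <= med
    if med > lo:
        scaled[low] = 0.5 * (v[low] - lo) / (med - lo)
    else:
        scaled[low] = 0.5
    if hi > med:
        scaled[~low] = 0.5 + 0.5 * (v[~low] - med) / (hi - med)
    else:
        scaled[~low] = 0.5
    out[mask] = scaled
    return out


def normalize_heatmap(m: ExpressionMatrix) -> HeatmapMatrix:
    """Rescale each dataset block of log2 values independently to [0, 1].

    Missing values (no probe) stay NaN; a constant block maps to 0.5
    everywhere.
    """
    out = m.values.copy().astype(float)
    for _, cols in m.blocks().items():
        block = m.values[cols].to_numpy(dtype=float)
        out[cols] = _rescale_block(block)
    return HeatmapMatrix(values=out, dataset_ids=dict(m.dataset_ids))


def cluster_genes(m: ExpressionMatrix) -> Dendrogram:
    """Average-linkage clustering of genes on Euclidean row distances.

    Missing values are imputed as the dataset-block median (with a
    warning), matching the convention that absent probes are uninformative
    rather than zero.
    """
    if len(m.genes) < 2:
        raise ValueError("clustering requires at least 2 genes")
    values = m.values.copy().astype(float)
    if values.isna().any().any():
        warnings.warn("missing expression values imputed as block medians",
                      stacklevel=2)
        for _, cols in m.blocks().items():
            med = float(np.nanmedian(values[cols].to_numpy()))
            values[cols] = values[cols].fillna(med)
    link = linkage(pdist(values.to_numpy(), metric="euclidean"),
                   method="average")
    return Dendrogram(labels=list(values.index), linkage_matrix=link)


def cut_largest_gap(dendrogram: Dendrogram) -> dict[str, int]:
    """Cut the dendrogram at the largest gap between merge heights."""
    heights = dendrogram.heights
    if len(heights) == 1:
        return dendrogram.cut(2)
    gaps = np.diff(heights)
    k = len(heights) - int(np.argmax(gaps))  # clusters above the gap
    return dendrogram.cut(k)


def identify_core_module(
    m: ExpressionMatrix,
    families: Mapping[str, str],
    target_families: tuple[str, ...] = ("CHK", "HPT", "RRB"),
) -> dict[str, str]:
    """The most highly expressed gene per family.

    "Most highly expressed" is the highest median over all samples
    (missing values excluded); ties break by mean, then by gene label.
    Families absent from the matrix are omitted with a warning.
    """
    medians = m.values.median(axis=1, skipna=True)
    means = m.values.mean(axis=1, skipna=True)
    core: dict[str, str] = {}
    for fam in target_families:
        members = [g for g in m.genes if families.get(g) == fam]
        if not members:
            warnings.warn(f"family {fam} absent from expression matrix",
                          stacklevel=2)
            continue
        core[fam] = max(
            members,
            key=lambda g: (medians[g], means[g], g),
        )
    return core
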