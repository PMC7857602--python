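"""Assignment of genes to DV expression clusters from 8x8 heat maps.

Genes are grouped by how far their predicted expression reaches along the
8-bin DV axis: ventrally restricted genes (bins 1-4) form cluster 1, genes
reaching bin 5 form cluster 2, genes reaching bins 6-7 form cluster 3, and
genes that are uniform, dorsally enriched, empty, or reach bin 8 form
cluster 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import GridHeatmap

__all__ = [
    "GeneClusterAssignment",
    "expressed_bins",
    "assign_cluster",
    "cluster_heatmap",
]


@dataclass(frozen=True)
class GeneClusterAssignment:
    gene: str
    expressed_bins: frozenset[int]
    cluster: int


def expressed_bins(dv_profile, cutoff: float = 0.5) -> frozenset[int]:
    """1-indexed DV positions whose expression exceeds the cutoff (A.U.)."""
    values = np.asarray(dv_profile, dtype=float)
    if values.shape != (8,):
        raise ValueError("dv_profile must have exactly 8 values")
    return frozenset(int(i) + 1 for i in np.flatnonzero(values > cutoff))


def assign_cluster(bins: frozenset[int] | set[int], dorsal_enrichment: bool = False) -> int:
    """Cluster from the dorsal-most expressed DV bin.

    Largest expressed bin <= 4 -> cluster 1; == 5 -> cluster 2; 6 or 7 ->
    cluster 3; bin 8 expressed, nothing expressed, or dorsally enriched
    expression -> cluster 4.
    """
    bins = set(bins)
    if not bins <= set(range(1, 9)):
        raise ValueError("expressed bins must be DV positions 1..8")
    if dorsal_enrichment or not bins or 8 in bins:
        return 4
    top = max(bins)
    if top <= 4:
        return 1
    if top == 5:
        return 2
    return 3


def cluster_heatmap(
    heatmap: GridHeatmap, gene: str | None = None, cutoff: float = 0.5
) -> GeneClusterAssignment:
    """Cluster a gene from its heat map's DV profile.

    Dorsal enrichment (more summed expression in bins 5-8 than 1-4) routes
    to cluster 4 regardless of reach.
    """
    bins = expressed_bins(heatmap.dv_profile, cutoff)
    dorsal = float(np.sum(heatmap.dv_profile[4:])) > float(np.sum(heatmap.dv_profile[:4]))
    name = gene if gene is not None else heatmap.channel
    return GeneClusterAssignment(name, bins, assign_cluster(bins, dorsal))
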