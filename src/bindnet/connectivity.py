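"""Per-participant functional network construction.

The chain mirrors the standard static-FC recipe for task fMRI: average voxel
signals within each parcel, correlate every pair of regional time series
(Pearson), extract a maximum-weight spanning tree so the network is connected
by construction, then densify with the strongest remaining correlations up to
a fixed edge density (10% by default). The binary mask multiplied back onto
the correlation matrix gives the weighted, thresholded network used by all
group-level statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._graph import DisjointSet

__all__ = [
    "TimeSeriesPanel",
    "FCMatrix",
    "BinaryNetwork",
    "ThresholdedNetwork",
    "parcel_average",
    "fc_matrix",
    "mst_backbone",
    "densify_to_sparsity",
    "apply_mask",
]


def default_region_labels(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"R{i:0{width}d}" for i in range(n)]


@dataclass
class TimeSeriesPanel:
    """Frames x regions BOLD matrix for one subject under one condition."""

    data: np.ndarray
    tr_seconds: float
    subject: int | str = 0
    condition: str = ""
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("panel data must be 2-D (frames x regions)")
        if self.data.shape[0] < 3:
            raise ValueError("panel needs at least 3 frames")
        if not np.isfinite(self.data).all():
            raise ValueError("panel contains non-finite values")
        if not self.region_labels:
            self.region_labels = default_region_labels(self.data.shape[1])
        if len(self.region_labels) != self.data.shape[1]:
            raise ValueError("region_labels length does not match data columns")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    r: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("FC matrix must be square")
        if not self.region_labels:
            self.region_labels = default_region_labels(self.r.shape[0])

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryNetwork:
    """Symmetric boolean adjacency mask with zero diagonal."""

    mask: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.region_labels:
            self.region_labels = default_region_labels(self.mask.shape[0])

    @property
    def n_regions(self) -> int:
        return self.mask.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.triu(self.mask, 1).sum())

    @property
    def sparsity(self) -> float:
        n = self.n_regions
        return self.edge_count / (n * (n - 1) / 2)


@dataclass
class ThresholdedNetwork:
    """Weighted FC restricted to the binary mask (elementwise product)."""

    w: np.ndarray
    mask: BinaryNetwork

    @property
    def n_regions(self) -> int:
        return self.w.shape[0]


def parcel_average(
    voxels: np.ndarray,
    labels: np.ndarray,
    tr_seconds: float = 1.5,
    subject: int | str = 0,
    condition: str = "",
) -> TimeSeriesPanel:
    """Average a frames x voxels matrix into regional time series.

    ``labels`` maps each voxel (column) to its region; regions are ordered by
    sorted unique label. Every region must own at least one voxel.
    """
    voxels = np.asarray(voxels, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != voxels.shape[1]:
        raise ValueError("one label per voxel column is required")
    uniq = np.unique(labels)
    if uniq.size == 0:
        raise ValueError("no voxels supplied")
    data = np.column_stack([voxels[:, labels == u].mean(axis=1) for u in uniq])
    return TimeSeriesPanel(
        data=data,
        tr_seconds=tr_seconds,
        subject=subject,
        condition=condition,
        region_labels=[str(u) for u in uniq],
    )


def fc_matrix(panel: TimeSeriesPanel | np.ndarray, region_labels=None) -> FCMatrix:
    """Pairwise Pearson correlation between regional time series."""
    if isinstance(panel, TimeSeriesPanel):
        data = panel.data
        region_labels = region_labels or panel.region_labels
    else:
        data = np.asarray(panel, dtype=float)
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        name = region_labels[bad] if region_labels else str(bad)
        raise ValueError(f"region {name!r} has zero variance; correlation undefined")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r=r, region_labels=list(region_labels) if region_labels else [])


def _sorted_edges(r: np.ndarray, absolute: bool = False):
    """Upper-triangle edges sorted strongest-first with a lexicographic tie-break."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = np.abs(r[iu, ju]) if absolute else r[iu, ju]
    order = np.lexsort((ju, iu, -w))  # primary: descending weight
    return iu[order], ju[order]


def mst_backbone(fc: FCMatrix, absolute: bool = False) -> BinaryNetwork:
    """Maximum-weight spanning tree of the correlation graph.

    Equivalent to the minimum spanning tree on distance 1 - r. Kruskal with a
    deterministic (node-index) tie-break guarantees bit-reproducible output.
    With ``absolute=True`` edges are ranked by |r| instead of signed r.
    """
    r = fc.r
    n = fc.n_regions
    if n < 2:
        raise ValueError("need at least 2 regions for a spanning tree")
    off = r[~np.eye(n, dtype=bool)]
    if not np.isfinite(off).all():
        raise ValueError("non-finite correlation weights")
    mask = np.zeros((n, n), dtype=bool)
    ds = DisjointSet(n)
    picked = 0
    for i, j in zip(*_sorted_edges(r, absolute)):
        if ds.union(int(i), int(j)):
            mask[i, j] = mask[j, i] = True
            picked += 1
            if picked == n - 1:
                break
    return BinaryNetwork(mask=mask, region_labels=fc.region_labels)


def target_edge_count(n_regions: int, sparsity: float) -> int:
    """Ceiling of sparsity * N(N-1)/2 possible undirected edges."""
    return math.ceil(sparsity * n_regions * (n_regions - 1) / 2)


def densify_to_sparsity(
    fc: FCMatrix,
    backbone: BinaryNetwork,
    sparsity: float = 0.10,
    absolute: bool = False,
) -> BinaryNetwork:
    """Add strongest non-tree edges until the target edge density is reached.

    The spanning-tree backbone is always retained, so the result stays
    connected. If the target count falls below the tree's N-1 edges the
    backbone itself is returned (density raised to tree density).
    """
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must lie in (0, 1]")
    n = fc.n_regions
    target = target_edge_count(n, sparsity)
    mask = backbone.mask.copy()
    have = int(np.triu(mask, 1).sum())
    if target <= have:
        return BinaryNetwork(mask=mask, region_labels=fc.region_labels)
    for i, j in zip(*_sorted_edges(fc.r, absolute)):
        if not mask[i, j]:
            mask[i, j] = mask[j, i] = True
            have += 1
            if have == target:
                break
    return BinaryNetwork(mask=mask, region_labels=fc.region_labels)


def apply_mask(fc: FCMatrix, binary: BinaryNetwork) -> ThresholdedNetwork:
    """Elementwise product of the correlation matrix and the binary mask."""
    if fc.r.shape != binary.mask.shape:
        raise ValueError("FC matrix and mask shapes differ")
    w = fc.r * binary.mask
    np.fill_diagonal(w, 0.0)
    return ThresholdedNetwork(w=w, mask=binary)
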