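"""Nodal graph metrics on binary networks and their group-level comparison.

Local efficiency of node v is the mean inverse shortest-path length among the
neighbors of v, computed inside the subgraph those neighbors induce:

    E_loc(v) = 1 / (|N(v)| (|N(v)|-1)) * sum_{i != j in N(v)} 1 / d_ij

with d_ij an unweighted (edge-count) distance; unreachable pairs contribute 0
and nodes with fewer than two neighbors score 0. The binary mask is the
substrate: the printed formula counts edges, so weights play no role here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import BinaryNetwork
from .stats import bh_fdr, paired_t

__all__ = ["local_efficiency", "local_efficiency_all", "node_degree", "compare_nodal_metric"]


def _as_mask(binary: BinaryNetwork | np.ndarray) -> np.ndarray:
    mask = binary.mask if isinstance(binary, BinaryNetwork) else np.asarray(binary, dtype=bool)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError("adjacency mask must be square")
    return mask


def local_efficiency(binary: BinaryNetwork | np.ndarray, v: int) -> float:
    """Local efficiency of node ``v`` on the binary mask (BFS distances)."""
    mask = _as_mask(binary)
    n = mask.shape[0]
    if not (0 <= v < n):
        raise IndexError(f"node {v} out of range for {n} regions")
    neighbors = np.flatnonzero(mask[v])
    k = neighbors.size
    if k < 2:
        return 0.0
    sub = mask[np.ix_(neighbors, neighbors)]
    d = shortest_path(csr_matrix(sub), method="D", unweighted=True, directed=False)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv.sum() / (k * (k - 1)))


def local_efficiency_all(binary: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Local efficiency of every node, as a length-N vector."""
    mask = _as_mask(binary)
    return np.array([local_efficiency(mask, v) for v in range(mask.shape[0])])


def node_degree(binary: BinaryNetwork | np.ndarray, v: int | None = None):
    """Number of edges incident to ``v`` (or the full degree vector)."""
    mask = _as_mask(binary)
    deg = mask.sum(axis=1).astype(int)
    if v is None:
        return deg
    if not (0 <= v < mask.shape[0]):
        raise IndexError(f"node {v} out of range")
    return int(deg[v])


def compare_nodal_metric(
    binding: np.ndarray,
    either: np.ndarray,
    q: float = 0.05,
    region_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Paired comparison of a nodal metric between conditions, FDR-corrected.

    ``binding`` and ``either`` are subjects x regions arrays of the metric
    (same subjects, same region order). A paired t-test (binding - either) is
    run per region, two-tailed raw p-values are corrected with
    Benjamini-Hochberg across all regions, and a region is called significant
    when it survives FDR with a positive t (the reported direction of the
    effect).

    Returns a DataFrame with region, t, p, p_adjusted, significant.
    """
    binding = np.asarray(binding, dtype=float)
    either = np.asarray(either, dtype=float)
    if binding.shape != either.shape:
        raise ValueError("condition tables must have identical shape")
    n_subj, n_regions = binding.shape
    if n_subj < 3:
        raise ValueError("need at least 3 subjects for the paired comparison")
    labels = region_labels or [f"R{i:03d}" for i in range(n_regions)]

    t = np.empty(n_regions)
    p = np.empty(n_regions)
    for r in range(n_regions):
        res = paired_t(binding[:, r], either[:, r], allow_zero_variance=True)
        t[r] = res["t"]
        p[r] = res["p_two_sided"]
    reject, p_adj = bh_fdr(p, q)
    return pd.DataFrame(
        {
            "region": labels,
            "t": t,
            "p": p,
            "p_adjusted": p_adj,
            "significant": reject & (t > 0),
        }
    )
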