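"""Network-based statistic (NBS) on a subnetwork of interest.

Edge-wise paired t-tests between conditions produce a t-matrix; edges passing
the primary threshold (p < alpha in the configured tail) are kept and grouped
into connected components. Significance is assessed at the component level:
the null distribution of the maximal component size is built by randomly
swapping each subject's condition labels (a sign flip of the paired
differences, the exchangeable scheme for a within-subject design), and each
observed component gets p = (1 + #{null max >= size}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._graph import edge_components
from .stats import bh_fdr

__all__ = [
    "EdgeStats",
    "NBSComponent",
    "NBSResult",
    "extract_subnetwork_weights",
    "edge_paired_tstats",
    "suprathreshold_components",
    "nbs_permutation_test",
    "edge_followup_tests",
]

TAILS = ("greater", "less", "two_sided")


@dataclass
class EdgeStats:
    """Symmetric edge-wise paired t and p matrices over k subnetwork nodes."""

    t: np.ndarray
    p: np.ndarray
    tail: str
    node_labels: list[str] = field(default_factory=list)
    edge_mask: np.ndarray | None = None  # edges actually tested


@dataclass
class NBSComponent:
    edges: list[tuple[int, int]]
    p_value: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> list[int]:
        return sorted({v for e in self.edges for v in e})


@dataclass
class NBSResult:
    components: list[NBSComponent]
    null_max_sizes: np.ndarray
    alpha_primary: float
    n_perm: int
    seed: int
    tail: str
    edge_stats: EdgeStats

    @property
    def significant_components(self) -> list[NBSComponent]:
        return [c for c in self.components if c.p_value < 0.05]


def extract_subnetwork_weights(
    masked_weights: list[np.ndarray] | np.ndarray, node_indices
) -> np.ndarray:
    """Stack per-subject masked weight matrices restricted to a node subset.

    Returns subjects x k x k. Edges absent from a subject's thresholded
    network carry weight 0, so the union of subject masks is the effective
    edge universe.
    """
    idx = np.asarray(node_indices, dtype=int)
    if len(np.unique(idx)) != idx.size:
        raise ValueError("subnetwork node indices must be distinct")
    stacked = np.stack([np.asarray(w, dtype=float) for w in masked_weights])
    return stacked[:, idx[:, None], idx[None, :]]


def _pair_diffs(binding: np.ndarray, either: np.ndarray) -> tuple[np.ndarray, tuple]:
    binding = np.asarray(binding, dtype=float)
    either = np.asarray(either, dtype=float)
    if binding.shape != either.shape:
        raise ValueError("paired design requires identical shapes in both conditions")
    if binding.ndim != 3 or binding.shape[1] != binding.shape[2]:
        raise ValueError("expected subjects x k x k weight arrays")
    n, k, _ = binding.shape
    if k < 2:
        raise ValueError("need at least 2 subnetwork nodes")
    iu, ju = np.triu_indices(k, 1)
    d = (binding - either)[:, iu, ju]  # subjects x edges
    return d, (n, k, iu, ju)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    """Vectorized paired t over columns; zero-variance columns get t = 0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = 0.0
    return t


def _p_from_t(t: np.ndarray, df: int, tail: str) -> np.ndarray:
    if tail == "greater":
        return stats.t.sf(t, df)
    if tail == "less":
        return stats.t.cdf(t, df)
    if tail == "two_sided":
        return 2 * stats.t.sf(np.abs(t), df)
    raise ValueError(f"unknown tail {tail!r}")


def edge_paired_tstats(
    binding: np.ndarray,
    either: np.ndarray,
    tail: str = "greater",
    node_labels: list[str] | None = None,
    edge_mask: np.ndarray | None = None,
) -> EdgeStats:
    """Paired t and p per upper-triangle edge, filled symmetrically.

    ``edge_mask`` (k x k boolean) restricts testing to an edge universe, e.g.
    the union of subjects' thresholded-network masks on the subnetwork;
    excluded edges get t = 0, p = 1. Zero-variance differences are reported
    subthreshold (t = 0, p = 1) rather than undefined.
    """
    d, (n, k, iu, ju) = _pair_diffs(binding, either)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    t_flat = _t_from_diffs(d)
    p_flat = _p_from_t(t_flat, n - 1, tail)
    p_flat[d.std(axis=0, ddof=1) == 0] = 1.0
    if edge_mask is not None:
        keep = np.asarray(edge_mask, dtype=bool)[iu, ju]
        t_flat = np.where(keep, t_flat, 0.0)
        p_flat = np.where(keep, p_flat, 1.0)
    t = np.zeros((k, k))
    p = np.ones((k, k))
    t[iu, ju] = t[ju, iu] = t_flat
    p[iu, ju] = p[ju, iu] = p_flat
    np.fill_diagonal(p, 1.0)
    return EdgeStats(
        t=t,
        p=p,
        tail=tail,
        node_labels=node_labels or [f"n{i}" for i in range(k)],
        edge_mask=edge_mask,
    )


def suprathreshold_components(
    edge_stats: EdgeStats, alpha_primary: float = 0.05
) -> list[NBSComponent]:
    """Connected components of edges with p < alpha in the configured tail."""
    k = edge_stats.p.shape[0]
    iu, ju = np.triu_indices(k, 1)
    keep = edge_stats.p[iu, ju] < alpha_primary
    edges = [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]
    return [NBSComponent(edges=c) for c in edge_components(edges, k)]


def _max_component_size(t_flat: np.ndarray, crit, iu, ju, k: int, tail: str) -> int:
    if tail == "greater":
        keep = t_flat > crit
    elif tail == "less":
        keep = t_flat < -crit
    else:
        keep = np.abs(t_flat) > crit
    if not keep.any():
        return 0
    edges = [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]
    comps = edge_components(edges, k)
    return len(comps[0]) if comps else 0


def nbs_permutation_test(
    binding: np.ndarray,
    either: np.ndarray,
    alpha_primary: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str = "greater",
    node_labels: list[str] | None = None,
    edge_mask: np.ndarray | None = None,
) -> NBSResult:
    """Component-level permutation inference on the subnetwork edges.

    Each permutation independently swaps every subject's condition labels
    (sign-flipping that subject's paired differences), recomputes the edge
    t-matrix, applies the same primary threshold and records the maximal
    component size. Observed component p-values use the add-one estimator
    p = (1 + #{null max >= observed size}) / (1 + n_perm).
    """
    import warnings as _warnings

    if n_perm < 100:
        _warnings.warn("n_perm < 100 gives a very coarse null; increase it", stacklevel=2)
    if tail not in TAILS:
        raise ValueError(f"unknown tail {tail!r}")
    d, (n, k, iu, ju) = _pair_diffs(binding, either)
    if edge_mask is not None:
        keep_universe = np.asarray(edge_mask, dtype=bool)[iu, ju]
        d = d * keep_universe  # excluded edges carry zero difference -> t = 0

    observed = edge_paired_tstats(
        binding, either, tail=tail, node_labels=node_labels, edge_mask=edge_mask
    )
    components = suprathreshold_components(observed, alpha_primary)

    df = n - 1
    crit = float(stats.t.isf(alpha_primary if tail != "two_sided" else alpha_primary / 2, df))

    # Sign-flip null, fully vectorized: with fixed sum(d^2) per edge, the
    # permuted t depends only on the flipped mean.
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    ss = (d**2).sum(axis=0)  # invariant under sign flips
    null_max = np.zeros(n_perm, dtype=int)
    mean_p = signs @ d / n
    var_p = (ss[None, :] - n * mean_p**2) / (n - 1)
    var_p = np.clip(var_p, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = mean_p / np.sqrt(var_p / n)
    t_p[var_p == 0] = 0.0
    for b in range(n_perm):
        null_max[b] = _max_component_size(t_p[b], crit, iu, ju, k, tail)

    for comp in components:
        comp.p_value = float((1 + np.sum(null_max >= comp.size)) / (1 + n_perm))
    return NBSResult(
        components=components,
        null_max_sizes=null_max,
        alpha_primary=alpha_primary,
        n_perm=n_perm,
        seed=seed,
        tail=tail,
        edge_stats=observed,
    )


def edge_followup_tests(
    result: NBSResult,
    binding: np.ndarray,
    either: np.ndarray,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-edge paired t within each significant component, BH-corrected.

    FDR runs over the edges of each component separately; t-values are by
    construction identical to the component's entries in the observed edge
    t-matrix. Returns an empty table when there is no component.
    """
    d, (n, k, iu, ju) = _pair_diffs(binding, either)
    rows = []
    labels = result.edge_stats.node_labels
    for ci, comp in enumerate(result.components):
        if not comp.edges:
            continue
        ps, ts = [], []
        for i, j in comp.edges:
            ts.append(result.edge_stats.t[i, j])
            ps.append(result.edge_stats.p[i, j])
        reject, p_adj = bh_fdr(np.array(ps), q)
        for (i, j), t, p, r, pa in zip(comp.edges, ts, ps, reject, p_adj):
            rows.append(
                {
                    "component": ci,
                    "component_p": comp.p_value,
                    "node_i": labels[i],
                    "node_j": labels[j],
                    "t": t,
                    "p": p,
                    "p_adjusted": pa,
                    "significant": bool(r),
                    "direction": "binding>either" if t > 0 else "binding<either",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "component",
            "component_p",
            "node_i",
            "node_j",
            "t",
            "p",
            "p_adjusted",
            "significant",
            "direction",
        ],
    )
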