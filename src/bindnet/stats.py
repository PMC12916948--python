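"""Shared statistical primitives: BH-FDR, Spearman, paired t, brain-behavior links."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "bh_fdr",
    "spearman_correlation",
    "paired_t",
    "brain_behavior_correlation",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (rejection mask, adjusted p-values). Adjusted p uses the standard
    cumulative-minimum formula; rejection of p_(i) happens for all i up to the
    largest with p_(i) <= (i/m) q.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def spearman_correlation(x, y, method: str = "t_approx") -> CorrelationResult:
    """Spearman rank correlation with mid-rank ties.

    p-value from the t-approximation t = rho sqrt((n-2)/(1-rho^2)) by default
    (appropriate at the study's n = 40); ``method='permutation'`` switches to
    a permutation p (exact enumeration is impractical, so 10,000 resamples),
    sensible for very small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "permutation":
        rng = np.random.default_rng(0)

        def _stat(xp, yp):
            return np.corrcoef(stats.rankdata(xp), stats.rankdata(yp))[0, 1]

        res = stats.permutation_test(
            (x, y), _stat, permutation_type="pairings", n_resamples=10_000, random_state=rng
        )
        p = float(res.pvalue)
    else:
        if abs(rho) >= 1.0:
            p = _P_FLOOR
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p=max(p, _P_FLOOR), n=n)


def paired_t(x, y, allow_zero_variance: bool = False) -> dict:
    """Paired t-test on x - y with sample (n-1) standard deviation.

    Returns t, df, two-sided p and the one-sided p for the 'greater'
    direction. A zero-variance difference with zero mean is undefined and
    raises unless ``allow_zero_variance`` (then t = 0, p = 1, used when
    scanning many regions where some may be exactly tied); zero variance with
    a nonzero mean reports an infinite t at the machine p floor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if mean == 0:
            if allow_zero_variance:
                return {"t": 0.0, "df": df, "p_two_sided": 1.0, "p_greater": 1.0}
            raise ValueError("paired t undefined: all differences are zero")
        t = float(np.inf) if mean > 0 else float(-np.inf)
        p2 = _P_FLOOR
        pg = _P_FLOOR if mean > 0 else 1.0
        return {"t": t, "df": df, "p_two_sided": p2, "p_greater": pg}
    t = float(mean / (sd / np.sqrt(n)))
    return {
        "t": t,
        "df": df,
        "p_two_sided": float(2 * stats.t.sf(abs(t), df)),
        "p_greater": float(stats.t.sf(t, df)),
    }


def brain_behavior_correlation(
    weights: np.ndarray,
    behavior: np.ndarray,
    edge_labels: list[str] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each edge's weight with a behavioral score.

    ``weights`` is subjects x edges, ``behavior`` a per-subject scalar (e.g.
    mean RT in the binding condition). Each edge is tested with Spearman
    correlation and the family is corrected with Benjamini-Hochberg.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    behavior = np.asarray(behavior, dtype=float)
    if weights.shape[0] != behavior.size:
        raise ValueError("weights and behavior must cover the same subjects")
    if weights.shape[1] == 0:
        raise ValueError("need at least one edge")
    labels = edge_labels or [f"edge{i}" for i in range(weights.shape[1])]
    rhos, ps = [], []
    for e in range(weights.shape[1]):
        res = spearman_correlation(weights[:, e], behavior)
        rhos.append(res.rho)
        ps.append(res.p)
    reject, p_adj = bh_fdr(np.array(ps), q)
    return pd.DataFrame(
        {
            "edge": labels,
            "rho": rhos,
            "p": ps,
            "p_adjusted": p_adj,
            "significant": reject,
        }
    )
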