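"""Intrinsic neural timescales from trial-averaged autocorrelation functions.

The timescale of a region is the TR-scaled area under its sample ACF up to —
but not including — the first non-positive lag: TR * sum_{k=0}^{L-1} rho(k),
where L is the smallest lag with rho(L) <= 0. Because rho(0) = 1 the estimate
is never smaller than one TR. Short timescales mark transient, rapidly
varying activity; long ones mark sustained activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .connectivity import TimeSeriesPanel
from .stats import bh_fdr, paired_t

__all__ = [
    "ACFCurve",
    "epoch_average",
    "acf_estimate",
    "intrinsic_timescale",
    "timescale_table",
    "compare_timescales",
]


@dataclass
class ACFCurve:
    """Sample autocorrelation values at lags 0..max_lag for one series."""

    lags: np.ndarray
    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must align")


def epoch_average(
    panel: TimeSeriesPanel,
    onsets_seconds: np.ndarray,
    window_trs: int = 10,
) -> np.ndarray:
    """Trial-averaged regional series: mean over trials of fixed-length windows.

    Each window starts at the frame nearest the trial's fixation onset and
    spans ``window_trs`` frames. Returns a window_trs x regions array.
    """
    onsets = np.asarray(onsets_seconds, dtype=float)
    if onsets.size == 0:
        raise ValueError("no trial onsets supplied")
    if window_trs < 2:
        raise ValueError("window must span at least 2 frames")
    starts = np.rint(onsets / panel.tr_seconds).astype(int)
    if (starts < 0).any() or (starts + window_trs > panel.n_frames).any():
        raise ValueError("a trial window falls outside the panel")
    stacked = np.stack([panel.data[s : s + window_trs] for s in starts])
    return stacked.mean(axis=0)


def acf_estimate(series: np.ndarray, max_lag: int | None = None, tr_seconds: float = 1.5) -> ACFCurve:
    """Sample ACF with the denominator-T (biased) convention, rho(0) = 1.

    rho(k) = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2,
    which keeps |rho| <= 1 for every lag. Default max_lag is floor(T/2).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    T = x.size
    if max_lag is None:
        max_lag = T // 2
    if T < max_lag + 2:
        raise ValueError("series too short for the requested max_lag")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("constant series: autocorrelation undefined")
    values = np.array([float(xc[: T - k] @ xc[k:]) / denom for k in range(max_lag + 1)])
    return ACFCurve(lags=np.arange(max_lag + 1), values=values, tr_seconds=tr_seconds)


def intrinsic_timescale(acf: ACFCurve) -> tuple[float, int]:
    """TR-scaled sum of ACF values before the first non-positive lag.

    Returns (timescale in seconds, truncation lag L). When the ACF never
    becomes non-positive within max_lag the full curve is summed and a
    truncation warning is raised so the cut is never silent.
    """
    nonpos = np.flatnonzero(acf.values <= 0)
    if nonpos.size:
        L = int(nonpos[0])
    else:
        L = int(acf.lags[-1] + 1)
        warnings.warn(
            "ACF stayed positive through max_lag; timescale truncated at the "
            "end of the curve",
            stacklevel=2,
        )
    return float(acf.tr_seconds * acf.values[:L].sum()), L


def timescale_table(
    panels: dict,
    onsets: dict | None = None,
    window_trs: int = 10,
    max_lag: int | None = None,
) -> pd.DataFrame:
    """Per subject x condition x region timescale table.

    ``panels`` maps (subject, condition) -> TimeSeriesPanel. When ``onsets``
    provides trial onsets for the same keys, the ACF is estimated on the
    trial-averaged series; otherwise on the full continuous series.
    """
    rows = []
    for (subject, condition), panel in panels.items():
        if onsets is not None:
            data = epoch_average(panel, onsets[(subject, condition)], window_trs)
        else:
            data = panel.data
        for r, label in enumerate(panel.region_labels):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = acf_estimate(data[:, r], max_lag=max_lag, tr_seconds=panel.tr_seconds)
                ts, L = intrinsic_timescale(curve)
            rows.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "region": label,
                    "timescale_seconds": ts,
                    "truncation_lag": L,
                }
            )
    return pd.DataFrame(rows)


def compare_timescales(table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """All pairwise region comparisons of timescale, BH-corrected.

    ``table`` is tidy (subject, region, timescale_seconds) for one condition.
    Runs a paired t for every region pair across subjects and corrects the
    family with Benjamini-Hochberg. The output also carries each region's
    mean timescale so the direction is readable.
    """
    wide = table.pivot_table(
        index="subject", columns="region", values="timescale_seconds", sort=True
    )
    if wide.isna().any().any():
        raise ValueError("unbalanced timescale table: every subject needs every region")
    regions = list(wide.columns)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to compare")
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    means = wide.mean(axis=0)
    rows = []
    for a, b in combinations(regions, 2):
        res = paired_t(wide[a].to_numpy(), wide[b].to_numpy(), allow_zero_variance=True)
        rows.append(
            {
                "region_a": a,
                "region_b": b,
                "mean_a_seconds": float(means[a]),
                "mean_b_seconds": float(means[b]),
                "t": res["t"],
                "p": res["p_two_sided"],
            }
        )
    out = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(out["p"].to_numpy(), q)
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out
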