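"""Change-detection behavior: d-prime, per-cell summaries, 2x2 within-subject ANOVA.

Sensitivity follows the equal-variance signal-detection model,
d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate), with a configurable
correction for perfect rates. The repeated-measures ANOVA implements the
classical within-subject sums-of-squares decomposition for a 2x2 design,
testing each effect against its own subject-by-effect interaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["dprime", "summarize_behavior", "rm_anova_2x2"]


def _corrected_rate(count: int, n: int, correction: str) -> float:
    if correction == "loglinear":
        return (count + 0.5) / (n + 1.0)
    if correction == "clamp":
        rate = count / n
        floor = 1.0 / (2 * n)
        return float(np.clip(rate, floor, 1.0 - floor))
    raise ValueError(f"unknown correction {correction!r}")


def dprime(
    hits: int, n_signal: int, fas: int, n_noise: int, correction: str = "loglinear"
) -> float:
    """Equal-variance signal-detection sensitivity from raw counts.

    ``loglinear`` adds 0.5 to both numerators and 1 to both denominators
    unconditionally; ``clamp`` clips rates into [1/2n, 1 - 1/2n]. Either rule
    keeps d' finite when a rate is 0 or 1.
    """
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("d-prime undefined: a cell has no signal or no noise trials")
    if not (0 <= hits <= n_signal and 0 <= fas <= n_noise):
        raise ValueError("counts inconsistent with trial totals")
    h = _corrected_rate(hits, n_signal, correction)
    f = _corrected_rate(fas, n_noise, correction)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def summarize_behavior(
    trials: pd.DataFrame,
    correction: str = "loglinear",
    rt_correct_only: bool = True,
) -> pd.DataFrame:
    """Per subject x condition x set-size behavioral summary.

    Hit/false-alarm rates are reported uncorrected; d' uses the corrected
    rates. Mean RT is taken over correct trials only by default (the
    conventional choice for change detection), configurable via
    ``rt_correct_only``.
    """
    required = {"subject", "condition", "set_size", "is_change", "response", "rt_seconds"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials = trials.copy()
    trials["says_change"] = trials["response"] == "change"
    trials["correct"] = trials["says_change"] == trials["is_change"]
    rows = []
    for (subject, condition, set_size), cell in trials.groupby(
        ["subject", "condition", "set_size"], sort=True
    ):
        signal = cell[cell["is_change"]]
        noise = cell[~cell["is_change"]]
        if len(signal) == 0 or len(noise) == 0:
            raise ValueError(
                f"cell (subject={subject}, {condition}, set size {set_size}) "
                "lacks signal or noise trials"
            )
        hits = int(signal["says_change"].sum())
        fas = int(noise["says_change"].sum())
        rt_pool = cell[cell["correct"]] if rt_correct_only else cell
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "set_size": set_size,
                "hit_rate": hits / len(signal),
                "fa_rate": fas / len(noise),
                "dprime": dprime(hits, len(signal), fas, len(noise), correction),
                "mean_rt_correct_seconds": float(rt_pool["rt_seconds"].mean())
                if len(rt_pool)
                else float("nan"),
                "n_signal": len(signal),
                "n_noise": len(noise),
            }
        )
    return pd.DataFrame(rows)


def rm_anova_2x2(values: np.ndarray, factor_a: str = "condition", factor_b: str = "set_size"):
    """Two-way fully within-subject ANOVA for a 2x2 design.

    ``values`` is subjects x 2 (factor A) x 2 (factor B). Each effect is
    tested against its subject-by-effect interaction with (1, n-1) degrees of
    freedom; partial eta squared is SS_effect / (SS_effect + SS_error). For
    a df-1 effect this F equals the squared paired t on the within-subject
    contrast.

    Returns a DataFrame with one row per effect (A, B, A x B).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("values must be subjects x 2 x 2")
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(y).all():
        raise ValueError("missing cell in the repeated-measures design")

    grand = y.mean()
    subj = y.mean(axis=(1, 2))            # per-subject mean
    a_mean = y.mean(axis=(0, 2))          # factor A level means
    b_mean = y.mean(axis=(0, 1))
    ab_mean = y.mean(axis=0)              # 2x2 cell means
    sa = y.mean(axis=2)                   # subject x A
    sb = y.mean(axis=1)                   # subject x B

    ss_a = 2 * n * ((a_mean - grand) ** 2).sum()
    ss_b = 2 * n * ((b_mean - grand) ** 2).sum()
    ss_ab = n * ((ab_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((sa - a_mean[None, :] - subj[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((sb - b_mean[None, :] - subj[:, None] + grand) ** 2).sum()
    resid = (
        y
        - sa[:, :, None]
        - sb[:, None, :]
        - ab_mean[None, :, :]
        + subj[:, None, None]
        + a_mean[None, :, None]
        + b_mean[None, None, :]
        - grand
    )
    ss_abs = (resid**2).sum()

    rows = []
    for name, ss_eff, ss_err in (
        (factor_a, ss_a, ss_as),
        (factor_b, ss_b, ss_bs),
        (f"{factor_a} x {factor_b}", ss_ab, ss_abs),
    ):
        df1, df2 = 1, n - 1
        if ss_eff == 0:
            f = 0.0
        elif ss_err == 0:
            f = float("inf")
        else:
            f = (ss_eff / df1) / (ss_err / df2)
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append(
            {
                "effect": name,
                "F": float(f),
                "df1": df1,
                "df2": df2,
                "p": p,
                "partial_eta_sq": float(eta),
            }
        )
    return pd.DataFrame(rows)
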