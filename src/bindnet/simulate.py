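"""Synthetic multi-subject two-condition BOLD study generator.

Emulates a 40-subject change-detection fMRI design with two scanning
conditions — remembering either feature ("either") versus remembering the
color-location conjunction ("binding") — at TR = 1.5 s over a 200-region
parcellation. Ground truth is planted in three places:

* a subnetwork of regions whose pairwise coupling is stronger in the binding
  condition (``planted_edges`` get ``base_r + delta_r`` instead of ``base_r``),
* region-specific temporal autocorrelation via per-region AR(1) coefficients
  ``phi``, so intrinsic-timescale estimators have a planted ordering,
* equal-variance signal-detection behavior with per-cell d' and log-normal
  reaction times, optionally rank-linked to each subject's coupling strength.

Everything is deterministic given the master seed: each (subject, condition,
purpose) triple gets its own numpy SeedSequence spawn key, so panels, motion
traces and behavior can be regenerated independently and bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import TimeSeriesPanel, default_region_labels

__all__ = [
    "SimulationConfig",
    "condition_covariance",
    "ar_filtered_correlation",
    "simulate_panel",
    "simulate_motion",
    "make_trial_events",
    "simulate_behavior_trials",
]

CONDITIONS = ("either", "binding")
_COND_CODE = {"either": 0, "binding": 1}
_PURPOSE = {"panel": 0, "motion": 1, "events": 2, "behavior": 3, "coupling": 4}

# Trial anatomy (seconds): fixation, memory array, delay, test, feedback.
TRIAL_PHASES = (0.5, 0.5, 6.5, 2.0, 1.0)
TRIAL_FIXED_SECONDS = sum(TRIAL_PHASES)  # 10.5 s before the jittered ITI


def _clique_edges(nodes: tuple[int, ...]) -> tuple[tuple[int, int], ...]:
    return tuple(
        (nodes[a], nodes[b]) for a in range(len(nodes)) for b in range(a + 1, len(nodes))
    )


@dataclass
class SimulationConfig:
    """Study-level parameters of the synthetic design.

    Defaults reproduce the emulated study: 40 subjects, 200 regions,
    3 runs x 24 trials per condition (~792 frames at TR 1.5 s), an 8-region
    planted subnetwork with coupling raised by ``delta_r`` in the binding
    condition, heterogeneous AR(1) coefficients spanning 0.2-0.8, worse d'
    for binding and for set size 6, and slower binding reaction times.
    """

    n_subjects: int = 40
    n_regions: int = 200
    n_frames: int = 792
    tr_seconds: float = 1.5
    base_r: float = 0.2
    planted_edges: tuple[tuple[int, int], ...] = _clique_edges(tuple(range(8)))
    delta_r: float = 0.15
    phi: np.ndarray | None = None  # default: linspace(0.2, 0.8, n_regions)
    dprime_true: dict[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("either", 3): 2.8,
            ("either", 6): 1.8,
            ("binding", 3): 2.4,
            ("binding", 6): 1.2,
        }
    )
    criterion: float = 0.0
    rt_location: dict[str, float] = field(
        default_factory=lambda: {"either": float(np.log(0.9)), "binding": float(np.log(1.05))}
    )
    rt_scale: float = 0.25
    rt_weight_link: float = 0.4  # binding log-RT shift per unit of subject coupling excess
    coupling_sd: float = 0.25  # between-subject spread of the planted-coupling multiplier
    n_trials: int = 72  # per condition (3 runs x 24 trials)
    set_sizes: tuple[int, int] = (3, 6)
    iti_choices: tuple[float, ...] = (4.5, 6.0, 7.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if not (0 <= self.base_r < 1):
            raise ValueError("base_r must lie in [0, 1)")
        if self.base_r + self.delta_r >= 1:
            raise ValueError("base_r + delta_r must stay below 1 (invalid effect size)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.rt_scale < 0:
            raise ValueError("rt_scale must be non-negative")
        seen = set()
        for i, j in self.planted_edges:
            if i == j:
                raise ValueError("planted edges must be off-diagonal")
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError("planted edge index out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError("planted edges must be distinct")
            seen.add(key)
        if self.phi is None:
            self.phi = np.linspace(0.2, 0.8, self.n_regions)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (self.n_regions,):
            raise ValueError("phi must have one coefficient per region")
        if np.any((self.phi < 0) | (self.phi >= 1)):
            raise ValueError("phi coefficients must lie in [0, 1)")
        if self.n_frames < 4 * self.n_regions:
            warnings.warn(
                "n_frames < 4 * n_regions: FC estimates will be noisy", stacklevel=2
            )

    def rng(self, subject: int, condition: str | None, purpose: str) -> np.random.Generator:
        cond = -1 if condition is None else _COND_CODE[condition]
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(int(subject), cond + 1, _PURPOSE[purpose])
        )
        return np.random.default_rng(ss)

    @property
    def region_labels(self) -> list[str]:
        return default_region_labels(self.n_regions)


def _psd_repair(corr: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues at zero and re-normalize to unit diagonal."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= -1e-10:
        return corr, False
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired, True


def coupling_multiplier(config: SimulationConfig, subject: int) -> float:
    """Per-subject scaling of the planted coupling increment.

    Drawn once per subject (shared by both conditions) around 1.0 with spread
    ``coupling_sd``, clipped to [0.25, 1.75] so the target correlation stays
    valid. Also drives the optional RT link.
    """
    if config.coupling_sd == 0:
        return 1.0
    z = config.rng(subject, None, "coupling").standard_normal()
    return float(np.clip(1.0 + config.coupling_sd * z, 0.25, 1.75))


def condition_covariance(
    config: SimulationConfig, condition: str, subject: int | None = None
) -> np.ndarray:
    """Target innovation correlation matrix for one condition.

    Off-diagonal entries equal ``base_r`` everywhere except the planted edges,
    which get ``base_r + delta_r`` in the binding condition (scaled by the
    subject's coupling multiplier when a subject is given). Repaired to the
    nearest positive semi-definite correlation matrix by eigenvalue clipping
    when needed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n = config.n_regions
    corr = np.full((n, n), config.base_r)
    np.fill_diagonal(corr, 1.0)
    if condition == "binding" and config.delta_r != 0:
        mult = 1.0 if subject is None else coupling_multiplier(config, subject)
        delta = config.delta_r * mult
        if config.base_r + delta >= 1:
            raise ValueError("effective base_r + delta_r reached 1 after subject scaling")
        for i, j in config.planted_edges:
            corr[i, j] = corr[j, i] = config.base_r + delta
    repaired, changed = _psd_repair(corr)
    if changed:
        warnings.warn("target correlation repaired to PSD by eigenvalue clipping", stacklevel=2)
    return repaired


def ar_filtered_correlation(target_r: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Zero-lag correlation of AR(1) processes driven by correlated innovations.

    For x_i,t = phi_i x_i,t-1 + e_i,t with corr(e_i, e_j) = r_ij, the
    stationary cross-correlation is
    r_ij * sqrt((1 - phi_i^2)(1 - phi_j^2)) / (1 - phi_i phi_j).
    Used to predict the FC the generator actually realizes.
    """
    phi = np.asarray(phi, dtype=float)
    scale = np.sqrt(np.outer(1 - phi**2, 1 - phi**2)) / (1 - np.outer(phi, phi))
    out = target_r * scale
    np.fill_diagonal(out, 1.0)
    return out


def simulate_panel(config: SimulationConfig, subject: int, condition: str) -> TimeSeriesPanel:
    """Simulate one subject-condition frames x regions BOLD panel.

    Cross-sectionally correlated Gaussian innovations (from the condition's
    target correlation) pass through a per-region AR(1) recursion and are then
    standardized per region. A 50-frame burn-in removes the initial transient.
    """
    corr = condition_covariance(config, condition, subject=subject)
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = config.rng(subject, condition, "panel")
    burn = 50
    z = rng.standard_normal((config.n_frames + burn, config.n_regions))
    innov = z @ factor.T
    x = np.empty_like(innov)
    x[0] = innov[0]
    phi = config.phi
    for t in range(1, innov.shape[0]):
        x[t] = phi * x[t - 1] + innov[t]
    x = x[burn:]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return TimeSeriesPanel(
        data=x,
        tr_seconds=config.tr_seconds,
        subject=subject,
        condition=condition,
        region_labels=config.region_labels,
    )


def simulate_motion(
    config: SimulationConfig,
    subject: int,
    high_motion: bool = False,
    step_mm: float = 0.01,
    step_rad: float = 2e-4,
) -> np.ndarray:
    """Frames x 6 head-motion trace (3 translations mm, 3 rotations rad).

    A bounded Gaussian random walk; ``high_motion`` scales the steps 15x so
    the downstream mean framewise displacement exceeds the 0.5 mm exclusion
    threshold.
    """
    if config.n_frames < 2:
        raise ValueError("need at least 2 frames for a motion trace")
    scale = 15.0 if high_motion else 1.0
    rng = config.rng(subject, None, "motion")
    steps = rng.standard_normal((config.n_frames, 6))
    steps[:, :3] *= step_mm * scale
    steps[:, 3:] *= step_rad * scale
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    walk[:, :3] = np.clip(walk[:, :3], -3.0, 3.0)
    walk[:, 3:] = np.clip(walk[:, 3:], -0.05, 0.05)
    return walk


def _balanced_cells(config: SimulationConfig, rng: np.random.Generator):
    """Per-trial (set_size, is_change) labels, balanced 50/50 within each cell."""
    n = config.n_trials
    per_size = n // len(config.set_sizes)
    cells = []
    for s in config.set_sizes:
        half = per_size // 2
        cells += [(s, True)] * half + [(s, False)] * (per_size - half)
    while len(cells) < n:  # remainder trials, if any
        cells.append((config.set_sizes[len(cells) % len(config.set_sizes)], len(cells) % 2 == 0))
    perm = rng.permutation(len(cells))
    return [cells[k] for k in perm]


def make_trial_events(config: SimulationConfig, subject: int, condition: str):
    """Trial-event table for one subject-condition scan.

    Onsets start at the first fixation (t = 0) and advance by the fixed trial
    anatomy (0.5 fixation + 0.5 memory + 6.5 delay + 2.0 test + 1.0 feedback)
    plus a jittered ITI of 4.5, 6.0 or 7.5 s.
    """
    import pandas as pd

    rng = config.rng(subject, condition, "events")
    cells = _balanced_cells(config, rng)
    itis = rng.choice(config.iti_choices, size=config.n_trials)
    onsets = np.concatenate([[0.0], np.cumsum(TRIAL_FIXED_SECONDS + itis[:-1])])
    return pd.DataFrame(
        {
            "trial_index": np.arange(config.n_trials),
            "onset_seconds": onsets,
            "condition": condition,
            "set_size": [c[0] for c in cells],
            "is_change": [c[1] for c in cells],
            "iti_seconds": itis,
        }
    )


def simulate_behavior_trials(config: SimulationConfig, subject: int):
    """Simulate change-detection responses and RTs for both conditions.

    Equal-variance signal-detection model: on change trials the decision
    variable is N(d', 1), on no-change trials N(0, 1); "change" is reported
    when it exceeds the decision threshold d'/2 + criterion, i.e. the
    criterion is measured from the unbiased midpoint (the standard relative
    criterion c, so c = 0 gives symmetric hit and correct-rejection rates).
    RTs are log-normal with a per-condition
    location; when ``rt_weight_link`` is nonzero the binding location shifts
    with the subject's planted-coupling excess, planting a rank correlation
    between connection weights and RT across subjects.
    """
    import pandas as pd

    rng = config.rng(subject, None, "behavior")
    mult = coupling_multiplier(config, subject)
    frames = []
    for condition in CONDITIONS:
        events = make_trial_events(config, subject, condition)
        d = np.array(
            [config.dprime_true[(condition, s)] for s in events["set_size"]], dtype=float
        )
        signal = events["is_change"].to_numpy()
        evidence = rng.standard_normal(len(events)) + np.where(signal, d, 0.0)
        says_change = evidence > d / 2.0 + config.criterion
        loc = config.rt_location[condition]
        if condition == "binding":
            loc = loc + config.rt_weight_link * (mult - 1.0)
        rt = np.exp(loc + config.rt_scale * rng.standard_normal(len(events)))
        df = events.copy()
        df["subject"] = subject
        df["response"] = np.where(says_change, "change", "no_change")
        df["rt_seconds"] = rt
        df["correct"] = says_change == signal
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
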