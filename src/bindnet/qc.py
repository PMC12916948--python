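"""Head-motion quality control: framewise displacement and subject exclusion."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = ["framewise_displacement", "exclude_high_motion", "PipelineAbort"]


class PipelineAbort(RuntimeError):
    """Raised when a QC step leaves nothing to analyze."""


def framewise_displacement(
    params: np.ndarray, sphere_radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Power-style framewise displacement from a frames x 6 motion trace.

    FD_t = sum |Delta translation_i| + sum |radius * Delta rotation_j| over the
    three translation (mm) and three rotation (radians) parameters. The first
    frame is assigned FD = 0 so the series aligns with frames; the returned
    mean is taken over frames 2..T.

    Returns (per-frame FD, mean FD).
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion trace must be frames x 6")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.isfinite(params).all():
        raise ValueError("motion trace contains non-finite values")
    diffs = np.abs(np.diff(params, axis=0))
    fd_body = diffs[:, :3].sum(axis=1) + sphere_radius_mm * diffs[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_body])
    return fd, float(fd_body.mean())


def exclude_high_motion(
    mean_fd: Mapping[int | str, float] | Sequence[float],
    threshold_mm: float = 0.5,
) -> tuple[list, list[str]]:
    """Drop subjects whose mean FD exceeds the threshold.

    Accepts a mapping subject -> mean FD (or a sequence, indexed 0..n-1).
    Returns (retained subject ids, per-subject decision log). Aborts if no
    subject survives.
    """
    if not isinstance(mean_fd, Mapping):
        mean_fd = {i: v for i, v in enumerate(mean_fd)}
    retained, log = [], []
    for subject, fd in mean_fd.items():
        if fd > threshold_mm:
            log.append(f"subject {subject}: mean FD {fd:.4f} mm > {threshold_mm} mm -> excluded")
        else:
            retained.append(subject)
            log.append(f"subject {subject}: mean FD {fd:.4f} mm <= {threshold_mm} mm -> retained")
    if not retained:
        raise PipelineAbort("motion QC excluded every subject; nothing left to analyze")
    return retained, log
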