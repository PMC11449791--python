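"""Movement gating and individual theta-cycle detection.

A theta cycle is a candidate central peak of the theta-band signal flanked
by a pair of consecutive valleys, where peak and valleys all exceed (in
absolute value) the Hilbert envelope of the low-frequency band at their
sample, the valley separation lies within [71, 200] ms (≈14 down to ≈5 Hz),
and the whole cycle falls inside a movement epoch (velocity > 2 cm/s).
Adjacent cycles may share a boundary valley, as successive cycles of a
continuous rhythm do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .emd import BandSignals, local_maxima, local_minima

__all__ = ["CycleDetectionParams", "ThetaCycle", "movement_mask", "detect_cycles",
           "cycles_to_frame"]


@dataclass
class CycleDetectionParams:
    velocity_thresh: float = 2.0     # cm/s, strict >
    min_valley_sep_ms: float = 71.0  # ~14 Hz
    max_valley_sep_ms: float = 200.0  # ~5 Hz
    min_epoch_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_valley_sep_ms < self.max_valley_sep_ms:
            raise ValueError("need 0 < min_valley_sep_ms < max_valley_sep_ms")


@dataclass
class ThetaCycle:
    peak_idx: int
    valley_left_idx: int
    valley_right_idx: int
    fs_hz: float
    slope_30_50: float | None = None

    def __post_init__(self) -> None:
        if not self.valley_left_idx < self.peak_idx < self.valley_right_idx:
            raise ValueError("cycle indices must satisfy left < peak < right")

    @property
    def duration_ms(self) -> float:
        return (self.valley_right_idx - self.valley_left_idx) / self.fs_hz * 1e3

    @property
    def peak_s(self) -> float:
        return self.peak_idx / self.fs_hz


def movement_mask(
    velocity: np.ndarray,
    fs_vel: float,
    thresh: float = 2.0,
    n_lfp: int | None = None,
    fs_lfp: float | None = None,
    min_epoch_s: float = 0.5,
) -> np.ndarray:
    """Boolean movement mask, optionally resampled to the LFP time base.

    The comparison is strictly greater-than (a sample at exactly the
    threshold does not count as movement); epochs shorter than
    ``min_epoch_s`` are dropped. If ``n_lfp``/``fs_lfp`` are given the mask
    is transferred to the LFP grid by linear interpolation of the 0/1
    trace (>= 0.5 counts as moving).
    """
    velocity = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(velocity)):
        raise ValueError("velocity must be finite")
    raw = velocity > thresh
    # drop short epochs
    mask = raw.copy()
    min_len = int(round(min_epoch_s * fs_vel))
    if min_len > 1 and mask.any():
        edges = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            if e - s < min_len:
                mask[s:e] = False
    if n_lfp is None:
        return mask
    if fs_lfp is None:
        raise ValueError("fs_lfp required when resampling to the LFP base")
    t_vel = np.arange(velocity.size) / fs_vel
    t_lfp = np.arange(n_lfp) / fs_lfp
    interp = np.interp(t_lfp, t_vel, mask.astype(float))
    return interp >= 0.5


def _epochs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts, ends))


def detect_cycles(
    bands: BandSignals,
    mask: np.ndarray | None = None,
    params: CycleDetectionParams | None = None,
) -> list[ThetaCycle]:
    """Detect individual theta cycles in the theta-band signal.

    Candidate peaks (local maxima) and valleys (local minima) of
    ``bands.theta`` qualify when they lie inside the movement mask and
    their absolute value exceeds the analytic-signal envelope of
    ``bands.low`` at the same sample. Each qualifying peak is paired with
    its nearest preceding and following qualifying valleys (no qualifying
    valley strictly between them) whose separation lies in
    ``[min, max]`` ms; assignment is greedy left-to-right, and adjacent
    cycles may share a boundary valley.
    """
    params = params or CycleDetectionParams()
    theta = bands.theta
    n = theta.size
    if mask is None:
        mask = np.ones(n, dtype=bool)
    if mask.size != n:
        raise ValueError("mask must be on the LFP time base")

    if not mask.any() or np.ptp(theta) == 0:
        return []
    low_env = np.abs(hilbert(bands.low)) if np.ptp(bands.low) > 0 else np.zeros(n)

    def qualifying(idx: np.ndarray) -> np.ndarray:
        keep = mask[idx] & (np.abs(theta[idx]) > low_env[idx])
        return idx[keep]

    peaks = qualifying(local_maxima(theta))
    valleys = qualifying(local_minima(theta))
    if peaks.size == 0 or valleys.size < 2:
        return []

    epochs = _epochs_of(mask)
    ep_starts = np.array([s for s, _ in epochs])
    ep_ends = np.array([e for _, e in epochs])

    min_sep = params.min_valley_sep_ms / 1e3 * bands.fs_hz
    max_sep = params.max_valley_sep_ms / 1e3 * bands.fs_hz

    cycles: list[ThetaCycle] = []
    last_right = -1
    for p in peaks:
        i = np.searchsorted(valleys, p)
        if i == 0 or i == valleys.size:
            continue
        v_left, v_right = valleys[i - 1], valleys[i]
        # consecutive valleys with exactly one qualifying peak between them
        between = peaks[(peaks > v_left) & (peaks < v_right)]
        if between.size != 1:
            continue
        sep = v_right - v_left
        if not (min_sep <= sep <= max_sep):
            continue
        # wholly inside one movement epoch
        k = np.searchsorted(ep_ends, v_left, side="right")
        if k >= ep_starts.size or not (ep_starts[k] <= v_left and v_right < ep_ends[k]):
            continue
        # greedy left-to-right; boundary valley may be shared
        if v_left < last_right:
            continue
        cycles.append(
            ThetaCycle(int(p), int(v_left), int(v_right), bands.fs_hz)
        )
        last_right = v_right
    return cycles


def tile_cycles(
    n_samples: int,
    fs_hz: float,
    window_ms: float = 125.0,
    mask: np.ndarray | None = None,
) -> list[ThetaCycle]:
    """Contiguous reference windows in the format of detected cycles.

    Tiles the record (or its masked epochs) with ``window_ms`` windows —
    the duration of a typical 8 Hz theta cycle. Used to calibrate the
    cycle-based spectral estimators on signals with a known spectrum,
    independently of the detector.
    """
    w = int(round(window_ms / 1e3 * fs_hz))
    if w < 2:
        raise ValueError("window too short")
    spans = _epochs_of(mask) if mask is not None else [(0, n_samples)]
    out = []
    for s, e in spans:
        for i0 in range(s, e - w, w):
            out.append(ThetaCycle(i0 + w // 2, i0, i0 + w, fs_hz))
    return out


def cycles_to_frame(cycles: list[ThetaCycle]) -> pd.DataFrame:
    """Tabulate cycles (seconds / ms) for CSV export."""
    return pd.DataFrame(
        {
            "peak_s": [c.peak_s for c in cycles],
            "valley_left_s": [c.valley_left_idx / c.fs_hz for c in cycles],
            "valley_right_s": [c.valley_right_idx / c.fs_hz for c in cycles],
            "duration_ms": [c.duration_ms for c in cycles],
            "slope_30_50": [c.slope_30_50 for c in cycles],
        }
    )
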