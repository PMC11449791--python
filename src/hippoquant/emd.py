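"""Empirical mode decomposition and instantaneous-frequency band grouping.

The LFP is decomposed into intrinsic mode functions (IMFs) by classical
envelope sifting (Huang-style EMD), and each IMF is assigned to one of three
physiological bands by its mean Hilbert instantaneous frequency:

* ``low``   — mean IF below 5 Hz (slow envelope of the signal),
* ``theta`` — mean IF in [5, 12) Hz (the locomotion theta rhythm),
* ``supra`` — mean IF at or above 12 Hz (gamma and faster activity).

Because IMFs are extracted by subtraction, the decomposition is complete by
construction: ``sum(imfs) + residual`` reproduces the input to floating
precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

__all__ = [
    "IMFSet",
    "BandSignals",
    "emd",
    "mean_instantaneous_frequency",
    "band_combine",
    "local_maxima",
    "local_minima",
]


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima, 3-point rule with plateau handling.

    On a plateau of equal samples flanked by lower values, the first sample
    of the plateau is returned.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    d = np.diff(x)
    # run-compress plateaus, keeping each plateau's first sample
    keep = np.concatenate([[True], d != 0])
    xc = x[keep]
    if xc.size < 3:
        return np.array([], dtype=int)
    orig = np.flatnonzero(keep)
    dc = np.diff(xc)
    is_max = (dc[:-1] > 0) & (dc[1:] < 0)
    return orig[1:-1][is_max]


def local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima (see :func:`local_maxima`)."""
    return local_maxima(-np.asarray(x, dtype=float))


def _envelope(x: np.ndarray, ext: np.ndarray, kind: str) -> np.ndarray | None:
    """Cubic-spline envelope through extrema with mirror boundary extension.

    Mirrors up to two extrema about each end of the series, which suppresses
    the end swings of an unconstrained spline. Returns ``None`` when fewer
    than two extrema exist.
    """
    n = x.size
    if ext.size < 2:
        return None
    t = ext.astype(float)
    v = x[ext]
    n_mirror = min(2, ext.size)
    t_left = 2 * 0.0 - t[:n_mirror][::-1]
    v_left = v[:n_mirror][::-1]
    t_right = 2 * (n - 1.0) - t[-n_mirror:][::-1]
    v_right = v[-n_mirror:][::-1]
    tt = np.concatenate([t_left, t, t_right])
    vv = np.concatenate([v_left, v, v_right])
    # mirroring can duplicate an endpoint extremum; keep strictly increasing
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, vv = tt[keep], vv[keep]
    if tt.size < 2:
        return None
    cs = CubicSpline(tt, vv)
    return cs(np.arange(n, dtype=float))


@dataclass
class IMFSet:
    """EMD output: ordered IMFs (fastest first), residual and mean IFs."""

    imfs: np.ndarray  # (n_imfs, n_samples)
    residual: np.ndarray
    fs_hz: float
    mean_if_hz: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean_if_hz is None:
            self.mean_if_hz = np.array(
                [mean_instantaneous_frequency(imf, self.fs_hz) for imf in self.imfs]
            )

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        if len(self.imfs) == 0:
            return self.residual.copy()
        return self.imfs.sum(axis=0) + self.residual


def emd(
    series: np.ndarray,
    fs_hz: float,
    max_imfs: int = 12,
    stop_sd: float = 0.2,
    max_sift_iter: int = 100,
) -> IMFSet:
    """Classical EMD by envelope sifting.

    Each IMF is obtained by iterating ``h <- h - (upper_env + lower_env)/2``
    until the Cauchy criterion ``sum((h_prev-h)^2)/sum(h_prev^2) < stop_sd``
    or ``max_sift_iter`` sifts. Extraction stops when the residual has fewer
    than two maxima or minima (monotonic within plateaus) or ``max_imfs`` is
    reached.

    Parameters
    ----------
    series : array
        Input signal, length >= 64, finite.
    fs_hz : float
        Sampling rate, used only for the per-IMF mean instantaneous
        frequencies attached to the result.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 64:
        raise ValueError("emd requires a 1-D series of at least 64 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("emd requires finite input")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        maxima = local_maxima(residual)
        minima = local_minima(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        for _sift in range(max_sift_iter):
            upper = _envelope(h, local_maxima(h), "max")
            lower = _envelope(h, local_minima(h), "min")
            if upper is None or lower is None:
                break
            m = 0.5 * (upper + lower)
            h_new = h - m
            denom = float(np.sum(h**2))
            if denom == 0.0:
                h = h_new
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < stop_sd:
                break
        imfs.append(h)
        residual = residual - h
    imf_arr = np.asarray(imfs) if imfs else np.empty((0, x.size))
    return IMFSet(imfs=imf_arr, residual=residual, fs_hz=fs_hz)


def mean_instantaneous_frequency(
    imf: np.ndarray, fs: float, amplitude_weighted: bool = True
) -> float:
    """Mean Hilbert instantaneous frequency of one IMF, in Hz.

    The phase of the analytic signal is differentiated sample-wise; samples
    with negative instantaneous frequency (phase reversals from noise) are
    excluded. By default the mean is weighted by the analytic amplitude,
    which makes it robust to phase noise where the IMF is quiescent; set
    ``amplitude_weighted=False`` for the plain arithmetic mean.
    """
    imf = np.asarray(imf, dtype=float)
    if imf.size < 4 or np.ptp(imf) == 0:
        raise ValueError("instantaneous frequency undefined for constant IMF")
    analytic = hilbert(imf)
    phase = np.unwrap(np.angle(analytic))
    inst_f = np.gradient(phase) * fs / (2.0 * np.pi)
    amp = np.abs(analytic)
    valid = inst_f > 0
    if not np.any(valid):
        raise ValueError("no positive instantaneous frequencies in IMF")
    if amplitude_weighted:
        w = amp[valid]
        if w.sum() == 0:
            return float(np.mean(inst_f[valid]))
        return float(np.sum(inst_f[valid] * w) / np.sum(w))
    return float(np.mean(inst_f[valid]))


@dataclass
class BandSignals:
    """Low / theta / supra-theta components of a decomposed signal."""

    low: np.ndarray
    theta: np.ndarray
    supra: np.ndarray
    residual: np.ndarray
    fs_hz: float

    def reconstruct(self) -> np.ndarray:
        return self.low + self.theta + self.supra + self.residual


def band_combine(
    imfset: IMFSet, theta_lo: float = 5.0, theta_hi: float = 12.0
) -> BandSignals:
    """Group IMFs into low (<theta_lo), theta [theta_lo, theta_hi) and supra.

    Each IMF goes to exactly one band by its mean instantaneous frequency;
    the theta band is the closed-open interval ``[theta_lo, theta_hi)``.
    Bands with no IMF are zero series.
    """
    n = imfset.residual.size
    low = np.zeros(n)
    theta = np.zeros(n)
    supra = np.zeros(n)
    for imf, f in zip(imfset.imfs, imfset.mean_if_hz):
        if f < theta_lo:
            low += imf
        elif f < theta_hi:
            theta += imf
        else:
            supra += imf
    return BandSignals(
        low=low, theta=theta, supra=supra,
        residual=imfset.residual.copy(), fs_hz=imfset.fs_hz,
    )
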