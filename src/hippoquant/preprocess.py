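"""Signal conditioning: downsampling, mains notch filtering, z-scoring.

The canonical order is downsample -> notch -> z-score (the notch is designed
at the downsampled rate); :func:`preprocess` applies all three and logs the
parameters used into the recording's ``meta['provenance']``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import signal as sps

from .recording import Recording

__all__ = ["downsample", "notch_filter", "zscore", "preprocess"]

log = logging.getLogger(__name__)

# anti-alias cutoff as a fraction of the target rate; transition band ends
# below the new Nyquist
_AA_CUTOFF_FRAC = 0.45


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased rate reduction to ``target_fs`` via polyphase resampling.

    A linear-phase FIR low-pass with cutoff ``0.45 * target_fs`` is applied
    inside :func:`scipy.signal.resample_poly`, which also compensates the
    group delay, so passband components keep their timing and amplitude.
    Non-integer decimation factors take the same polyphase path (rational
    resampling); the velocity trace is untouched.
    """
    if target_fs > rec.fs_hz:
        raise ValueError("target_fs must not exceed the current rate")
    if math.isclose(target_fs, rec.fs_hz):
        return rec.replace(meta={**rec.meta})
    # rational approximation of the rate change
    frac = (target_fs / rec.fs_hz)
    from fractions import Fraction

    ratio = Fraction(frac).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    # FIR designed in the upsampled domain: cutoff 0.45*target_fs relative
    # to the upsampled Nyquist fs*up/2 -> normalized 0.9/down
    half_len = 25 * max(up, down)
    taps = sps.firwin(2 * half_len + 1, 0.9 / down, window=("kaiser", 5.0))
    out = sps.resample_poly(rec.samples, up, down, window=taps * up)
    new = rec.replace(samples=out, fs_hz=rec.fs_hz * up / down)
    new.meta.setdefault("provenance", []).append(
        {"op": "downsample", "target_fs": target_fs, "up": up, "down": down,
         "cutoff_hz": _AA_CUTOFF_FRAC * target_fs}
    )
    return new


def notch_filter(
    rec: Recording,
    base_hz: float = 50.0,
    n_harmonics: int | None = None,
    half_width_hz: float = 1.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-stop at the mains frequency and harmonics.

    Each harmonic ``k * base_hz`` receives an order-``order`` Butterworth
    band-stop of half-width ``half_width_hz``, applied forward-backward
    (``sosfiltfilt``) so the passband phase is untouched. By default every
    integer harmonic below 0.9x Nyquist is notched; harmonics at or above
    Nyquist are skipped with a logged notice.
    """
    nyq = rec.fs_hz / 2.0
    if base_hz >= nyq:
        raise ValueError("base_hz must be below Nyquist")
    if n_harmonics is None:
        n_harmonics = int(0.9 * nyq // base_hz)
    x = rec.samples.copy()
    applied = []
    for k in range(1, n_harmonics + 1):
        f0 = k * base_hz
        if f0 + half_width_hz >= nyq:
            log.info("notch harmonic %.0f Hz >= Nyquist, skipped", f0)
            continue
        sos = sps.butter(
            order, [f0 - half_width_hz, f0 + half_width_hz],
            btype="bandstop", fs=rec.fs_hz, output="sos",
        )
        x = sps.sosfiltfilt(sos, x)
        applied.append(f0)
    new = rec.replace(samples=x)
    new.meta.setdefault("provenance", []).append(
        {"op": "notch", "base_hz": base_hz, "harmonics_hz": applied,
         "half_width_hz": half_width_hz, "order": order, "zero_phase": True}
    )
    return new


def zscore(rec: Recording) -> Recording:
    """Normalize to zero mean and unit sample (n-1) standard deviation."""
    sd = float(np.std(rec.samples, ddof=1))
    if not np.isfinite(sd) or sd < 1e-12 * (1.0 + abs(float(rec.samples.mean()))):
        raise ValueError("cannot z-score a constant signal")
    x = (rec.samples - rec.samples.mean()) / sd
    new = rec.replace(samples=x)
    new.meta.setdefault("provenance", []).append({"op": "zscore", "ddof": 1})
    return new


def preprocess(
    rec: Recording,
    target_fs: float = 1000.0,
    notch_base_hz: float = 50.0,
    n_harmonics: int | None = None,
) -> Recording:
    """Full conditioning chain: downsample, notch mains, z-score."""
    out = downsample(rec, target_fs)
    out = notch_filter(out, base_hz=notch_base_hz, n_harmonics=n_harmonics)
    return zscore(out)
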