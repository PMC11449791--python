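"""PSD estimation and the 30–50 Hz log-log spectral slope (E:I proxy).

A flatter (less negative) 1/f slope of the LFP power spectrum in the
30–50 Hz band is read as a shift of the circuit toward excitation. Two
estimators are provided, mirroring the two levels of the analysis:

* :func:`pooled_theta_psd` — concatenate all detected theta cycles and run
  Welch's method on the concatenation (group-level spectrum);
* :func:`cycle_psd` — a Hamming-windowed, zero-padded periodogram of one
  cycle (per-cycle slope samples for inferential statistics).

The slope itself is an ordinary least-squares fit of ``log10(power)`` on
``log10(frequency)`` over the band, exposed both functionally
(:func:`fit_slope`) and as a model/results pair
(:class:`SpectralSlopeModel` / :class:`SpectralSlopeResults`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal as sps

from .cycles import ThetaCycle
from .recording import Recording

__all__ = [
    "PSDEstimate",
    "SlopeFit",
    "welch_psd",
    "pooled_theta_psd",
    "cycle_psd",
    "fit_slope",
    "per_cycle_slopes",
    "SpectralSlopeModel",
    "SpectralSlopeResults",
]

RESOLUTION_HZ = 0.2  # frequency-grid spacing of all PSD estimates
WINDOW_S = 5.0       # Welch segment length
OVERLAP = 0.5
SLOPE_BAND = (30.0, 50.0)


@dataclass
class PSDEstimate:
    """One-sided PSD on a uniform frequency grid."""

    freq_hz: np.ndarray
    power: np.ndarray
    window_s: float = WINDOW_S
    overlap_frac: float = OVERLAP
    resolution_hz: float = RESOLUTION_HZ

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freq_hz.size != self.power.size:
            raise ValueError("freq/power size mismatch")
        if np.any(np.diff(self.freq_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def band(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        sel = (self.freq_hz >= lo) & (self.freq_hz <= hi)
        return self.freq_hz[sel], self.power[sel]


def _nfft(fs: float) -> int:
    return int(round(fs / RESOLUTION_HZ))


def welch_psd(
    series: np.ndarray,
    fs: float,
    window_s: float = WINDOW_S,
    overlap: float = OVERLAP,
    resolution_hz: float = RESOLUTION_HZ,
) -> PSDEstimate:
    """Welch PSD: Hamming-tapered segments, 50% overlap, 0.2 Hz grid.

    Series shorter than one window are zero-padded (single-segment path),
    keeping the frequency grid contract.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    nfft = int(round(fs / resolution_hz))
    nperseg = min(x.size, int(round(window_s * fs)))
    f, p = sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=int(nperseg * overlap), nfft=max(nfft, nperseg),
        detrend="constant",
    )
    return PSDEstimate(f, p, window_s, overlap, resolution_hz)


def _taper_snippet(x: np.ndarray, fs: float, taper_s: float = 0.005) -> np.ndarray:
    """5 ms raised-cosine edge taper, to suppress splice artifacts."""
    m = int(round(taper_s * fs))
    if m < 1 or 2 * m >= x.size:
        return x
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
    out = x.copy()
    out[:m] *= ramp
    out[-m:] *= ramp[::-1]
    return out


def pooled_theta_psd(rec: Recording, cycles: list[ThetaCycle]) -> PSDEstimate:
    """Welch PSD of all theta cycles concatenated in time order.

    Valley-to-valley snippets are edge-tapered (5 ms cosine) and spliced;
    Welch's method then runs on the concatenation, so the estimate reflects
    theta-cycle content only.
    """
    if not cycles:
        raise ValueError("no cycles to pool")
    ordered = sorted(cycles, key=lambda c: c.valley_left_idx)
    # adjacent cycles of a continuous rhythm share boundary valleys: merge
    # contiguous cycles into runs so only true splice points are tapered
    runs: list[tuple[int, int]] = []
    start, end = ordered[0].valley_left_idx, ordered[0].valley_right_idx
    for c in ordered[1:]:
        if c.valley_left_idx <= end:
            end = max(end, c.valley_right_idx)
        else:
            runs.append((start, end))
            start, end = c.valley_left_idx, c.valley_right_idx
    runs.append((start, end))
    snippets = [
        _taper_snippet(rec.samples[i0:i1 + 1], rec.fs_hz) for i0, i1 in runs
    ]
    return welch_psd(np.concatenate(snippets), rec.fs_hz)


def cycle_psd(rec: Recording, cycle: ThetaCycle) -> PSDEstimate:
    """Hamming-windowed periodogram of one cycle, zero-padded to 0.2 Hz."""
    snip = rec.samples[cycle.valley_left_idx:cycle.valley_right_idx + 1]
    if snip.size / rec.fs_hz * 1e3 < 71.0 - 1e-9:
        raise ValueError("cycle snippet shorter than 71 ms")
    f, p = sps.periodogram(
        snip, fs=rec.fs_hz, window="hamming", nfft=_nfft(rec.fs_hz),
        detrend="constant",
    )
    return PSDEstimate(f, p, window_s=snip.size / rec.fs_hz)


@dataclass
class SlopeFit:
    """OLS fit of log10(power) on log10(frequency) over a band."""

    a: float            # intercept, log10 power at 1 Hz
    b: float            # slope, log-power per log-Hz
    band_hz: tuple[float, float]
    r2: float
    n_points: int
    residual_var: float
    b_stderr: float

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SlopeFit(b={self.b:.3f}±{self.b_stderr:.3f}, a={self.a:.3f}, "
            f"r2={self.r2:.3f}, band={self.band_hz}, n={self.n_points})"
        )


class SpectralSlopeModel:
    """Log-log power-law model of a PSD band: log10 P = a + b·log10 f + ε.

    Parameters
    ----------
    psd : PSDEstimate
        The spectrum to fit.
    band : (lo, hi)
        Frequency band, endpoints inclusive; default 30–50 Hz.

    Grid points with non-positive power are dropped with a warning; at
    least three points must remain.
    """

    def __init__(
        self,
        psd: PSDEstimate,
        band: tuple[float, float] = SLOPE_BAND,
        exclude_hz: list[tuple[float, float]] | None = None,
    ):
        lo, hi = band
        f, p = psd.band(lo, hi)
        if exclude_hz:
            # e.g. the stopbands of applied notch filters: those bins were
            # deliberately emptied and carry no information about the slope
            keep = np.ones(f.size, dtype=bool)
            for xlo, xhi in exclude_hz:
                keep &= ~((f >= xlo) & (f <= xhi))
            f, p = f[keep], p[keep]
        if np.any(p <= 0):
            warnings.warn("dropping non-positive power values in fit band",
                          stacklevel=2)
            keep = p > 0
            f, p = f[keep], p[keep]
        if f.size < 3:
            raise ValueError("need at least 3 positive-power points in band")
        self.band = (float(lo), float(hi))
        self.logf = np.log10(f)
        self.logp = np.log10(p)

    @classmethod
    def from_recording(
        cls,
        rec: Recording,
        cycles: list[ThetaCycle],
        band: tuple[float, float] = SLOPE_BAND,
    ) -> "SpectralSlopeModel":
        """Build from a recording by pooling its detected theta cycles."""
        return cls(pooled_theta_psd(rec, cycles), band)

    def fit(self) -> "SpectralSlopeResults":
        X = sm.add_constant(self.logf)
        res = sm.OLS(self.logp, X).fit()
        return SpectralSlopeResults(self, res)


class SpectralSlopeResults:
    """Results wrapper: estimates, uncertainties and a summary table."""

    def __init__(self, model: SpectralSlopeModel, ols_results):
        self.model = model
        self._ols = ols_results
        self.params = ols_results.params          # [a, b]
        self.bse = ols_results.bse
        self.tvalues = ols_results.tvalues
        self.pvalues = ols_results.pvalues
        self.rsquared = float(ols_results.rsquared)

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    @property
    def slope_stderr(self) -> float:
        return float(self.bse[1])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return self._ols.conf_int(alpha)

    def as_slope_fit(self) -> SlopeFit:
        resid = self._ols.resid
        dof = max(self._ols.df_resid, 1)
        return SlopeFit(
            a=self.intercept,
            b=self.slope,
            band_hz=self.model.band,
            r2=self.rsquared,
            n_points=self.model.logf.size,
            residual_var=float(resid @ resid / dof),
            b_stderr=self.slope_stderr,
        )

    def plot(self, psd: PSDEstimate | None = None, ax=None):
        """Log-log plot of the fitted band (and optionally the full PSD)
        with the regression line; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if psd is not None:
            ax.loglog(psd.freq_hz[1:], psd.power[1:], color="0.7", lw=0.8,
                      label="PSD")
        f = 10 ** self.model.logf
        ax.loglog(f, 10 ** self.model.logp, "k.", ms=3, label="fit band")
        ax.loglog(f, 10 ** (self.intercept + self.slope * self.model.logf),
                  "r-", label=f"slope {self.slope:.2f}")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("power spectral density")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        lines = [
            "Spectral slope fit: log10(P) = a + b*log10(f)",
            f"  band: {self.model.band[0]:.1f}-{self.model.band[1]:.1f} Hz "
            f"({self.model.logf.size} points)",
            f"  slope b     = {self.slope: .4f}  (SE {self.slope_stderr:.4f})",
            f"  intercept a = {self.intercept: .4f}  (SE {float(self.bse[0]):.4f})",
            f"  R^2         = {self.rsquared:.4f}",
        ]
        return "\n".join(lines)


def fit_slope(
    psd: PSDEstimate,
    band: tuple[float, float] = SLOPE_BAND,
    exclude_hz: list[tuple[float, float]] | None = None,
) -> SlopeFit:
    """Functional front-end: OLS log-log slope of a PSD over ``band``.

    ``exclude_hz`` drops frequency ranges from the fit — used by the
    pipeline to leave out applied notch stopbands.
    """
    return SpectralSlopeModel(psd, band, exclude_hz).fit().as_slope_fit()


def notch_exclusions(
    rec: Recording,
    band: tuple[float, float] = SLOPE_BAND,
    margin_hz: float = 3.0,
) -> list[tuple[float, float]]:
    """Notch stopbands (± ``margin_hz``) from the recording's provenance
    log that intersect ``band``; empty if no notch was applied."""
    out = []
    for step in rec.meta.get("provenance", []):
        if step.get("op") == "notch":
            for f0 in step.get("harmonics_hz", []):
                lo, hi = f0 - margin_hz, f0 + margin_hz
                if hi >= band[0] and lo <= band[1]:
                    out.append((lo, hi))
    return out


def per_cycle_slopes(
    rec: Recording,
    cycles: list[ThetaCycle],
    band: tuple[float, float] = SLOPE_BAND,
    exclude_hz: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Fitted 30–50 Hz slope of each cycle; also filled into the cycles.

    Equivalent to ``fit_slope(cycle_psd(rec, c))`` per cycle, but cycles
    of equal length are batched through one FFT and a closed-form OLS
    slope (the PSD scale factor cancels in the log-log slope).
    """
    nfft = _nfft(rec.fs_hz)
    grid = np.fft.rfftfreq(nfft, d=1.0 / rec.fs_hz)
    sel = (grid >= band[0]) & (grid <= band[1])
    for xlo, xhi in exclude_hz or []:
        sel &= ~((grid >= xlo) & (grid <= xhi))
    logf = np.log10(grid[sel])
    lf_c = logf - logf.mean()
    denom = float(lf_c @ lf_c)

    out = np.empty(len(cycles))
    by_len: dict[int, list[int]] = {}
    for i, c in enumerate(cycles):
        by_len.setdefault(c.valley_right_idx - c.valley_left_idx + 1, []).append(i)
    for length, idxs in by_len.items():
        if length / rec.fs_hz * 1e3 < 71.0 - 1e-9:
            raise ValueError("cycle snippet shorter than 71 ms")
        snips = np.stack(
            [rec.samples[cycles[i].valley_left_idx:
                         cycles[i].valley_left_idx + length] for i in idxs]
        )
        snips = snips - snips.mean(axis=1, keepdims=True)
        win = sps.get_window("hamming", length)
        spec = np.abs(np.fft.rfft(snips * win, n=nfft, axis=1)[:, sel]) ** 2
        logp = np.log10(np.clip(spec, 1e-300, None))
        b = (logp @ lf_c) / denom
        for k, i in enumerate(idxs):
            cycles[i].slope_30_50 = float(b[k])
            out[i] = b[k]
    return out
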