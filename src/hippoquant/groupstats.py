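"""Group-level inference on spectral slopes and morphometric measures.

Two routes mirror the two slope estimators: the group slopes come from a
log-log regression on each group's mean PSD, with the slope difference
tested through the group-interaction term of a pooled regression; the
per-cycle slope samples are compared by Welch's unequal-variance t test,
gated by Shapiro–Wilk normality with a Mann–Whitney U fallback. Outlier
screening uses the two-sided single-outlier Grubbs test at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as st

from .spectral import PSDEstimate, SLOPE_BAND, SpectralSlopeModel

__all__ = [
    "GroupComparison",
    "mean_psd",
    "compare_mean_psd_slopes",
    "welch_t",
    "shapiro_wilk",
    "grubbs_test",
    "mann_whitney_u",
    "summarize",
    "compare_samples",
]


@dataclass
class GroupComparison:
    """Two-group slope comparison: group fits plus the difference test."""

    slope_A: float
    slope_B: float
    t_stat: float
    df: float
    p_value: float
    test_name: str
    n_A: int
    n_B: int

    @property
    def difference(self) -> float:
        return self.slope_A - self.slope_B

    def summary(self) -> str:
        return (
            f"{self.test_name}: slope_A={self.slope_A:.3f} (n={self.n_A}), "
            f"slope_B={self.slope_B:.3f} (n={self.n_B}), "
            f"diff={self.difference:.3f}, t={self.t_stat:.3f}, "
            f"df={self.df:.1f}, p={self.p_value:.3g}"
        )


def mean_psd(psds: list[PSDEstimate]) -> PSDEstimate:
    """Pointwise arithmetic mean of PSDs sharing one frequency grid."""
    if not psds:
        raise ValueError("no PSDs")
    f0 = psds[0].freq_hz
    for p in psds[1:]:
        if p.freq_hz.size != f0.size or not np.allclose(p.freq_hz, f0):
            raise ValueError("frequency grids differ")
    power = np.mean([p.power for p in psds], axis=0)
    return PSDEstimate(f0.copy(), power)


def compare_mean_psd_slopes(
    psds_A: list[PSDEstimate],
    psds_B: list[PSDEstimate],
    band: tuple[float, float] = SLOPE_BAND,
    exclude_hz: list[tuple[float, float]] | None = None,
) -> GroupComparison:
    """Group slopes from mean PSDs; difference via pooled interaction OLS.

    Each group's slope is the log-log fit on its mean PSD. The two band
    spectra are then stacked into one regression
    ``log10 P ~ log10 f * group`` and the slope difference is the t test
    on the interaction coefficient. ``exclude_hz`` drops frequency ranges
    (e.g. notch stopbands) from both fits.
    """
    ma = SpectralSlopeModel(mean_psd(psds_A), band, exclude_hz)
    mb = SpectralSlopeModel(mean_psd(psds_B), band, exclude_hz)
    fit_a = ma.fit()
    fit_b = mb.fit()
    logf = np.concatenate([ma.logf, mb.logf])
    logp = np.concatenate([ma.logp, mb.logp])
    g = np.concatenate([np.zeros(ma.logf.size), np.ones(mb.logf.size)])
    X = sm.add_constant(np.column_stack([logf, g, logf * g]))
    res = sm.OLS(logp, X).fit()
    t = float(res.tvalues[3])
    p = float(res.pvalues[3])
    if not np.isfinite(t):  # identical groups: zero residual variance
        t, p = 0.0, 1.0
    return GroupComparison(
        slope_A=fit_a.slope,
        slope_B=fit_b.slope,
        t_stat=t,
        df=float(res.df_resid),
        p_value=p,
        test_name="mean-PSD log-log interaction t",
        n_A=len(psds_A),
        n_B=len(psds_B),
    )


def welch_t(sample_A, sample_B) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, two-sided p)."""
    a = np.asarray(sample_A, dtype=float)
    b = np.asarray(sample_B, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        return 0.0, float(a.size + b.size - 2), 1.0
    res = st.ttest_ind(a, b, equal_var=False)
    se2 = va / a.size + vb / b.size
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk normality test (Royston AS R94), 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = st.shapiro(x)
    return float(w), float(p)


def grubbs_test(
    sample, alpha: float = 0.05
) -> tuple[int | None, float, float]:
    """Two-sided single-outlier Grubbs test.

    Returns ``(index_of_outlier_or_None, G, G_crit)`` with
    ``G = max|x - mean| / s`` (sample SD) and the critical value from the
    t-distribution formula. At most one point is flagged per call; for the
    conventional iterative screen, remove the flagged point and call again.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        return None, 0.0, np.inf
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    G = float(dev[i] / s)
    t2 = st.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    G_crit = float((n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2)))
    return (i if G > G_crit else None), G, G_crit


def mann_whitney_u(sample_A, sample_B) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (exact when min(n) <= 8, else normal approx)."""
    a = np.asarray(sample_A, dtype=float)
    b = np.asarray(sample_B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    exact = min(a.size, b.size) <= 8
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if exact and not has_ties else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def summarize(sample) -> tuple[float, float, int]:
    """Mean, SEM (SD/sqrt(n), sample SD) and n. SEM of one value is 0."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if x.size == 1:
        warnings.warn("SEM of a single observation reported as 0", stacklevel=2)
        return float(x[0]), 0.0, 1
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), int(x.size)


def compare_samples(
    sample_A, sample_B, alpha: float = 0.05
) -> GroupComparison:
    """Normality-gated two-sample comparison of per-cycle slope samples.

    Welch's t when both samples pass Shapiro–Wilk at ``alpha``, otherwise
    the two-sided Mann–Whitney U test.
    """
    a = np.asarray(sample_A, dtype=float)
    b = np.asarray(sample_B, dtype=float)
    normal = shapiro_wilk(a)[1] > alpha and shapiro_wilk(b)[1] > alpha
    if normal:
        t, df, p = welch_t(a, b)
        name = "Welch t"
    else:
        t, p = mann_whitney_u(a, b)
        df = np.nan
        name = "Mann-Whitney U"
    return GroupComparison(
        slope_A=float(a.mean()), slope_B=float(b.mean()),
        t_stat=t, df=df, p_value=p, test_name=name,
        n_A=a.size, n_B=b.size,
    )
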