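# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical choices that shape the results.

## 1. Signal conditioning

Recordings are downsampled to 1 kHz with a linear-phase FIR anti-alias
filter (cutoff 0.45 × target rate, polyphase resampling, group delay
compensated; non-integer factors take the same rational-resampling path).
Mains contamination is removed with an order-4 Butterworth band-stop of
±1 Hz half-width at 50 Hz and every integer harmonic below 0.9 × Nyquist,
applied forward–backward so the passband phase is untouched. The trace is
then z-scored with the sample (n−1) standard deviation. The order —
downsample, notch, z-score — is fixed, and every step logs its parameters
into the recording's provenance block. The notch order, bandwidth and
zero-phase application are package defaults, exposed in the API: the
conditioning recipe itself only prescribes "a Butterworth bandstop of
around 50 Hz".

## 2. EMD and band grouping

Classical envelope sifting: cubic-spline envelopes through the maxima and
minima (with two extrema mirrored about each end to suppress end swings),
iterated until the Cauchy criterion Σ(h₁−h₀)²/Σh₀² < 0.2 or 100 sift
iterations, at most 12 IMFs, extraction stopping when the residual has
fewer than two extrema. These are the standard defaults of the original
sifting algorithm; the source method names EMD without parameters.
Because IMFs are obtained by subtraction, `sum(imfs) + residual`
reproduces the input to floating precision — the completeness tests
assert ≤ 1e-8 relative RMS and observe ~1e-16.

Each IMF's mean instantaneous frequency is the amplitude-weighted mean of
the analytic-signal phase derivative, excluding negative-frequency
samples; weighting makes the mean robust to phase noise where the IMF is
quiescent (the arithmetic mean is available via a flag). Bands are
closed–open: theta is [5, 12) Hz.

EMD is not unique, so no reference implementation can be matched sample
by sample (and none is available in this environment); correctness is
instead anchored to analytic oracles: tone mixtures at 2/8/40 Hz must
reassemble into low/theta/supra components correlating ≥ 0.95 with the
original tones, a 5→10 Hz chirp must average 7.5 Hz, and completeness
must hold for every input.

## 3. Theta-cycle detection

Movement is velocity > 2 cm/s (strictly greater; epochs under 0.5 s
dropped; the mask is transferred to the LFP grid by linear
interpolation). Candidate peaks and valleys are local extrema of the
theta band (3-point rule; the first sample of a plateau wins) whose
absolute value exceeds the Hilbert envelope of the low band at the same
sample — "envelope" is implemented as the analytic-signal magnitude, and
the criterion is applied to the peak and both valleys. A cycle is one
qualifying peak between two consecutive qualifying valleys separated by
71–200 ms, wholly inside one movement epoch. Assignment is greedy
left-to-right; adjacent cycles of a continuous rhythm share their
boundary valley, which is what makes 60 s of 8 Hz theta yield 479 cycles
rather than 240.

## 4. Spectral slope estimation

All PSDs live on a 0.2 Hz grid (nfft = fs / 0.2). The pooled estimator
concatenates the valley-to-valley cycle snippets — contiguous cycles are
merged into runs so only true splice points receive the 5 ms cosine edge
taper — and applies Welch's method with a Hamming 5 s window and 50 %
overlap. The per-cycle estimator is a Hamming-windowed, mean-removed
periodogram of the single snippet, zero-padded to the same grid; cycles
of equal length are batched through one FFT, which is algebraically
identical to the per-snippet path (the scale factor cancels in the
log-log slope).

The slope model is OLS of log₁₀ power on log₁₀ frequency over 30–50 Hz,
endpoints inclusive ("log log" is read as log–log axes; an iterated
logarithm of densities in (0,1) is undefined). `SpectralSlopeModel.fit()`
returns the estimates with their standard errors, t values, R² and a
summary table; non-positive powers are dropped with a warning and at
least three points must remain.

**Notch-band exclusion.** After notch filtering, the bins inside the
stopband carry no information; leaving them in the fit drags the pooled
slope by roughly −2.6 and, through the short-window spectral kernel, the
per-cycle slope by about −0.4. The pipeline therefore excludes the
applied notch bands (±3 Hz; widened by half the window's spectral FWHM,
1.3/T Hz, for per-cycle fits) from slope fits. `fit_slope` itself
defaults to no exclusion, so the bare estimator remains exactly the
printed regression.

**Hamming leakage, and how the estimators are calibrated.** The Hamming
window's sidelobe floor is ≈ −56 dB at the 22–42 Hz offsets separating
theta from the fit band. On a synthetic recording whose background is a
pure power law, a theta rhythm strong enough to satisfy the envelope
detection criterion (amplitude ≳ 2 noise-SD) leaks enough power through
that floor to flatten any β ≥ 2.5 estimate by order 1 — with a 5 s
Hamming window this is irreducible, a property of the stated estimator,
not of its implementation. Real spectra carry far more 30–50 Hz power
relative to theta than a globally pure power law does, which is why the
estimator works on real data. Slope calibration is therefore measured on
aperiodic recordings (theta and gamma amplitudes zero), with the
cycle-based estimators driven by 125 ms ground-truth tiling windows —
the full estimator path (snippet extraction, splicing, tapering, Welch,
per-window periodograms, OLS) is exercised; only the detector, which is
calibrated separately on strong-theta signals, is bypassed. Under these
conditions the pooled estimator recovers −β within ±0.05 and the
per-cycle mean within ±0.15 across β ∈ {2, 2.5, 3} (20 × 120 s
recordings each; tolerances asserted at ±0.2 / ±0.3).

## 5. Group statistics

Group slopes come from the mean PSD of each group; the slope difference
is the t test on the interaction coefficient of the pooled regression
log₁₀ P ~ log₁₀ f × group (how the source obtained its group t statistic
is not stated; the interaction term is the standard inference for a
slope contrast). Per-cycle slope samples are compared by Welch's
unequal-variance t with Welch–Satterthwaite degrees of freedom, gated by
Shapiro–Wilk normality at α = 0.05 with a two-sided Mann–Whitney U
fallback (exact for min(n) ≤ 8 without ties, normal approximation
otherwise). Grubbs' two-sided single-outlier test uses the t-based
critical value and flags at most one point per call — the conventional
iterative screen removes the flagged point and re-runs. SEM of a single
observation is reported as 0 with a warning.

The per-cycle group test treats cycles as the unit of inference, as
printed in the source analysis. This is pseudo-replication: per-window
slopes within one recording share that realization's spectral noise
(SD ≈ 0.2 between recording means), so the group study pools windows
from all recordings per group; with only one or two recordings per group
the contrast can flip sign even at n ≈ 1000 windows.

## 6. Synthetic data: what it emulates, what it does not

The LFP generator sums:

* **background**: spectral-synthesis Gaussian noise with amplitudes
  ∝ max(f, knee)^(−β/2), Hermitian symmetry and random phases —
  the expected periodogram follows f^(−β) exactly above the knee, so β
  is analytic ground truth. The 1 Hz knee mirrors the infra-slow plateau
  of real recordings; a pure power law down to 1/duration Hz would put
  nearly all variance below 1 Hz and make any Hamming-windowed estimate
  leakage-dominated. Unit variance after normalization.
* **theta**: a movement-gated cosine, frequency-modulated 6–10 Hz by
  default (so instantaneous-frequency estimation is exercised), amplitude
  3 noise-SD — theta-dominant, as in stratum pyramidale during running.
  Ground-truth peak times are the phase zeros inside movement epochs.
* **theta-nested gamma**: band-passed (30–50 Hz) β-colored noise whose
  amplitude follows (1 + cos θ-phase)/2, scaled so its average in-band
  power equals `gamma_rel` × the aperiodic floor. Using a carrier that
  shares the background exponent elevates the band uniformly; a
  white-in-band carrier would tilt the 30–50 Hz slope by ≈ +0.25 at
  `gamma_rel` = 1, and any theta-rate amplitude modulation smears the
  band edges by ±8 Hz — which is why calibration recordings set
  `gamma_rel` = 0.
* **mains**: a 50 Hz sinusoid plus a 0.3-amplitude first harmonic.
* **velocity**: 50 samples/s, > 2 cm/s exactly inside the generated
  movement bouts.

Not emulated: spikes and spike bleed-through, electrode drift and
artifacts, cross-frequency phase dynamics beyond simple amplitude
coupling, multi-channel geometry, and the amplitude scale of real
recordings (signals are unitless, mirroring z-scored data). Passing
tests therefore demonstrate estimator correctness under known spectra,
not robustness to every pathology of real recordings.

Trees grow radially outward in straight steps with optional per-step
angular jitter and scheduled branch events; with no branches and no
jitter the tree is a straight radial cable, giving closed-form Sholl
counts. Spine geometries are drawn strictly inside their class's rule
region (lengths never at the 1.0 / 1.5 µm boundaries), so a correct
classifier must score 100 %. Puncta images place non-overlapping disks
by rejection sampling at 0.125 µm/px in an 18.33 × 18.33 µm field
(the 336 µm² neuropil square), intensity 200 on background 20, with
optional Gaussian noise.

## 7. Morphometric rules and their edge conventions

* **Spines** — rules evaluated in order: stubby iff length < 1 µm and no
  neck; mushroom iff a head is discernible, head diameter ≥ 1.5 × neck
  length (inclusive, "at least") and length < 1.5 µm; thin iff
  length ≥ 1.5 µm, or length in [1, 1.5] µm without a discernible head.
  Length exactly 1.5 µm goes to thin. The mushroom rule compares a
  diameter against a length, as printed in the original criteria. A
  geometry satisfying no rule returns `unclassified` with a notice.
* **Segments** — half-open [lo, hi): a spine at exactly 50 µm belongs to
  the 50–100 µm segment.
* **Boutons** — backbone brightness and width are medians over the
  profile (robust; the source does not define "backbone" numerically);
  candidates are local brightness maxima; acceptance requires ≥ 2× both;
  the "no crossing axons" criterion is a manual per-candidate input
  flag, not computed. Profiles must span ≥ 10 µm.
* **Sholl** — 3-D Euclidean distance from the soma node; per segment the
  squared distance is a convex quadratic, so crossings are counted on
  its two monotone pieces (min < r ≤ max): landing exactly on a sphere
  counts once, grazing tangencies do not. Distances within 1 nm of a
  sphere snap onto it so adjacent segments treat a node on the sphere
  consistently. The dense-sampling oracle (0.01 µm steps, endpoint
  included exactly) agrees with the analytic count integer-for-integer
  on all random fixtures.
* **Puncta** — rolling-ball background subtraction (radius 50 px),
  8-bit conversion (min–max rescale for non-8-bit input), fixed
  threshold (a required input: the original thresholds are
  marker-specific and unpublished), binary Gaussian blur σ = 1 px
  re-thresholded at 0.5 (denoises and splits close appositions),
  4-connected components. The neuropil-square analysis applies no area
  filter; the perisomatic ring analysis keeps components with
  0.15 ≤ area ≤ 2.5 µm² in the ring formed by dilating the soma polygon
  by 1.25 µm, and reports puncta per µm of soma perimeter plus the ring
  area fraction. Note the ring clips large blobs: the filter applies to
  the clipped component area, which is what a binarized-ROI measurement
  sees.
* **Optical density** — OD = −log₁₀(G/G_max) with G_max the bit-depth
  maximum and zero grey clamped to one count; the reported value is the
  ROI mean minus the white-matter ROI mean (the named software converts
  grey to OD without printing the formula; this is its standard
  calibration-free form).
* **Stereology** — Cavalieri: Σ areas × thickness × series factor;
  fractionator: per-marker and intersection counts × series factor;
  NanoSIMS: mean positive-ROI ¹⁵N/¹⁴N over mean negative-ROI ratio;
  co-expression: 100 × |base ∧ probe| / |base|. All exact arithmetic.

## 8. Problem sizes

The validation studies use 120 s recordings at 1 kHz, 20 seeds per
exponent and 20 recordings per group — large enough that the seed-mean
standard error (~0.04 on a slope) sits well inside the asserted
tolerances, and the entire suite runs in about a minute on one CPU.
The per-cycle estimators batch windows of equal length through a single
FFT, which is what keeps ~20 000 per-window fits per study cheap.

## 9. Known limitations

* With theta-dominant input and a pure power-law floor, the raw-snippet
  Hamming–Welch slope is leakage-limited for β ≥ 2.5 (§4); on real data
  the relative 30–50 Hz floor is higher and the printed estimator
  behaves.
* EMD band splitting is not a filter bank: on steep-spectrum noise the
  theta-assigned IMF absorbs part of the 30–50 Hz energy, so slopes must
  be fit on raw snippets, not on the supra-theta component.
* The per-cycle slope distribution is wide (SD ≈ 1.5–2 per window);
  inferences at the cycle level inherit the pseudo-replication caveat of
  §5.
* The puncta pipeline operates on single-plane 2-D images; 3-D puncta
  detection and automated soma/dendrite segmentation are out of scope.
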