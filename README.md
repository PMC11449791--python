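# hippoquant

Quantification of hippocampal excitatory:inhibitory (E:I) balance from CA1
local field potentials, together with the interneuron morphometry that
accompanies such studies.

**Who it is for.** Systems-neuroscience labs that record LFP from behaving
rodents and read the 30–50 Hz aperiodic spectral slope as a proxy for the
E:I ratio of the circuit (a flatter, less negative slope indicates a shift
toward excitation), and that quantify the structure of the inhibitory
circuitry — dendritic spines, *en passant* boutons, Sholl profiles,
synaptic puncta, immunoreactivity, stereological counts and volumes,
NanoSIMS isotope ratios.

## The model at the core

During locomotion the CA1 LFP is dominated by the 5–12 Hz theta rhythm.
The pipeline:

1. **conditions** the raw trace (downsample to 1 kHz, zero-phase
   Butterworth band-stop at 50 Hz and harmonics, z-score);
2. **decomposes** it by empirical mode decomposition (EMD / Hilbert–Huang)
   and groups the intrinsic mode functions by mean instantaneous frequency
   into low (< 5 Hz), theta (5–12 Hz) and supra-theta (> 12 Hz) bands;
3. **detects individual theta cycles** during movement (velocity
   > 2 cm/s): a central theta peak flanked by consecutive valleys, all
   exceeding the Hilbert envelope of the low band, with valley separation
   in [71, 200] ms;
4. **estimates the PSD** of the cycles (Welch, Hamming 5 s window, 50 %
   overlap, 0.2 Hz resolution — pooled over concatenated cycles, or a
   zero-padded periodogram per cycle) and fits the power law

   log₁₀ PSD(f) = a + b · log₁₀ f + ε,  30 ≤ f ≤ 50 Hz,

   by ordinary least squares. The slope *b* is the E:I proxy;
5. **compares groups**: slopes from each group's mean PSD with the
   difference tested through a group × log-frequency interaction term, and
   per-cycle slope samples through Welch's unequal-variance *t* test
   (Shapiro–Wilk gate, Mann–Whitney *U* fallback; Grubbs outlier screen at
   α = 0.05).

Every input the pipeline consumes can be synthesized with embedded ground
truth (`hippoquant.synthetic`): 1/f^β noise with an analytically known
exponent, movement-gated frequency-modulated theta with theta-nested gamma
bursts and mains contamination, velocity traces, random SWC trees,
class-conditional spine geometries, and puncta images with known
centers and areas.

The morphometry side implements the field's decision rules exactly:
spine classes (stubby / mushroom / thin by protrusion length and
head-to-neck ratio), spine densities per 50 µm dendritic segment, *en
passant* bouton criteria (≥ 2× backbone brightness and width), Sholl
intersections by exact segment–sphere crossing counts, puncta
densitometry (rolling-ball background subtraction, fixed threshold, blur,
connected components), the perisomatic 1.25 µm ring analysis with the
0.15–2.5 µm² area filter, white-matter-normalized optical density,
Cavalieri volumes, fractionator counts, ¹⁵N/¹⁴N ratios, and marker
co-expression percentages.

## Worked example

```python
import hippoquant as hq

# 1. a 60 s synthetic recording: 1/f^2.5 background, movement-gated theta
rec, truth = hq.generate_lfp(hq.LfpSimParams(duration_s=60.0, seed=42))
res = hq.analyze_recording(rec)
print(len(res.cycles), "cycles detected of", truth.true_cycle_times.size, "generated")
# -> 441 cycles detected of 480 generated

# 2. the spectral-slope model on an aperiodic recording with known beta=2.5
rec2, _ = hq.generate_lfp(hq.LfpSimParams(duration_s=120.0, beta=2.5, seed=7,
                                          theta_amp=0.0, gamma_rel=0.0))
pre = hq.preprocess(rec2)
windows = hq.tile_cycles(pre.samples.size, pre.fs_hz)   # 125 ms reference windows
psd = hq.pooled_theta_psd(pre, windows)
fit = hq.SpectralSlopeModel(psd, band=(30, 50),
                            exclude_hz=hq.notch_exclusions(pre)).fit()
print(fit.summary())
# Spectral slope fit: log10(P) = a + b*log10(f)
#   band: 30.0-50.0 Hz (85 points)
#   slope b     = -2.5683  (SE 0.1126)
#   intercept a = -0.1060  (SE 0.1782)
#   R^2         = 0.8623
```

The fitted slope −2.57 ± 0.11 recovers the generator's true exponent
(−2.5) through the full estimator chain; the 85 fit points are the 0.2 Hz
grid over 30–50 Hz minus the 50 Hz notch stopband. A two-group contrast
mirroring a treatment effect:

```python
g = hq.group_difference_study(beta_A=2.91, beta_B=2.52, n_per_group=20, seed=1)
print(g["mean_psd"].summary())
# mean-PSD log-log interaction t: slope_A=-2.866 (n=20), slope_B=-2.572 (n=20),
#   diff=-0.294, t=7.620, df=166.0, p=1.85e-12
```

Group A (steeper slope, more inhibition-dominated) and group B (flatter,
shifted toward excitation) are separated at p ≈ 2 × 10⁻¹²; the per-cycle
slope samples in `g["per_cycle"]` carry the corresponding Welch *t*.

A command-line interface mirrors the library:

```bash
hippoquant simulate-lfp --seed 1 --duration 60 -o rec.h5
hippoquant analyze rec.h5 -o cycles.csv
hippoquant simulate-tree --seed 3 --branches 0 -o tree.swc
hippoquant sholl tree.swc --step 20
```

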