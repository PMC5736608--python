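# Methods

## Signal model and conventions

All phases are radians wrapped to (−π, π], with 0 at the oscillation peak
(cosine convention) and ±π at the trough. Epoch intervals are half-open
[t_start, t_end) in seconds from session start. Time series are float
arrays with an explicit sampling rate (2 kHz by default).

**Zero-phase bandpass.** Windowed-sinc FIR (Hamming), order three cycles of
the band's low edge by default, applied forward and backward so the net
group delay is zero and stopband attenuation doubles in dB. Both passes are
run as FFT convolutions; `numtaps` samples at each edge are flagged as
transient and excluded from every downstream statistic. The 0.5-Hz-wide
comodulogram bands instead size the filter from the bandwidth (transition
width = bandwidth/2, ≈ 6.6·rate/bandwidth taps), because the default order
rule cannot resolve sub-hertz bands.

**Instantaneous phase.** Angle of the analytic signal (Hilbert transform)
of the bandpassed trace. Constant input raises: its phase is undefined.

**Morlet power.** The wavelet at frequency f is a complex exponential under
a Gaussian envelope with σ_t = n_cycles/(2πf), n_cycles = 2, truncated at
±5σ_t and L1-normalized so a unit cosine at f yields power ≈ 1. Power is
the squared magnitude of the convolution; per-frequency cone-of-influence
edges (kernel half-width) are flagged. Two cycles is a deliberately short
wavelet: it has σ_f = f/2 spectral width, which matters for interpretation
(below).

## Phase–amplitude coupling

Theta phase is binned into 100 bins of π/50 rad with centers at
−180° + 3.6°·(k + ½). The mean gamma power per bin, taken raw (not
z-scored) and normalized by its sum, weights the bin-center phasors; the
resultant's magnitude is the MRL and its argument the preferred phase.
Amplitude-band power is the mean wavelet power across the 1-Hz-spaced rows
inside the band (a bandpass + squared-Hilbert-envelope alternative is
available via `power_method="hilbert"`). Epoch samples are pooled
(concatenated) before binning rather than averaged per epoch, matching the
short center-arm runs the analysis is designed for; one PAC estimate
requires ≥ 10 s of usable data (≈ 80 theta cycles), and per-epoch MRLs used
in paired tests skip that gate but inherit its noise.

**Closed form.** The generator modulates gamma *power* as
1 + m·cos(φ − φ₀) (carrier envelope ∝ √(1 + m·cosφ)), so the power-weighted
MRL is analytically m/2 at direction φ₀. Modulating power rather than
amplitude is what makes the closed form exact under power weighting; an
amplitude-domain raised cosine would give m/(1 + m²/2) instead.

**Significance.** A circular-time-shift surrogate (uniform shift in
[1 s, T − 1 s], 200 draws) provides the null; it preserves both marginals
and autocorrelations while destroying the phase–power alignment. This
requires aperiodic theta — for a strictly periodic oscillator a circular
shift only rotates the preferred phase — which is one reason the generator
wanders theta frequency (below).

**Comodulogram.** Phase centers 4–20 Hz in 0.5-Hz steps (contiguous
0.5-Hz-wide bands), amplitude rows 30–150 Hz in 1-Hz steps. With 2-cycle
wavelets the coupling ridge of a jittered ~50-Hz carrier peaks a few hertz
*below* the carrier (typically 44–46 Hz): the wavelet bandwidth grows with
frequency, so higher rows absorb proportionally more unmodulated background
(residual theta, the fast-gamma carrier), diluting their relative
modulation. This is a property of short wavelets, not of the generator.

## n:m phase–phase coupling

Entry (n, m) is the resultant length of the wrapped per-sample difference
n·φ_slow − m·φ_fast (no binning); default grid n ∈ 1..4, m ∈ 1..16. For
independent uniform phases the expected resultant of N samples is
√π/(2√N), the Rayleigh floor used in tests.

## Gamma peaks

Candidate peaks are strict local maxima of the gamma-bandpassed voltage
outside filter transients; they are retained greedily in descending
amplitude with a symmetric 100-ms exclusion zone (ties go to the earlier
peak), so surviving peaks are pairwise ≥ 100 ms apart — at most one peak
per theta cycle. No amplitude threshold is applied by default (an optional
envelope threshold exists). Peak-triggered averages use ±100-ms raw-LFP
windows (peaks without a full window are dropped and counted) with a
theta-filtered overlay of the same windows.

## Spike tools

Units must satisfy L-ratio ≤ 0.1 *and* isolation distance ≥ 10 (inclusive
bounds); missing metrics exclude the unit with reason "missing". Spike
phases are nearest-sample lookups in the phase series; locking uses the
unweighted MRL and Rayleigh's test (Z = nR², p by the standard series
approximation), requiring ≥ 10 spikes in support.

The cross-correlogram is CCG = C₁₂/(T·√(f₁f₂)) with C₁₂ the raw count of
spike pairs within ±1 ms (inclusive; each spike may join several pairs, no
jitter correction). The lag-resolved curve uses 0.5-ms bins over ±50 ms
with the identical per-bin normalization; the reported peak height is the
maximum over the bins covering [−0.5, 0.5] ms. Same-stereotrode pairs are
refused by default (detection shadowing biases near-zero lags). Note the
normalization removes only the first-order rate dependence: for independent
Poisson trains E[CCG] = 2τ·√(f₁f₂) (τ = 1 ms), so chance coincidence still
scales with the geometric mean rate — while a perfectly synchronous pair
stays at exactly 1 under any common rate change.

**Quartile analysis.** Sessions are cut into non-overlapping 2-s windows
(configurable), each contributing one PAC value; windows are ranked within
session into quartiles. Per-unit rates are z-scored across windows,
averaged per quartile, then averaged within and across animals.
Significance comes from an OLS regression of the *animal-level* quartile
means on the quartile index with animal indicators: regressing per-unit
means instead under-covers (z-scoring forces each unit's four quartile
means toward a zero sum; measured 89.7% CI coverage at nominal 95%),
whereas the animal-level regression restores ~94% null coverage and
matches the within-animal-then-across-animals averaging hierarchy.

## Session statistics

Per condition (e.g. sample-correct), epochs are selected from the trial
table, epochs shorter than 0.5 s dropped with a count, samples pooled for
one PAC estimate, and per-epoch MRLs retained for paired tests. Group
inference uses the paired t (identical vectors return t = 0, p = 1 rather
than NaN), the unpaired t, and a two-way ANOVA with Type II sums of squares
(exact for balanced designs, well-defined for the mildly unbalanced trial
counts behavior produces). Accuracy–coupling association is reported at
three levels: session-wise Pearson r, Pearson r of per-animal means, and
the p-value of the coupling coefficient in an OLS of accuracy on coupling
with animal indicators (the honest test when animals contribute several
sessions). No multiple-testing correction is applied; all tests are listed
so users may adjust. The Watson–Williams test uses the standard
K = 1 + 3/(8κ̂) correction and warns when κ̂ < 1.

`run_pipeline` chains filtering → coupling → gamma peaks → unit locking →
group statistics over one or more session directories and writes a JSON
report that is byte-identical across reruns on identical inputs (sorted
keys, no timestamps).

## Synthetic generator

The generator emulates the dual-site recording geometry the analyses
target; its defaults are the study conditions the tests run under.

| parameter | default | meaning |
|---|---|---|
| f_theta | 8 Hz | theta frequency (vHPC) |
| theta_freq_jitter | 0.05 | fractional per-second wander of theta frequency |
| theta_amp / mpfc_theta_amp | 1.0 / 0.15 a.u. | theta amplitude in vHPC / mPFC |
| slow/fast gamma bands | 30–70 / 80–120 Hz | carrier at band center, ±10% frequency jitter per theta cycle (linearly interpolated, phase-continuous) |
| gamma_amp | 0.5 a.u. | carrier base amplitude |
| mod_depth_slow/fast | 0.3 | power-modulation depth ∈ [0, 1] |
| preferred_phase_slow/fast | 0 / π/2 rad | theta phase of maximal gamma power |
| noise_exponent / noise_amp | 1.0 / 0.1 | 1/f^β background, RMS amplitude |
| spike_baseline_rate / spike_kappa | 5 Hz / 1 | von Mises intensity r₀·e^{κcos(φ−ψ)}/I₀(κ) (mean rate r₀) |
| frac_unlocked | 0.25 | fraction of units with κ = 0 |
| n_trials / duration_per_epoch | 20 / 1.5 s | paired sample+choice center-arm epochs |
| phase_effect | 0 | choice − sample slow-gamma depth difference, applied on correct trials only |
| p_correct | 0.8 | Bernoulli probability of a correct trial |
| sample_rate | 2000 Hz | acquisition rate |

Design notes: theta frequency wanders ±5% on a one-second scale so that
time-shift surrogates destroy coupling (a strictly periodic theta defeats
them); gamma carriers take a new frequency each theta cycle with linear
interpolation so the band has realistic width without phase
discontinuities; mPFC theta is weak (0.15 a.u.) as in prefrontal
recordings, which also keeps its leakage through the wide 2-cycle wavelets
small relative to gamma power; the `phase_effect` applies to the slow-gamma
depth only, mirroring the sample/choice dissociation the pipeline is meant
to detect; correct/incorrect labels are Bernoulli(0.8), typical
post-criterion performance. All draws derive from one `default_rng(seed)`,
so identical (config, seed) pairs are bit-identical.

What the generator does **not** emulate: biophysical LFP generation, volume
conduction, movement/behavioral state, artifacts and line noise, theta
waveform asymmetry, non-stationary firing rates. Passing tests therefore
demonstrate correctness of the estimators under a known generative model,
not robustness to every property of real recordings.

## Problem sizes and numerical choices

Closed-form PAC checks use 60-s noiseless pairs with both gamma bands
modulated at the same depth and phase (cross-band wavelet leakage then
carries the same raised cosine, keeping the m/2 identity; with only one
band modulated, leakage from the other band dilutes the estimate by a few
percent). The end-to-end behavioral recovery uses 10 sessions of 20 trials
at 1 kHz per experiment — the contrast is strong enough that detection is
essentially certain — and 16 replicate null experiments bound the false-
positive rate binomially. Type-I calibrations use 2000 simulations per
test; quartile calibration 300. Empty phase bins propagate as NaN and are
excluded from the weighted resultant; degenerate inputs (constant traces,
all-zero weights, < 4 distinct coupling values, empty trains) raise typed
errors rather than returning quiet NaNs.

## Known limitations

* The 2-cycle Morlet's bandwidth makes narrowband quantities (comodulogram
  ridge location, absolute MRL) systematically biased by a few percent /
  hertz; comparisons across conditions computed identically are unaffected.
* Per-epoch MRLs from ~1.5-s epochs are noisy and upward-biased (finite-
  sample resultant); they are used only in paired within-session contrasts.
* The animal-indicator OLS is a fixed-effects stand-in for a hierarchical
  model; with very few animals its p-values are approximate.
* The spike generator draws at most one spike per sample (Bernoulli
  approximation), accurate while r·dt ≪ 1.
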