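# Methods

This note documents the models, estimators, parameter choices and known
limitations of `voltdend`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## The measurement problem

Two-photon imaging of a subthreshold-optimized GEVI in Purkinje-cell
dendrites yields small movies (~208 × 24 µm at 0.8 µm/px) at 440 Hz. The
sensor dims on depolarization, so signals are analyzed as `−ΔF/F₀`
(positive = depolarization). Two event classes matter: complex spikes (CS) —
large (~31 % −ΔF/F₀), fast (10.5 ms FWHM), ~1.3 Hz — and optogenetically
evoked IPSPs — small (~8 %), slow (time-to-peak ~85 ms) brightenings. A
widefield stimulation LED forces the detector to be gated (blanked) for a
few milliseconds around every pulse. Stimulation hardware and the frame
clock are unsynchronized but co-recorded on a 20 kHz DAQ.

## Synthetic data generator

`voltdend.synth.simulate_movie` renders the per-pixel forward model

    F_p(t) = background + B · bleach(t) · w_p · (1 − v_cs(t) − drift(t) + g_p · u(t)) + ε_p(t)

with `w` the dendrite band (cubic path, hard width cut), `v_cs` the CS
depolarization, `u ≥ 0` the IPSP hyperpolarization magnitude, `g_p` a
per-4.8 µm-segment heterogeneity factor, and Gaussian noise of sd
`noise_scale · sqrt(mean brightness)` (shot-noise approximation). Frames
whose exposure overlaps an LED ± 1 ms gating interval are blanked to 0.
Determinism: one master `SeedSequence`, fixed named substreams; identical
seeds give bit-identical movies.

Kernels. The CS waveform is a difference of exponentials with 1 ms rise
and decay solved numerically for a 10.5 ms FWHM, peak-aligned to the
ground-truth spike time. The IPSP kernel is alpha-like, parameterized by
time-to-peak (85.4 ms) and decay (120 ms). Microzones: cells may share a
parent Poisson source whose events they inherit with Gaussian timing jitter
and independent failures; the spike-time difference of two such cells has
sd `jitter·√2`, which anchors the synchrony tests.

Noise budget. The defaults place the whole-dendrite background sd mostly
in *shared* subthreshold fluctuation (OU drift, sd 0.03 −ΔF/F₀ ≈ 2 mV at
the sensor's ~1.5 %/mV slope, cutoff 0.5 Hz) rather than in per-pixel shot
noise (brightness 30 photons/px/frame). This split is forced by internal
consistency: per-segment traces must correlate strongly enough for
correlation clustering to work at all, while the whole-cell detectability
stays near d′ ≈ 5–6. A pure shot-noise budget reaching the same d′ would
leave segment pairs at r ≈ 0.01 and make clustering impossible.
`calibrate_noise_for_dprime` solves the pixel-noise scale for a requested
d′ in closed form, using the *frame-sampled* expected CS peak (~80 % of the
continuous-time amplitude at 440 Hz) because that is the amplitude the d′
estimator sees.

Trial-to-trial IPSP variability defaults to cv 0.10 (multiplicative,
shared across segments), and segment heterogeneity to cv 0.13. Because
heterogeneity is a stable anatomical property, repeated sessions of the
same cell can pin the factors via `SceneConfig.segment_factors`.

What the generator does not emulate: optical PSF and scattering, motion
(movies are motion-free; registration is out of scope), opsin photocycle
dynamics, true Poisson statistics at very low photon counts, and any
non-stationarity of firing rates. Passing tests therefore demonstrate
correctness of the estimators under the stated statistical structure, not
robustness to real-data artifacts outside it.

## Trace processing and spike detection

`F₀` is a centered 2 s running mean (truncated at the edges; a running
percentile is available). Gated samples are repaired by linear
interpolation between valid neighbors before normalization and flagged as
missing. The subthreshold baseline is a zero-phase (forward–backward)
5th-order Butterworth low-pass, default 4 Hz; zero-phase filtering squares
the magnitude response, which the filter tests account for analytically.

Detection is two-pass: candidate spikes found on the one-frame-Gaussian-
smoothed residual are excised from the raw signal ([−10, +25] ms, linear
interpolation), the baseline and noise are re-estimated on the cleaned
signal, and the second-pass detections are final. Two estimator choices are
deliberate and load-bearing:

* σ is the robust (1.4826 × MAD) sd of the **unsmoothed**
  baseline-subtracted residual, while the 3 σ threshold is applied to the
  **smoothed** residual. Smoothing lowers the noise floor ~2× without
  materially attenuating a 10.5 ms event, so large events sit far above
  threshold while single-frame noise excursions produce essentially no
  false positives. Thresholding the smoothed residual at 3× its *own* sd
  would instead yield tens of false positives per minute for Gaussian-like
  noise.
* Candidate maxima closer than the 25 ms window collapse to the larger one
  *unless* separated by a valley below ¾ of the smaller peak. A bump riding
  a spike's monotone tail shows no such valley and is suppressed; two
  overlapping spike waveforms ≥ ~2 frames apart do and are both kept.

Per spike, a Gaussian is fitted in a 15 ms window (offset bounded to ±½
frame) to obtain the sub-frame alignment used by spike-triggered averages.
`d′` draws one background sample per spike uniformly (seeded) from
[−250, −200] ms before it.

## Segmentation and clustering

Masks are refined as `N(G(X))³` (Gaussian σ default 1 px). The backbone
cubic is fitted in the weighted principal-axis frame (so vertical dendrites
work), and the path is trimmed to the central 99 % of the weight mass along
its axis so faint blur tails do not stretch it. Segments are 4.8 µm of arc;
a trailing remainder shorter than half a segment merges into the last one.
Pixels join the segment of their nearest path point.

Clustering uses Pearson correlation of the *spike-band* signal — one-frame
smoothed, baseline-removed — so the grouping keys on shared complex spikes
rather than on photobleaching or drift, which are correlated across the
whole field of view. Average-linkage agglomeration on `1 − r` is cut at
`r* = 0.5` (configurable); zero-variance segments are excluded with a
warning.

## Triggered averages and IPSP features

Because triggers land at random phases within a frame (trigger and frame
clocks are co-recorded at 20 kHz but not synchronized), pooling every
trial's samples at their true latency and re-binning at e.g. 2 kHz
super-resolves the average response; empty bins are interpolated and
flagged. Spike-triggered averages align trials by the per-spike Gaussian
offsets.

IPSP amplitude is the pre-stimulus reference minus the minimum of the
low-pass baseline in a 20–200 ms post-stimulus window. The reference is
the mean over [−200, −50] ms before the trigger rather than the value at
the trigger: the zero-phase filter spreads the response symmetrically in
time, so the trigger-time value is already contaminated by the response
itself (a ~30 % amplitude underestimate in simulation). The residual
systematic bias of the measured amplitude — background dilution plus filter
attenuation — is ≤ ~8 % and is part of what the acceptance benchmark
reports.

Per-segment response maps read every segment and every trial at one fixed
trough latency estimated from the trial-averaged, segment-averaged
response. This matters: a per-trial minimum search selects on noise, which
adds a common offset and flattens the across-segment contrast, biasing the
heterogeneity CV low and breaking the variance decomposition
`σ²_obs = σ²_true + σ²_noise/n_trials` that the CV benchmark verifies. CV
is the across-segment sample sd (ddof 1) over |mean|; the spike-amplitude
map reads all segments at the spike times detected on the whole-cell trace
(one common event set). The spike-probability window defaults to 150 ms
post-stimulus (configurable; no canonical value exists).

## Synchrony

Cross-correlograms use 4 ms bins over ±200 ms. The significance predictor
is a partially hollow Gaussian convolution (half-width 10 bins, center
weight 0 by default, edges renormalized); per-bin one-sided Poisson tail
probabilities are Bonferroni-corrected across bins at α = 0.01. Synchrony
width — the run of consecutive significant bins containing the peak — is
only defined for peaks above 10 counts; a Gaussian is fitted to
counts-minus-predictor within ±50 ms. Widths and fitted sd are reported on
binned data, so a 1 ms jitter (difference sd 1.4 ms) reads out near the bin
quantization floor; recovery accuracy is quoted at 2 ms jitter, where
binning inflates the fitted sd by only a few percent.

## Plasticity statistics

Cells are matched across sessions per FOV by a composite score — weighted
Jaccard mask overlap (0.4), correlation-matrix similarity (0.3),
spike-template correlation (0.2), firing-rate similarity (0.1) — maximized
by optimal one-to-one assignment (greedy above 20 cells), threshold 0.6;
unmatched cells are excluded, mirroring experimental practice. The paired
pre/post test is the two-sided Wilcoxon signed-rank on per-cell mean
amplitudes (exact for n ≤ 25 without ties). Group contrasts use a linear
mixed model (statsmodels MixedLM) with random intercepts for animal and for
FOV nested in animal; the Wald statistic on the group coefficient is
referred to a t distribution with between-FOV degrees of freedom
(`n_FOV − 2`). In a 600-run null calibration at the experiment's design the
asymptotic z-test was anticonservative (type-I 0.065 at α = 0.05) and
animal-level df (4) strongly conservative (0.017); the FOV-level df is
calibrated (0.052). A singular fit falls back to OLS with cluster-robust
(by animal) errors, flagged.

Neighbor correlations pool all ordered within-FOV cell pairs
(symmetrized); the null shuffles cell identities across FOVs within each
mouse (500 shuffles, seeded), preserving per-mouse counts and the pairing
topology, and the observed r's mid-percentile is reported (uniform under
exchangeability — verified by KS test).

## Problem sizes used in validation

Chosen so the full validation runs comfortably on one core:

* detection: 20 movies, 1 cell, 60 s, 16 × 64 px, noise calibrated to d′ = 5;
* clustering: 20 movies, 2 cells, 60 s, 20 × 64 px at nominal noise;
* IPSP gradedness: 20 movies, 122 s (60 stimuli at 0.5 Hz → 20 per LED level);
* CV recovery: 3 × 20 movies, 44 s (22 trials), heterogeneity cv ∈ {0, 0.1, 0.2};
* plasticity: 10 experiments of 32 + 32 cells (2 cells/FOV, 4 + 2 mice),
  pre/post sessions of 42 s (20 stimuli) per FOV, plus a 200-run
  feature-level null calibration of the group test;
* CCG: 100 null runs (600 s trains) and 4 × 30 jitter runs.

The plasticity sessions use 20 stimuli instead of the experimental 60 —
per-cell log-ratio noise is √3 larger than at full trial count, which the
32-cell groups absorb.

## Known limitations

* Amplitudes are as-measured: the running-window F₀ and the baseline filter
  attenuate event amplitudes by several percent (systematically, equally
  pre/post, so ratios are nearly unbiased); no deconvolution is attempted.
* The latency-to-10 % feature is read on the filtered baseline, which
  spreads onset backward; it is reported for relative comparisons, not as
  an absolute synaptic delay.
* Segment maps from fitted paths mix adjacent heterogeneity blocks near
  segment boundaries when the fitted arc origin differs from the generator
  grid; the CV benchmark therefore validates the measurement chain on the
  generator's own segment geometry.
* The mixed model assumes Gaussian random effects; with very few animals
  its variance components are weakly identified (hence the df correction
  and the robust fallback).
* Spike detection assumes the 440 Hz frame rate resolves the CS waveform;
  somatic simple spikes are out of reach at this rate by design.
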