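# Methods

This note documents the models, defaults and numerical choices behind
`eapclust`, and what the synthetic-data tests do and do not establish
about real recordings.

## Waveform model and feature extraction

The analysis operates on per-unit mean EAP matrices (channels × time at
30 kHz, i.e. 0.0333 ms per sample). The probe is modelled as one
two-column side of a high-density shank with 20 µm vertical pitch;
staggered lateral offsets are ignored and inter-site distance is taken as
the vertical spacing. Depths are signed, positive toward the pia, so
outward spike propagation gives a negative latency-vs-depth slope below
the soma and a positive one above it. This sign convention is what makes
the symmetry index SI = |1/V_below + 1/V_above|/√2 (distance to the line
y = −x) read zero for equal-speed bidirectional propagation; the raw
ratio (1/V_below)/(1/V_above) is also reported as `propagation_ratio`
without interpretation.

Extraction details that matter:

* The peak channel is the channel with the largest extremum magnitude;
  TPW runs from the global minimum of that channel to the following
  maximum, REP from that peak to the first half-peak crossing (linear
  interpolation between samples). Features are reported at the raw
  0.0333 ms quantisation; optional sub-sample refinement is deliberately
  off so results are exactly reproducible.
* Velocity fits use channels within ±200 µm of the peak channel (10 rows
  each way), include the peak channel as the zero-latency anchor in both
  side fits, and exclude channels below 12 % of the maximum amplitude —
  trough times on near-noise channels are meaningless. A side with fewer
  than 3 usable channels yields an undefined slope and a flagged unit.
* Spread is the contiguous supra-threshold (12 %) run of channels
  containing the peak channel, measured as an extent in µm.
* Per-channel trough search is restricted to 1 ms before / 2 ms after the
  peak-channel trough, wide enough for the broadest units.

## Synthetic EAP generator

No analytic waveform shape is canonical for EAPs, so the generator uses a
two-lobe template chosen to be exactly invertible by the extractor: a
negative Gaussian trough (σ = TPW/5, negligible at the peak) plus a
positive lobe (40 % of trough amplitude) that rises as sin² to a maximum
exactly TPW after the trough and decays exponentially with time constant
REP/ln 2, placing the half-peak crossing exactly REP after the peak.
Per-channel amplitude decays as exp(−|d|/decay_length) (default 100 µm)
and trough latency shifts linearly with signed depth at the generated
1/V slopes. Round-trip tests at zero noise therefore recover TPW/REP to
one sample and, for sample-commensurate slopes, the velocities to 1e−9
relative error.

The default population emulates the study conditions: 1,204 units,
23.3 %/76.7 % narrow/wide mixture; narrow units at TPW 0.25 ± 0.04 ms,
REP 0.20 ± 0.04 ms, wide at 0.65 ± 0.08 / 0.55 ± 0.08 ms; three
propagation sub-components per class (weights from the reported
sub-cluster sizes 130/82/69 and 479/235/209) with (1/V_below, 1/V_above)
means of (−0.001, 0.001), (−0.005, 0.001), (−0.001, 0.005) ms/µm for the
narrow class and (−0.004, 0.001), (−0.004, 0.004), (−0.001, 0.001) for
the wide class, SD 0.0005 ms/µm; amplitude 150 ± 40 µV with 5 µV white
noise. Where the source conditions state no value (the sub-component
means and SDs, decay length, noise level) these were chosen once as
physiologically plausible magnitudes — propagation speeds of order
0.2–1 m/s and amplitudes typical of well-isolated units — and are not
tuned. Firing rates are log-normal around the class medians (4.85 Hz
narrow, 2.05 Hz wide, σ = 0.8 in log space).

What the generator does **not** emulate: spike-sorting artefacts,
waveform drift, electrode-to-cell geometry beyond a vertical decay,
bursting/refractory ISI structure, correlated noise across channels, and
real LFP spectra (the phase-locking generator uses a single sinusoid plus
white noise). Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical structure, not robustness to
every failure mode of real data.

## Cluster-number selection

WCSS uses best-of-restarts K-means with random centroid initialisation
(matching the stated protocol of many random initial values; the library
default is 1,000 restarts, and the pipeline/test configurations use
50–100, which is ample for the 2-D, well-separated problems run here).
The density function f(K) follows the recursion above and requires
feature dimension > 1. Selection defaults to the density criterion;
the elbow is operationalised as maximum discrete curvature (second
difference) of the normalised WCSS curve, a crude surrogate for a visual
elbow that can under-estimate K when more than two well-separated
components are present, which is why it is not the default. The joint
mode returns an explicit disagreement rather than guessing. The K = 1
fallback threshold (min f(K) ≥ 0.85) follows the cited density-function
method. Features are z-scored before clustering (configurable off):
TPW/REP and the velocity slopes live on very different scales.

Sub-cluster names are canonical so labels are reproducible across runs:
FS sub-clusters by ascending mean symmetry index (FS1 most symmetric),
RS sub-clusters by ascending mean |1/V_below|.

## Ensemble classification

Each of the 100 members sees an independent stratified 75/25 split;
stratification guarantees every member observes all classes (pure random
splits can starve a small class). Oversampling to 1:1 happens strictly
inside each training split — global upsampling would leak duplicates into
validation. Standardisation statistics come from the training split only.
Accuracy is reported both pooled over held-out predictions and as the
per-member mean ± SE. Majority-vote ties break toward the
lexicographically smallest label and are flagged. `cross_map` logs an
extrapolation warning when most test samples fall outside the 1–99
percentile box of the training features.

## Spike-train, visual and optotagging metrics

CV uses the sample standard deviation over ISIs divided by the mean; LV
is the adjacent-ISI statistic with denominator n − 1 (n = number of
ISIs). Both need at least two ISIs, otherwise NaN + flag. The visual
metrics are computed on the preferred (max mean rate) condition's 1 ms
PSTH: f1/f0 is twice the magnitude of the Fourier component at the
stimulus temporal frequency over the mean rate; the modulation index is
the z-scored power at the stimulus frequency relative to the PSTH power
spectrum (DC excluded), with MI > 3 read as strong modulation — this
formula is a reconstruction from the cited definition, labelled as such;
lifetime sparseness uses the standard (1 − (Σr/n)²/(Σr²/n))/(1 − 1/n).
Optotagging rates are computed per trial then averaged; the baseline
window is the 6 ms immediately before pulse onset, length-matched to the
2–8 ms response window, and the criterion is response > 25 Hz and > 2.5×
baseline. The synthetic light response starts at 2 ms plus up to 1 ms of
uniform per-trial latency jitter, keeping evoked spikes inside the
response window.

## Phase locking

LFP is bandpass filtered with a zero-phase (forward–backward) FIR filter
whose length covers at least three cycles of the band's lower edge, then
Hilbert-transformed; the analytic-signal angle is mapped so 0° is the
oscillation peak and 180° the trough. Each spike takes the phase of its
nearest sample; the first 10,000 spikes chronologically are used. Units
need ≥ 100 spikes. The Rayleigh test uses the standard finite-n
approximation; locking requires p < 0.001. The von Mises fit is maximum
likelihood (scale fixed at 1). The concentration parameter κ is
unbounded; the mean resultant length, which lies in [0, 1], is reported
alongside it, and no truncation is applied. Band presets: default edges
theta 3–8, alpha 8–12.5, beta 12.5–30, low gamma 30–50, high gamma
50–90 Hz, with an alternative "methods" preset (alpha 8–12, beta 12–30)
because both conventions are in circulation. Group comparisons use a
two-sample proportion z-test on locked fractions and Mann–Whitney on κ of
locked units, Holm–Bonferroni corrected across bands.

The κ = 0 calibration (rejection rate 0.001 ± 3 binomial SE over 2,000
replicates) and the κ recovery grid (within 10 % at 5,000 spikes) run
through the full generate → filter → Hilbert → test path; phase
quantisation at the LFP rate (1250 Hz default) attenuates κ by ~1–2 %,
well inside the tolerance.

## Morphology

SWC trees are validated for a single root, no orphans, no cycles and full
connectivity; branch points are nodes with ≥ 2 children (the soma
qualifies if it has several stems, contributing w = 0). The bifurcation
distance reduces to the vertical offset y_N − y_S because the reference
direction is the unit y-axis; the explicit projection formula is kept as
an independent cross-check. Exclusion of |w| > 200 µm is applied before
per-neuron normalisation. No re-alignment of the morphology to the pia is
performed; the file's y-axis is trusted.

## Problem sizes and determinism

Test and pipeline runs use 250–1,204 units, 30–120 s of spiking per unit,
50–100 K-means restarts and 2,000 calibration replicates; these sizes
give stable statistics for every assertion while keeping the full suite
around half a minute. Every stochastic component takes an explicit seed
(NumPy `default_rng`), generators are bit-reproducible given (params,
seed), and the pipeline writes byte-identical tables on reruns with the
same config; the run manifest records the config hash, seed and package
version.

## Known limitations

* The elbow criterion is a heuristic; on > 2 strongly separated
  components it may select 2 and force a joint-mode disagreement.
* The MI and sparseness formulas are reconstructions of definitions the
  source literature specifies only by citation.
* Velocity features inherit the 0.0333 ms latency quantisation; slopes
  below ~1e−4 ms/µm are dominated by quantisation noise at 20 µm pitch.
* The two-way mapping is only as good as the feature overlap between
  domains; the extrapolation warning is a coarse support check, not a
  calibration guarantee.
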