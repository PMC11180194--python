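# Methods

## Signals and model

Each recording site contributes two streams. The LFP stream is the 3–200 Hz
band of the wide-band signal; the SPK stream is the 300–6000 Hz band,
full-wave rectified and mean-subtracted, so that its sub-100 Hz content
reflects the envelope of multi-unit discharge. Both filters are 4-pole
zero-phase (forward–backward) Butterworth band-passes, implemented as
second-order sections for numerical stability. Site spectra are Welch
estimates with 2-s Hamming windows and 50% overlap, giving a 0.5 Hz grid;
sites shorter than 1.5 windows (< 3 s) are excluded rather than estimated.
Bins within 2 Hz of 50 Hz and its harmonics are replaced by the mean of the
nearest unaffected bin on each side (single-sided at the grid edge); the
repair is idempotent because repaired bins depend only on bins outside the
notch bands.

Spectra are modeled in log10 power over 3–70 Hz as an aperiodic power law
plus Gaussian peaks:

log10 P(f) = b − α·log10 f + Σ_k h_k·exp(−(f − c_k)²/(2σ_k²)).

The fit is the standard iterative procedure: (1) a robust initial aperiodic
fit (ordinary least-squares fit, then a refit restricted to the points
whose flattened residual is at or below its 2.5th percentile, which are the
points least affected by peaks); (2) peak extraction tallest-first from the
flattened spectrum, stopping at 6 peaks or when the tallest point falls
below 2 SD of the flattened spectrum or below 0.05 log-units; (3) joint
bounded nonlinear least-squares refinement of all Gaussians; (4) a final
aperiodic fit on the peak-removed spectrum. R² and the mean absolute error
(MAE) are computed in log10 power; a zero-variance spectrum yields an
undefined (NaN) R², never 1. All initial values derive deterministically
from the data, so fits are reproducible.

One extension beyond the standard procedure is a frequency-proportional
peak-width bound: the effective lower bandwidth bound at center `c` is
max(0.8, 0.02·c) Hz, which prevents implausibly narrow peaks at high
frequencies. The proportional upper bound is disabled (second element 0).
This proportional-bound semantics is an interpretation and is isolated in
`FitSettings.bandwidth_bounds` so it can be swapped. Reported peak
bandwidth is 2σ. MAE is computed in log power, consistent with the fitting
space.

Validation of the fitter relies on independent oracles rather than a
reference library: an exact power-law input is recovered to 1e−3; the
averaged periodogram of 1000 random-walk (Brown) signals fits with
α = 2.0 ± 0.1 and white noise with α = 0.0 ± 0.05; the exponent is exactly
invariant to rescaling the input power; and fits are fixed points —
refitting the spectrum implied by a fit reproduces that fit.

## Whitening

Frequency-domain whitening multiplies each PSD bin by f^α with the site's
own fitted exponent; it is linear and exactly invertible. Time-domain
whitening multiplies the signal by a symmetric n-point Hann window,
scales the FFT magnitudes on 3–70 Hz by f^α (α fitted on the magnitude
spectrum itself), zeroes magnitudes outside 3–70 Hz so all sites are
treated identically, preserves phases, inverse-transforms, and re-estimates
the PSD by Welch. The Hann window's amplitude distortion is not compensated
before the Welch re-estimate; since every site passes through the same
window, cross-site comparisons are unaffected. DC is never scaled (0^α
guard). Both routes locate the same beta center frequency within one bin on
synthetic cohorts.

## Beta features

The beta center frequency (βCF) is the frequency of the highest local
maximum (strictly greater than both neighbors) between 13 and 33 Hz of a
whitened, normalized spectrum; the absence of a local maximum is a valid
no-peak outcome, excluded from paired analyses. Trajectory-level βCFs are
detected on the average whitened spectrum of the motor-domain sites inside
the safe boundaries, which stabilizes the estimate relative to single
sites. Bandwidths are measured at half (and quarter and three-quarter) of
the peak's topographic prominence, evaluated within the full 3–70 Hz
spectrum so shoulders are handled; flank crossings are located by linear
interpolation between the bracketing bins, and a flank that never crosses
within the grid censors the record with a flag. Downshift summaries count
the fractions of pairs with SPK βCF below / above / within 0.5 Hz (one
bin) of the LFP βCF, with a two-tailed Wilcoxon signed-rank test.

## Trajectories

A trajectory is included iff pre-STN, motor and non-motor subregions are
all present and each is strictly longer than 1 mm. Subregion borders are
taken midway between adjacent sites with different labels (sites are
points, not intervals); the exit border extends half a median STN step
beyond the last site. Safe boundaries exclude sites within 0.5 mm of the
motor and non-motor borders on both sides and the final 0.5 mm of pre-STN.
Subregion spectra are unweighted means over retained (non-outlier,
duration-qualified, non-boundary) sites. RMS values are normalized per
trajectory by the mean of the first ten sites; when an outlier falls among
the first ten, the baseline is computed over its non-outlier members — an
interpretation, since the ordering of outlier removal and baseline
computation is otherwise open. Outlier fences (3 × interquartile ranges
beyond the quartiles, linear-interpolation quartiles) are applied per
trajectory per stream.

## Synthetic data

The signal-level simulators are constructed as follows: Brown
noise is a cumulative sum of unit Gaussian increments (exactly α = 2,
validated by exponent recovery), high-pass filtered at 0.1 Hz with a
causal 2nd-order Butterworth (mimicking the acquisition chain), with the
first and last quarters discarded (8192 → 4096 samples at 4096 Hz). The
beta sine (20 Hz) is generated at full pre-trim length and trimmed with
the noise so phases stay aligned; its amplitude is 0.5·SD of the noise
(1.2·SD for the spiking membrane). Spikes: the threshold is the 60th
percentile of the high-amplitude beta sine; within each beta cycle the
supra-threshold samples of the membrane form that peak's spiking region,
one Poisson draw (mean 6) decides the spike count, and spike times are
uniform without replacement on the region's sample grid. Drawing per beta
cycle rather than per contiguous supra-threshold run is an interpretation;
it keeps the realized mean at 6 per region (within 1% empirically), whereas
run-level draws are distorted by noise-split slivers. Spikes are scaled by
3 × the beta maximum, the sum is band-passed 300–2000 Hz (6-pole
Butterworth) and rectified.

A known consequence of this construction, documented because it differs
from the intuition that spikes are "invisible" below 300 Hz: the spike
impulses contribute a flat broadband floor (≈ A²·rate/fs) that crosses the
1/f² membrane spectrum inside 3–70 Hz, so the fitted exponent of the
membrane+spikes signal is mildly flattened (≈ 1.6 vs 2.0 on averaged
PSDs). The tests assert this direction and bound rather than exact
invariance.

Test spectra for the goodness-of-fit surface are log-log-linear with
offset set equal to the exponent (mirroring the empirical offset–exponent
correlation), over exponents −0.25…2.25 (step 0.25) and noise calibrated
by bisection (25 iterations, 5% relative acceptance) to MAE targets
0.005…0.145 (8 even levels; the level count is a choice, the endpoints are
given), 20 repeats per cell, optionally with the three standard Gaussian
peaks (18 ± 5 Hz at 1.5, 25 ± 8 Hz at 3, 35 ± 5 Hz at 2 log-units). Cell
R² is averaged on the atanh scale and back-transformed.

The cohort generator draws, per trajectory, an LFP exponent ~ N(2.20,
0.40), a SPK exponent ~ N(0.11, 0.22), an LFP βCF ~ N(26, 2.5) Hz clipped
to the high-beta range, and a SPK βCF equal to the LFP βCF minus a
positive downshift ~ N(8, 1.5) Hz, clipped to low beta; βCFs snap to the
0.5 Hz analysis grid. Exponents are constant along a trajectory — a
simplification (real pre-STN LFP exponents run slightly higher than
intra-STN ones). Sites are 4 s at 4096 Hz: ten pre-STN sites at 400 µm
steps, then 100 µm steps through a 2.5 mm motor and 1.5 mm non-motor
subregion (desk-scale defaults; 30 patients × 1 trajectory). LFP carries
its beta sine in all subregions (half amplitude outside motor, mimicking
volume conduction); SPK beta exists only in the motor domain; SPK gains a
2× amplitude step inside the STN, and every site's amplitude is jittered
lognormally (σ = 0.25) so RMS dispersion resembles real trajectories.
Clinical tables draw demographics from plausible marginals and generate
each response as the z-scored demographic family times known coefficients
(0.5, −0.3, 0.4, 0.2) plus Gaussian noise (SD 0.5); the ordinal DBS
evaluation is additionally rounded to −2…+2.

What the generator does not emulate: volume-conduction geometry, electrode
impedance, non-stationarity within a site, tremor-phenotype signal
differences, correlated clinical–neuronal structure (responses link to
demographics, not to the neural draws), and the 44 kHz hardware chain.
Passing recovery tests therefore demonstrates the pipeline's correctness
under the assumed statistical structure, not clinical validity on real
recordings.

## Statistics

GLMs are Gaussian-identity linear models on z-scored predictors and
responses. Family orders: zeroth = the four members additively; first =
the six pairwise products only; higher = the four triple products plus the
quadruple product, in one model (treating the "three or four member"
description as a single five-term model; splitting into two models is
possible behind the same design-matrix helper). AIC is n·ln(RSS/n) + 2k
with k counting slopes, intercept and error variance — constants are
internally consistent, which is all model comparison needs. The model-level
p-value is the F-test against the intercept-only model, also for the
interaction-only orders. The two-way ANOVA of aperiodic parameters uses
Type II sums of squares (main effects unconfounded by interaction ordering
on unbalanced data) with a Bonferroni-corrected pairwise rank-sum table
over the six stream × subregion cells. Pointwise spectrum comparisons use
the two-tailed rank-sum per bin with threshold 0.05/3 for the three
subregion contrasts. Permutation nulls for Spearman correlations shuffle
one member 100 times.

## Problem sizes and numerical choices

Averaged-PSD simulations use 1000 realizations (seconds of CPU); the
recovery suite runs the default 30-patient cohort; null calibrations use
500 replicates (300 for permutation coverage). The 0.5 Hz Welch grid,
3–70 Hz fit range, 13–33 Hz beta band, one-bin (0.5 Hz) equality tolerance
and 0.5 mm safe margins are fixed throughout. Welch segments are not
detrended (a constant-detrend option exists in scipy but is off by
default here). Degenerate inputs are handled explicitly: zero-variance
spectra give NaN R²; zero baseline SD bins in the distance z-score are set
to 0 and flagged; empty spike trains are flagged, not errors; optimizer
failures mark the fit non-converged and keep the best available
parameters.

## Known limitations

The fitter was not compared against an external reference implementation;
its validation is oracle-based (see above). Knee-mode aperiodic fits,
multitaper estimation, burst-timing analyses and ordinal models for the
DBS evaluation are out of scope. The subregion labels are an input — no
border detection is performed. The cohort generator's clinical layer uses
the demographic family as ground truth; wiring the neural draws into the
responses would allow end-to-end clinical recovery tests and is a natural
extension.
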