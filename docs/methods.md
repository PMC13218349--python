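# Methods notes

This note documents the models and numerical conventions behind
`betabold`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish.

## Synthetic session generator (`betabold.synth`)

The generator emulates a unimanual isometric handgrip paradigm: each of
`n_trials` trials is an inter-trial fixation of 3–5 s (uniform jitter)
followed by adapt (2 s), low (3 s), ramp (3 s) and high (3 s) phases;
sources are sampled at 250 Hz. Resting runs are emulated as a single
segment later split into contiguous 3-s pseudo-phases
(`split_rest`).

**Background.** Each parcel carries 1/f noise with one-sided PSD
`S(f) = 10^offset · f^−exponent`, synthesized by spectrally shaping
white Gaussian noise in the frequency domain (direct control of offset
and exponent; an AR process would only approximate a power law).
Defaults: offset −0.5, exponent 1.5 — a mid-range EEG-like slope.

**Bursts.** Burst onsets follow a homogeneous Poisson process per
phase; each event is a Hann-windowed 20 Hz carrier packet whose
envelope peak defines its amplitude. Default rates are
IT 0.6 / adapt 0.45 / low, ramp, high 0.25 / rest 0.55 events/s,
following the reported qualitative ordering (inter-trial and rest above
execution phases, adapt intermediate). Durations are truncated normal
(0.35 ± 0.08 s, support > 0.15 s so that every planted event survives
the detector's 100 ms filter); amplitudes are truncated normal
2.0 ± 0.4. With the default background this puts burst packets far
above the band's mean wavelet amplitude (≈ 0.16): the generator
deliberately produces the unambiguous, high-amplitude transients that
the burst literature describes, which is the regime in which a
2-SD/100-ms detector is expected to operate cleanly. None of these
values is a claim about real data; they are free parameters of the
exercise. Overlapping packets in one parcel are merged in the
ground-truth raster and event list, so the number of ground-truth
events always equals the number of raster runs. A designated "motor"
parcel can spawn synchronous bursts in coupled parcels with given
probabilities, which produces graded co-occurrence structure.

**BOLD.** BOLD is the discrete convolution of the ground-truth raster
with a known HRF, sampled every TR = 2.12 s, plus white Gaussian
noise. The default generating HRF lies inside the spherical-Laguerre
span (L = 2, α = 0.75, μ = 3.5), so that estimation error is
attributable to the estimator rather than to basis mismatch; a
double-gamma truth can be substituted to study mismatch.

**Geometry.** Parcel centroids are uniform on the unit sphere; the
synthetic receptor map is Gaussian-kernel-smoothed white noise with a
configurable angular correlation scale (scale → 0 gives spatially
independent values). The map stands in for a real PET-derived receptor
density map, which is out of scope here.

**What the generator does not emulate:** volume conduction/source
leakage, non-Poisson burst timing (refractoriness, trial-locked
dynamics), amplitude–duration correlations, non-stationary 1/f
parameters within a phase, physiological BOLD noise spectra (the noise
is white), and head-motion artifacts. Passing tests therefore
establish internal correctness and recoverability under the stated
model, not performance on real recordings.

## Aperiodic parameterization (`betabold.spectral`)

Sliding spectra are one-sided PSDs from non-overlapping 1-s Hann
windows (trailing partial windows dropped; frequency resolution 1 Hz).
The aperiodic model is the two-parameter power law
`log10 P = offset − exponent·log10 f` over 3–45 Hz (inside the 1–50 Hz
band-passed regime, avoiding filter edges); no knee term. Peaks are
handled by an iterative robust line fit: bins whose residual exceeds
2.5 SD above the current line are flagged as oscillatory peaks and
excluded from the refit (≤ 3 passes). `r2` is the squared correlation
between model and observed log-power over the retained bins — the
aperiodic analogue of a full-model fit quality, since narrowband peaks
are deliberately left unmodelled.

**Averaging order.** Phase-level parameters are obtained by fitting the
across-window *mean* power spectrum (default), not by averaging
per-window fits. The log of a single-window periodogram is biased
(E[ln χ²₂/2] = −0.577 nats ≈ −0.25 log10 units), so averaging
per-window log-domain fits would bias the offset and hence the
baseline; averaging the linear spectra first is unbiased and was
chosen as the default, with per-window fitting available
(`fit_phase(..., mode="per-window")`).

**Power → amplitude conversion.** The burst detector operates on
wavelet amplitude, so the band baseline must be expressed in that
convention. For Gaussian background with PSD `S`, the wavelet
coefficient at frequency f is circularly Gaussian with
`E|W|² = ½∫S(ν)|H_f(ν)|²dν` (`H_f` the kernel's frequency response at
unit sinusoid gain), giving a Rayleigh mean `E|W| = √(π/4 · E|W|²)`.
The default baseline is the 13–30 Hz average of this expected
amplitude under the fitted aperiodic model; on synthetic background it
matches the empirical mean band amplitude to within a few percent. A
plain `sqrt(power)` mode is available.

## Burst detection (`betabold.bursts`)

The Morlet convention is a mother wavelet of central frequency 1 Hz
and temporal FWHM 3 s, time-scaled to each analysis frequency
(13–30 Hz in 1 Hz steps), normalized to unit sinusoid gain; this is
the Brainstorm-style reading of "1 Hz central frequency and 3 s time
resolution" and is cross-checked in the tests against MNE's Morlet
implementation at the matched cycle count. Detection runs on the
band-averaged 1-D amplitude series: baseline subtraction per phase,
clipping at zero, threshold = 2·SD of the subtracted amplitude over
each single trial, binarization, concatenation, run-length filtering
(> 100 ms strictly).

Per-trial (rather than per-phase-segment) SD pooling is the default
for two reasons: the threshold's defining phrase ties the SD to "each
single trial's" amplitude, and a per-segment threshold is degenerate
in burst-free segments — 2·SD of pure background is always exceeded
somewhere, and with the band-averaged series' ≈0.1 s correlation time
many such excursions survive the duration filter (measured precision
0.65 per-segment vs 0.98 per-trial at the default SNR). Per-segment
pooling remains available (`pool="segment"`).

**Flexible segmentation.** Each phase is shrunk by a 0.2 s margin at
both ends; an event whose onset falls in a working window belongs to
that phase, a boundary-crossing event extends the boundary to its
offset, and the next phase's effective start moves past the extension
(events starting inside a margin strip are captured by the preceding
phase). Every event is assigned to exactly one phase; rates use the
post-extension effective durations. Intervals are half-open
`[onset, offset)` with durations from sample counts.

**Fidelity scoring.** Detected and ground-truth events are matched
when their intersection covers ≥ 50 % of the *shorter* event — the
burst state (above-threshold time) is by construction shorter than the
generative envelope duration, so requiring coverage of the longer
event would conflate threshold geometry with detection failure.

## Networks (`betabold.network`)

Co-occurrence is `|A∧B|/|A|` on the binarized rasters (undefined when
A has no burst samples). FC is the maximum absolute Pearson
correlation over lags within ±100 ms (biased denominator, endpoints
included) on the band-limited signal itself — not its envelope —
Fisher-Z transformed with |r| clipped at 1 − 1e−7. Node strength is
the row mean of |FC| excluding the diagonal.

## HRF estimation (`betabold.hrf`)

The spherical Laguerre basis is
`b_j(n) = √(j!/((j+2)!α³)) · e^(−n/(2α)) · K_j(n/α)` with
`K_j(x) = Σ_{r≤j} C(j+2, j−r)(−x)^r/r!`; this normalization is the
unique one making the family orthonormal under the r²-weighted inner
product, verified by quadrature in the tests. Columns are convolved
with a unit-area Gaussian (mean μ, SD τ = 1 s, truncated at ±4τ) on a
causal 30 s support.

Fitting convolves the burst raster with the smoothed columns, adds an
intercept, and solves ordinary least squares; the hyperparameter grid
is L ∈ {1, 2, 3}, α ∈ {0.5, 0.75, 1.0}, μ ∈ {2.5, 3.0, …, 5.0} s
(the stated ranges at a practical resolution), scored by 3-fold CV
over contiguous thirds (time-blocked to respect autocorrelation) with
Pearson r on the held-out third; the winner is refit on the full
series. Features: peak = signed value at max |h| (negative-deflection
HRFs keep their sign), area = Σh·dt, power = Σh²/len; min-max
normalization is undefined for constant curves and reported missing.

**Model grid.** Estimation runs on a decimated grid (default 25 Hz in
the pipeline; any rate works) with the raster aggregated by bin sums,
which preserves burst-sample totals; tests assert that 250 Hz and
25 Hz fits agree in curve shape and CV performance. 25 Hz is
commensurate with TR = 2.12 s (53 samples per volume).

**Up-sampling.** TR-sampled BOLD is interpolated to the model grid by
a cubic spline (default); linear interpolation is available. Cubic
was made the default because the piecewise-linear round trip alone
caps noiseless HRF recovery near r ≈ 0.989 even when the estimator is
exact on the model grid, whereas the spline preserves > 0.99 recovery;
neither adds power above the original Nyquist beyond interpolation
roll-off.

**Surrogates.** The null redraws burst onsets uniformly over the
session, preserving event count and durations (rejection sampling
against overlap), and repeats the entire fit + CV; the p-value is
`(1 + #{null ≥ empirical}) / (n_shuffles + 1)`. Sample-permutation and
trial-shuffle variants were considered; onset redrawing destroys the
burst–BOLD alignment while preserving the regressor's marginal
statistics, which is the property the test needs.

## Statistics (`betabold.stats`)

Wilcoxon signed-rank tests drop zero differences (Wilcoxon's rule) and
report a tie-corrected, continuity-corrected normal-approximation z, so
an effect size `r = |z|/√n` exists even at n = 11; exact small-sample
p-values are available and are the default inside `mc_power`, matching
R's `wilcox.test` for tie-free data. The Rosenthal formula is not
universal in the literature but is the unique convention consistent
with all seven reported (z, r) pairs it is tested against. Note that
`z = 2.67, n = 11` gives r = 0.8050, on the rounding boundary — the
reported pair is consistent only because the reported z is itself
rounded; tests therefore use the propagated-rounding band
`0.005 + 0.005/√11` instead of naive re-rounding.

`mc_power` simulates normally distributed paired differences and
applies the two-sided exact Wilcoxon test at α (both configurable).
At n = 11 the signed-rank null is discrete: the attainable test size
nearest below 0.05 is 0.0420, so the null rejection rate calibrates to
0.042, not 0.05 — the calibration test asserts exactly that. For the
pegboard difference (−1.79 ± 1.77, n = 11), the achieved power
computes to ≈ 0.82.

The spin test draws uniform random 3-D rotations
(`special_ortho_group`), rotates the parcel centroids, and reassigns
map values by a one-to-one minimum-distance assignment
(`linear_sum_assignment`) rather than independent nearest-neighbour
lookup, so every null map is an exact permutation of the original
(value multiset preserved, no duplicated parcels); the two-sided
p-value is `(1 + #{|null| ≥ |obs|}) / (n_rot + 1)`, with the
95th-percentile threshold also exposed.

## Problem sizes in tests and drivers

The test suite and analysis drivers use reduced but non-trivial
problem sizes chosen as the smallest at which the asserted properties
are stable: 10–30 trial sessions with 2–6 parcels for the detection
chain, 5–10 minute sessions at 10–25 Hz model rate for HRF fitting,
99 surrogate shuffles / 99–200 spin rotations per null, and 5000
Monte-Carlo iterations for power (the count used in the study). All
randomness is seeded; identical seeds give bit-identical outputs.

## Known limitations

- The aperiodic model has no knee; spectra with a bend inside 3–45 Hz
  will bias the exponent.
- Detection is 1-D (band-averaged); frequency-resolved (2-D) burst
  detection and burst subtyping are out of scope.
- FC carries no volume-conduction or leakage correction.
- The surrogate and CV machinery assumes a stationary HRF within a
  session; drifting neurovascular coupling is not modelled.
- The exact size of the signed-rank test at small n is below the
  nominal α (see above); power values inherit that conservatism.
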