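# betabold

Analysis pipeline linking transient **beta bursts** (13–30 Hz) in
parcel-level EEG source series to **BOLD hemodynamics**, for
simultaneous EEG–fMRI studies of motor control. It implements, as a
tested and reusable package, the full chain from raw parcel time-series
to burst-driven hemodynamic response functions:

1. **Aperiodic (1/f) parameterization** — non-overlapping 1-s Hann
   spectra per task phase, decomposed as
   `log10 P(f) = offset − exponent · log10 f` with iterative exclusion
   of narrowband peaks; the 13–30 Hz aperiodic model defines the
   amplitude baseline for burst extraction.
2. **Burst detection** — Morlet time–frequency amplitude (mother
   wavelet 1 Hz / FWHM 3 s, rescaled per frequency), band-averaged,
   baseline-subtracted and clipped at zero; threshold 2·SD of each
   trial's amplitude; only excursions longer than 100 ms are kept.
   A *flexible interval* rule (0.2 s margins, dynamically extended
   boundaries) assigns every burst wholly to one task phase.
3. **Burst networks** — asymmetric co-occurrence rates
   `|A∧B| / |A|`, lagged cross-correlation FC (±100 ms, Fisher-Z),
   node strength, rank-shift comparisons.
4. **HRF deconvolution** — the spherical Laguerre basis

   `b_j(n) = sqrt(j! / ((j+2)!·α³)) · e^(−n/(2α)) · K_j(n/α)`,

   with `K_j` the generalized Laguerre polynomial of order two,
   smoothed by a Gaussian kernel `G(μ, τ=1 s)`; coefficients by least
   squares on the burst-train regressors, hyperparameters
   (`L ∈ {1..3}`, `α ∈ [0.5, 1]`, `μ ∈ [2.5, 5]` s) chosen by 3-fold
   CV on contiguous thirds; onset-shuffled surrogate nulls; HRF peak,
   area and power features.
5. **Statistics** — paired Wilcoxon signed-rank tests with Rosenthal
   effect sizes `r = |z|/√n`, Benjamini–Hochberg FDR, Simes global
   p, Monte-Carlo power for paired differences, and a spin test
   (random sphere rotations + one-to-one nearest-parcel reassignment)
   for spatial map correlations.

Because raw EEG–fMRI data of this kind are rarely shareable, the
package ships a first-class synthetic-session generator
(`betabold.synth`) emulating the handgrip paradigm — 50 trials of
inter-trial rest (3–5 s jitter), adapt 2 s, low 3 s, ramp 3 s, high 3 s
at 250 Hz — with 1/f background, phase-dependent Poisson burst packets,
burst-driven BOLD at TR = 2.12 s, and full ground truth for every
stage.

## Worked example

```bash
python analysis/01_simulate_session.py   # synthetic session + ground truth
python analysis/03_detect_bursts.py      # burst detection vs ground truth
python analysis/05_estimate_hrf.py       # HRF estimation + surrogates
```

The detection step prints, for a 6-parcel 10-trial session (seed 7):

```
        rate  amplitude  duration
phase
IT     0.535      0.652     0.212
adapt  0.406      0.612     0.214
high   0.288      0.637     0.209
low    0.201      0.695     0.229
ramp   0.231      0.631     0.223

detection vs ground truth: precision 0.996, recall 0.909
```

i.e. detected burst rates follow the generative phase ordering
(inter-trial > adapt > execution phases) and virtually every detected
event corresponds to a planted burst. The HRF step then reports
per-parcel CV prediction correlations around 0.83–0.95, surrogate
p = 0.02 (the floor at 49 shuffles) for every parcel, and a median
correlation of 0.991 between estimated and generating HRF curves.

The same pipeline is scriptable from a single config:

```bash
betabold demo --out out/ --seed 1      # every stage, one command
betabold run --config cfg.yaml         # custom configuration
```

## Layout

- `src/betabold/` — library: `synth`, `spectral`, `bursts`, `network`,
  `hrf`, `stats`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing `results/`
- `tests/` — pytest suite, including end-to-end acceptance properties
- `docs/methods.md` — model assumptions, parameter choices, limitations
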