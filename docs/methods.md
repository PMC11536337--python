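# Methods

This note documents the models and procedures `peepkit` implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter.

## The call and its eight parameters

The unit of analysis is a single-note tonal advertisement call ("peep"):
mean duration ≈ 64 ms, peak frequency ≈ 6.7 kHz within a 5.6–8.4 kHz band,
repeated about every 4 s, with occasional long breaks splitting a recording
into call sequences. Per call we measure:

| parameter | unit | definition |
|---|---|---|
| CD | s | selection duration, end − begin |
| CD90 | s | span between the 5% and 95% points of cumulative in-band energy |
| T95 | % | position of the 95% cumulative-energy point, relative to CD |
| ICI | s | end of a call to the beginning of the next; undefined for a recording's last call and across sequence breaks |
| PF | Hz | argmax of the call's mean power spectrum (FFT 1024, Blackman, hop 96) |
| LF, HF | Hz | 2.5% / 97.5% cumulative spectral-energy quantiles |
| FR | Hz | HF − LF, by definition |

T95 is reported as a percentage in (0, 100], matching how such envelope
statistics are printed in field studies. Temporal measures integrate the
band-limited waveform energy at sample resolution (FFT brick-wall band-pass,
linear interpolation of the quantile crossing), so a constant-amplitude call
gives CD90 = 0.9 CD and T95 = 95% up to discretization (< 0.2 ms / 0.2
percentage points). LF/HF use energy quantiles rather than a dB-down
threshold because that parallels the temporal energy-percentile measures and
is robust to noise; a −`x` dB-below-peak crossing is available
(`measure_spectral(..., method="db_down")`). Note that a pure tone's measured
FR is bounded below by the analysis window's main lobe (~4 bins ≈ 170 Hz for
the 1024-point Blackman), and for frequency-swept calls the energy-weighted
quantiles sit slightly inside the sweep extremes — LF/HF are descriptive
statistics of the spectrum, not estimates of the sweep endpoints.

## Detector

A band-limited energy detector: per-frame 5–10 kHz energy (FFT 64, Blackman,
hop 32; the hop is not fixed by convention, 50% overlap is the package
default) is compared against a noise floor that is the 20th percentile of the
band energy over a sliding 1 s block advanced by 0.5 s and held constant
between hops. Frames above `noise × 10^(21 dB / 10)` are hot; hot runs closed
over ≤ 1 cold frame form candidates; candidates need ≥ 60% hot-frame
occupancy, are merged when closer than 0.2 s, and must fall within the
duration bounds. The SNR threshold is interpreted in dB (the native unit of
such detectors); a 21% linear ratio would fire continuously on noise. The
published duration bounds (0.1–1 s) exceed the call durations this detector
targets and are kept only as the `DetectorSettings.raven_paper()` preset; the
working default is 0.01–1 s.

Boundary refinement (`refine_boundaries`, on by default) band-passes a padded
window around each candidate, smooths the instantaneous power over 0.5 ms,
and walks outward from the call peak to the first crossing of
`max(peak × 10^(−65 dB/10), 4 × window noise floor)`. On clean audio this
recovers the rendered call extent to within ~1 ms (under two frame hops); at
the default −30 dB noise the crossing sits where the envelope emerges from
the noise, leaving a few ms of onset bias — the same compromise a human
annotator faces. Detection is invariant to global gain by construction
(signal and floor scale together).

## Individuality metrics

Inclusion filters, applied in order: drop recordings made while the male sat
on a clutch (their calls differ systematically); drop recordings with < 30
calls; drop each recording's first 5 calls; drop every first-of-sequence call
(first calls are ~15% shorter and ~27% quieter — the package verifies this
with its own Welch t-test implementation); drop recordings left with < 25
calls, then males with < 3 qualifying recordings, and keep a seeded random 3
recordings per male. The original call count per recording is cached in a
`n_calls_orig` column so re-applying the filters is a no-op.

* **CV decomposition.** CV = SD/mean × 100 (sample SD). CVw is the mean over
  males of the mean within-recording CV; CVb is the CV of all pooled calls.
  Ratios above 1 indicate individual distinctiveness.
* **PCA** on the correlation matrix (the parameters mix s, Hz and %), with a
  deterministic sign convention (largest-magnitude loading positive).
  Eigenvalues sum to the number of parameters; two are ~0 because CD90 and FR
  are near-deterministic functions of the other parameters.
* **Beecher's Hs.** Per PC, a one-way ANOVA with male as factor;
  `HS_j = log2(√F_j)` floored at 0, summed over either all PCs or only those
  with eigenvalue > 1. This is the F-to-bits convention of the
  identity-metrics literature (IDmeasurer's `calcHS`). ANOVA units are
  individual calls; a recording-means variant is available
  (`unit="recording_means"`). `2^Hs` is the maximum group size in which an
  individual remains identifiable.
* **LDA assignment** uses scikit-learn's linear discriminant classifier
  (shared within-class covariance) under leave-one-call-out (default),
  leave-one-recording-out, or resubstitution; a rank-deficient pooled
  covariance triggers shrinkage regularization with a warning. Accuracy is
  reported per male and as mean ± SD against the 100/n_males % chance level.
  Leave-one-recording-out is the most honest scheme when recording-level
  effects exist, and on null data its accuracy sits slightly *below* nominal
  chance (a known property of cross-validated classifiers), so null
  comparisons should use a permutation distribution rather than 1/n.

A caveat the tests make explicit: because `HS_j` grows with the ANOVA F,
which grows linearly with the per-male call count, Hs on large, clean,
exactly-Gaussian synthetic data is much larger (≈ 20 bits at the default
calibration) than values reported from noisy field recordings (≈ 3 bits).
The package therefore asserts the *properties* of Hs (monotone in
between-male variance, ≈ 0 under permuted labels, conservative policy ≤ full
policy) rather than any absolute synthetic value.

## Regression stages

* **Total mating success** (per male): Poisson GLM with log link, response =
  seasonal clutch count, predictors = body size and the male's mean CD, ICI,
  T95, PF and FR (CD90, LF, HF are omitted from the preset as near-collinear
  with these; custom designs are accepted). Fitted by IRLS implemented in
  `peepkit.stats` (convergence when max |Δβ| < 1e-8, 50-iteration cap,
  divergence guard for separation-like geometry); Wald z from the
  expected-information covariance. Verified against an independent numerical
  likelihood maximization to 1e-6 and against statsmodels.
* **Nightly mating success**: logit model `success ~ calling +
  clutch_present + (1 | male)`, marginal likelihood by adaptive Gauss–Hermite
  quadrature — per male, a Newton inner loop finds the posterior mode and
  curvature of the random intercept, and the 15-node (default) Hermite rule
  is recentred and rescaled there; 1 node is exactly the Laplace
  approximation. The marginal likelihood is maximized with BFGS over
  (β, log σ); standard errors come from the numerical Hessian. σ → 0 is
  reported as a boundary fit; a single-male dataset degenerates to a plain
  logistic GLM. The quadrature agrees with dense adaptive integration to
  1e-4 in log-likelihood, and the Wald test's type-I error under a null
  simulation lies in the nominal band.
* **Condition LMMs**: per parameter, `y ~ condition + temperature + rainfall
  + (1 | male)` with treatment coding, brooding as the reference level. REML:
  the variance *ratios* are profiled on the log scale and every solve uses
  the Woodbury identity, so the cost scales with the number of random-effect
  levels, not calls. Term tests are Wald chi-square on the fitted model
  (2 df for the 3-level condition); a likelihood-ratio alternative is
  deliberately not offered to keep the reported statistic unambiguous.
  P-values across the 8 parameter models are corrected by weighted
  Holm–Bonferroni (equal weights by default = classical Holm; weights
  configurable). Pairwise condition contrasts use estimated marginal means at
  covariate means with studentized-range (Tukey) adjustment for 3 groups and
  containment-style residual df `n − p − (n_groups − 1)` — the df convention
  is a package choice, stated in the output.
* **Descriptive means**: per-parameter intercept-only model with random
  intercepts for male, recording (nested in male) and calling condition,
  using the same variance-components machinery (three factors through
  Woodbury); degenerate condition grouping falls back to two-level nesting
  with a warning.

## Synthetic-data generator

Each male owns latent means for six base parameters (CD, ICI, T95, PF, LF,
HF) drawn from population normals; each recording shifts them again
(recording-level CV); each call jitters within the recording (within CV).
Frequency draws are rejected until 0 < LF < PF < HF (bounded retries).
Defaults reproduce the published descriptive statistics of this call type:
means (0.064 s, 4.04 s, 78.9%, 6724/6440/7153 Hz), within-recording CVs
(8.08, 18.3, 5.14, 1.37, 1.34, 1.59 %), and pooled between-male CVs (13.67,
36.21, 9.97, 3.58, 2.75, 5.22 %). Because the pooled CV includes the
within-recording scatter, the latent male- and recording-level CVs are each
set to √((CVb² − CVw²)/2) — an even split, chosen once; the data do not
constrain the split, and it determines how harsh leave-one-recording-out
validation is.

Calls render as sine sweeps LF → PF → HF (PF at the envelope peak) under a
raised-cosine attack/decay envelope whose asymmetry is solved (bisection on a
4096-point energy grid, cached) so the 95% cumulative-energy point lands at
the target T95; attainable T95 spans ≈ 55–98% of CD and targets are clipped
into that range. CD90 derives from the same envelope; FR = HF − LF. Sequence
structure: each call is followed, with probability 0.05, by a break of
21 s + Exp(5 s) (just above the 20 s `seq_gap_threshold` that defines a new
sequence downstream — the threshold itself sits just above the largest
plausible within-sequence interval); the first call of each sequence is
scaled by 0.846 in duration and 0.734 in amplitude (the published first-call
deficit). Condition offsets relative to "no clutches" are +0.002 / −0.003 s
(CD) and −0.187 / +0.532 s (ICI) for guarding / brooding, reproducing the
published pairwise contrasts (brooding − guarding = −0.005 s CD, +0.719 s
ICI). Call duration shortens with temperature at −0.0005 s/°C around 25 °C
(the direction is established; the magnitude is a package choice of
plausible size). Amplitude is arbitrary per recording (recording distance is
uncontrolled in the field): lognormal spread of 0.3 at the recording level
and 0.1 per call. Background noise is white Gaussian at −30 dB (amplitude)
relative to the nominal call peak; pink or rain-burst noise is out of scope.
ICIs across sequence breaks are recorded as missing — a break is silence, not
call spacing.

Behavioral-stage simulators: per-male seasonal clutch counts are Poisson with
log-mean `log(4.7) + 73 × (CD − 0.064)` (only call duration has a true
effect); nightly observations cover 48 males × 30 nights with calling
probability 0.7, clutch presence 0.5, true effects (−5.29, 3.54, 0.57) and
male random-intercept SD 1 — sized so the rare non-calling successes are
populated and the GLMM is identifiable.

What the generator does **not** emulate — and hence what passing tests do not
show about field data: reverberation and multipath (the dominant cause of
manual boundary correction in real recordings), overlapping heterospecific
callers, rain transients, amplitude modulation within a call, non-Gaussian
parameter distributions, and measurement error in male identity. Absolute
individuality metrics (Hs, LDA accuracy) on synthetic data are therefore
optimistic; the recovery and invariance properties are the meaningful
results.

## Problem sizes and determinism

Simulation-based checks use study-scale data (26 recorded males × 3 kept
recordings × ≥ 25 calls; 48 monitored males) with 100 Poisson replicates,
60 GLMM replicates and 20 LMM replicates — sizes at which CI coverage and
sign-recovery rates are stable to a few percent. All randomness flows from
numpy `default_rng` seeds; identical spec + seed reproduces tables and WAV
audio bit-for-bit. Coverage checks simulate from the fitted model's own
assumptions (no recording-level variance in the LMM recovery runs), since
Wald CI coverage is only defined against the data-generating process the
model assumes; the individuality analyses keep the full calibration,
including recording effects.

## Known limitations

* The detector is a semantic reimplementation of the published settings, not
  a bit-exact clone of the commercial tool; occupancy/separation interplay
  follows the contract stated above.
* LF/HF estimate spectral-energy quantiles, not sweep endpoints.
* The GLMM supports a single random intercept (male); crossed or slope
  effects are out of scope.
* Tukey p-values use a fixed residual-df convention rather than
  Satterthwaite/Kenward–Roger approximations.
* Hs inherits the sample-size sensitivity of its F-ratio definition; compare
  values only at matched designs.
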