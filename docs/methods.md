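# Methods

## Data model

A recording is organised as patient → days → sessions → per-condition trial
tensors of shape (trial × channel × timepoint), with one shared time axis in
seconds relative to stimulus onset. Conditions are exactly `"yes"` and
`"no"`; per-condition trial counts may differ and may be zero. On disk the
dataset is a JSON manifest (authoritative for the time axis, channel count
and sampling rate) plus one tidy long CSV per session with header
`condition,trial,channel,time_s,value`. Values are written with 17
significant digits, so a write→read round-trip reproduces every float
exactly; CSV time values must agree with the manifest axis to a relative
1e-9. Trial and channel indices are 0-based and contiguous; no probe
geometry is stored because none of the analyses use it.

## Averaging orders and replicate units

`collapse(dataset, spec)` applies unweighted arithmetic means over two of
the three axes {trial, session, channel}, in the stated order; the surviving
axis becomes the replicate unit of the subsequent timepoint-wise two-sample
t-test.

- `A-flawed` (trials, then sessions; channels survive): the test compares
  condition means using the across-**channel** variance. Channels measure
  overlapping hemodynamics and share systemic noise, so they are far from
  independent; with inter-channel correlation ρ = 0.95 and 20 channels the
  across-channel variance understates the sampling variance of the condition
  means by roughly a factor (1−ρ) + session/trial noise terms, and t-values
  in the tens appear in pure noise.
- `B-correct` (channels, then trials; sessions survive): sessions are
  modelled as independent replicates, and the test is calibrated (type-I
  fraction ≈ α on the null generator).

Both canonical orders produce *identical* grand-mean curves — each reduces
algebraically to mean over sessions of (mean over trials of (mean over
channels)) — including for unbalanced designs. The orders differ only in
the retained variance, which is exactly the point.

The default test is the unpaired pooled-variance Student t; paired and Welch
variants are exposed by flag because the original analyses' exact choice is
unknown. Degenerate inputs are defined, not delegated: zero pooled variance
with equal means gives t = 0, p = 1; zero variance with unequal means gives
p = 0, a signed-infinite t, and a `RuntimeWarning` plus a per-timepoint
`degenerate` flag (noiseless synthetic fixtures hit this path). Multiple
comparison correction defaults to `"none"` to mirror the audited analyses;
Bonferroni and Benjamini–Hochberg are available, and for the per-channel
analysis they are applied jointly across channels × timepoints.

Since collapsing channels can dilute a spatially localised effect,
`channelwise_ttest` runs the session-replicate analysis separately per
channel and is the recommended mode for real data.

## Permutation validity audit

`audit(dataset, spec, n_perm, audit_alpha, seed)` reruns collapse + t-test
after randomly reassigning pooled trials to conditions. Permutation is
within-session, preserving each session's per-condition counts — the
conservative choice that respects session-level structure; a global
(dataset-wide pooling) variant is available by flag. A permutation is
*flagged* when any timepoint has uncorrected p < `audit_alpha` (default
0.0005, the display threshold at which the flawed analysis is examined).
Permutation i uses derived seed `(seed, i)`, so individual permutations are
reproducible in isolation. A sound procedure should flag at roughly the rate
1 − (1 − audit_alpha)^(effective number of independent timepoints) — about
0.1 for 200 independent timepoints — while the channel-replicate order flags
essentially every permutation.

With `n_perm = 0` the result is defined (empty counts, 0 flagged,
`fraction_flagged = NaN`, serialised as `null`).

## Decoding pipeline

Per day, trials from all sessions are pooled and reduced to features.
Default features are per-channel window means: mean over the response window
(2, 8) s minus the mean over the baseline window (−5, 0) s. The response
window brackets the canonical HRF peak at ~5 s; a ±3 s window retains most
of the effect's discriminable energy under the generative model while
keeping one feature per channel. A flattened `full_timecourse`
representation is available by flag.

Accuracy is estimated by stratified 10-fold cross-validation (stratification
declared: it prevents degenerate single-class test blocks on small days).
Within each training fold, classes are balanced by randomly undersampling
the majority class — training data only; held-out trials are never balanced
and never touch model selection. The regulariser C of a linear SVM is chosen
by an inner 10-fold grid search on the balanced training data over 7
log-spaced values 10⁻³..10³, ties resolved toward the smallest
(most-regularised) C. The solver is scikit-learn's liblinear primal
formulation (`LinearSVC(dual=False)`, tol 1e-4): deterministic and fast over
the entire C grid. Pooled correct/total counts across folds — not the mean
of fold accuracies — feed the binomial test, because the binomial model
needs trial counts.

A leakage guard is part of the contract and the test suite: with the fold
partition held fixed, flipping every held-out label changes neither the
selected C nor the trained model's decision values.

## Chance-level assessment

`accuracy_binomial_test(k, n, chance, alpha)` computes the exact one-sided
tail P[X ≥ k] under Binomial(n, chance) (two-sided and less-than variants by
flag) plus a two-sided Clopper–Pearson interval at 1 − α. One-sided
significance at α coincides exactly with the one-sided lower Clopper–Pearson
bound at confidence 1 − α exceeding `chance` (tested). Chance defaults to
0.5 for the yes/no paradigm and is configurable for others.
`min_trials_for_significance(target, chance, alpha)` searches n = 1, 2, …
exactly; e.g. a perfect decoder needs n = 5 against chance 0.5 at α = 0.05,
and 80% accuracy needs well over 10 trials — which is why accuracy claims
from 10-trial samples carry no evidential weight without this test.

**Caveat (measured here, applies equally to the procedure being audited):**
the binomial test treats pooled CV predictions as independent Bernoulli
draws, but folds share overlapping training data. On pure-noise features
(400 trials, 20 features) the pooled accuracy is unbiased (mean 0.498 over
100 simulations) yet its standard deviation is ≈ 0.032 versus the binomial
0.025, so the nominal 5% test rejects ≈ 12% of null runs. Exceeding-chance
claims from pooled CV counts are therefore somewhat anti-conservative even
when done "correctly"; day-level replication (each day an independent
binomial) mitigates this.

## Synthetic generator

Per trial, channel c, time τ:

x(τ, c) = β·h(τ)·g_c·[condition = yes] + σ_s·z(τ) + ε_c(τ) + d_c(τ)

- `h`: double-gamma HRF (peak delay 6 s, undershoot delay 16 s, dispersions
  1 s, undershoot ratio 1/6), zero for τ ≤ 0, normalised to unit peak; the
  peak sits at ≈ 5 s.
- `z`: shared standard-normal process, white in time, scaled by σ_s — the
  sole source of inter-channel correlation, ρ = σ_s²/(σ_s²+σ_c²).
- `ε_c`: independent per-channel white noise, sd σ_c.
- `d_c`: per-channel stationary AR(1) drift (coefficient φ, innovation sd
  σ_i; marginal variance σ_i²/(1−φ²)) — the sole source of temporal
  autocorrelation, kept orthogonal to the correlation knob by design.

Everything is drawn fresh per trial; datasets are bit-reproducible given the
seed. The effect enters only "yes" trials (the analyses only use the
difference). The model is jointly Gaussian, so the Bayes-optimal
single-trial accuracy is Φ(d/2) with d² = μᵀK⁻¹μ; because the channel
covariance block-diagonalises in the channel eigenbasis (all-ones direction
vs its complement), d² reduces to at most two T×T solves
(`bayes_discriminability`). A brute-force full-covariance likelihood-ratio
Monte-Carlo serves as the independent cross-check in the tests.

### Presets (the simulated study conditions)

- `null-highcorr`: β = 0, ρ = 0.95 (σ_s² = 0.95, σ_c² = 0.05), 20 channels,
  1 day × 10 sessions × 10 trials/condition, epochs (−5, 20) s at 8 Hz (200
  timepoints), no drift. The regime in which the averaging-order flaw is
  most visible.
- `effect-strong`: epochs (−5, 15) s at 2 Hz, ρ = 0.95, AR(1) drift with
  marginal sd 2.0 and φ = 0.95, 10 sessions × 20 trials/condition, and
  β ≈ 1.343 computed at preset construction so the model's Bayes accuracy is
  exactly 0.9. The noise mix and epoch were fixed from the closed-form
  discriminability of the *window-mean feature* under the same model
  (≈ 0.80), so a competent decoder on default features can recover most of
  the model's separability.
- `imbalanced`: null data with 7 yes / 3 no trials per session, exercising
  the undersampling logic.

Sampling rates and epoch windows are stand-ins chosen for the simulator; the
source experiments' acquisition parameters are not public in usable form.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analyses are sensitive to:
channel correlation, session/trial grouping, class imbalance, baseline
windows, a canonical evoked response, slow drift. It deliberately omits
physiological detail — Mayer waves, motion artifacts, heterogeneous channel
loadings by default, HbR, non-Gaussian tails, session-level random effects.
Passing tests therefore demonstrate that the *procedures* behave as claimed
(calibration, inflation, audit verdicts, decoder recovery) on data meeting
their assumptions; they do not certify behaviour on real recordings, where
session-level random effects would further widen the gap between the two
averaging orders' validity.

## Numerical and design choices

- Time axes are uniform by contract; `n = round((end − start)·fs)` samples
  at `start + k/fs`.
- Seeds: all derived via `numpy.random.SeedSequence`-style composite keys
  (`[seed, stage, index]`), so stages and permutations are independently
  reproducible.
- Reports are JSON validated against pydantic models whose JSON Schemas ship
  under `trialaudit/schemas/`; reports contain no timestamps, so reruns with
  the same config are byte-identical. Timings go to the stderr log.
- Problem sizes in the acceptance script (20 null simulations, 5 effect
  simulations, 400-trial decoding panels) are the package's chosen study
  conditions; the whole script runs in well under a minute on one CPU.

## Known limitations

- Sessions are treated as exchangeable replicates; a hierarchical
  (mixed-effects) model would be the better analysis for real multi-day data
  and is intentionally not implemented here.
- The binomial-vs-chance test on pooled CV counts is anti-conservative under
  fold dependence (measured above).
- No cluster-based permutation statistics across timepoints; the audit's
  flag criterion is the simple any-timepoint rule.
- The `.mat` layout of the original supplementary data is not parsed; the
  CSV/manifest interchange carries the same logical schema.
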