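# Methods

This note documents the models, estimators and numerical choices behind
`innerspeech`, and what the synthetic-data tests do and do not establish
about real recordings.

## Task and data model

A session is a set of trials of a cued word-production task. Each trial
has six fixed-duration phases — ITI 2.0 s, cue 1.5 s, D1 0.5 s, internal
speech 1.5 s, D2 0.5 s, vocalized speech 1.5 s (7.5 s total) — and one of
W = 8 words (six lexical, two pseudowords), cued aurally or in writing.
All times are seconds relative to trial start; intervals are half-open
[onset, offset). Auditory cues begin 200–650 ms into the cue phase (the
sound-output latency of the rig being emulated); written cues appear at
phase onset.

Behavioural error trials (speaking during the internal phase, vocalizing
the wrong word) are retained in the on-disk archive with an `error_kind`
flag and removed only at analysis time, so the archive remains a faithful
record and every analysis applies the same exclusion.

## Synthetic sessions

Each simulated unit is an inhomogeneous Poisson process with a
piecewise-constant rate: a baseline plus an additive gain per (word,
phase), plus an optional cue-modality gain during the cue phase. Additive
gains (spikes/s) keep effect sizes directly interpretable against the
baseline. Defaults, chosen once as a realistic strongly-tuned regime:

- baseline ~ Gamma(shape 2, scale 4), mean 8 spikes/s — a typical
  cortical single-unit range;
- tuned fractions 0.5 / 0.5 / 0.6 of units in cue / internal / speech;
- gain magnitudes |N(5, 2)| spikes/s per word;
- SMG-like units: word-selective gains in the active phases; by default a
  unit reuses one per-word gain profile in every phase it is tuned in
  (`word_code="shared"`), so word codes generalize across phases and
  tuning is preserved between internal and vocalized speech;
  `word_code="independent"` gives orthogonal phase codes for control
  experiments;
- S1-like units: one word-agnostic gain, in the vocalized-speech phase
  only — speech production modulates them, word identity does not;
- auditory trials draw an audio onset ~ U(0.200, 0.650) s and the
  cue-phase gain starts at audio onset; rates are clipped at zero and
  clip events counted; trial order is one seeded permutation per session.

What the generator does *not* emulate: within-phase rate dynamics
(responses are flat within a phase), spike-waveform or refractory
structure, rate drift across a session, correlated noise between units,
and latency heterogeneity (latency defaults to 0). Passing tests
therefore establish the correctness and calibration of the estimators
under Poisson variability and the task's factorial structure — not
robustness to every property of real recordings.

## Firing rates

Rates are spike counts in 50-ms bins divided by the bin width, smoothed
with a Gaussian kernel of width 50 ms. The kernel width is interpreted as
the standard deviation (the most common convention; the choice is
isolated in one constant), truncated at ±4σ and renormalized. Edge
handling is reflection padding, which keeps constant signals exactly
constant at trial boundaries. Smoothing is applied across the whole trial
before any phase slicing, and before audio-onset alignment.

Audio-onset alignment re-indexes the cue-phase bin block of auditory
trials so bin 0 starts at the audio onset rounded to the nearest bin
edge; the block's tail reads the immediately following (real) bins, and
the tensor reports the common-coverage window (cue duration minus the
largest shift) past which cue bins mix with the next phase. Non-auditory
trials pass through unchanged.

A phase's bin set is every bin whose left edge lies in [onset, offset);
phase averages are plain means over those bins.

## Word tuning

Per unit, firing rate is modelled as FR = Σ_w β_w X_w + β₀, with X_w the
word indicator and β₀ the offset equal to the unit's average ITI rate.
The offset is implemented literally: the ITI mean (over the same trials)
is subtracted from the response and the W indicators are fit without an
intercept, so β_w is exactly the word mean minus the ITI mean. The
alternative — estimating β₀ from pooled ITI reference rows — mixes the
2-s ITI window's (low) residual variance into the tested phase's; with
0.5-s delay phases that understates the standard errors fourfold and
inflated the null false-positive rate to ~20% in simulation, which is why
this package anchors the offset instead. Because β_w inherits the
sampling variance of the subtracted ITI mean, that variance
(Var(ITI)/n) is added to SE(β_w)²; with it, the measured null
false-positive rate is at the nominal 5% per phase. For the ITI phase
itself this correction double-counts shared trials and is slightly
conservative, which is acceptable for a rest-phase control.

t = β/SE with residual d.f. n − W; two-sided p values; Benjamini–Hochberg
FDR per unit across its W word p values (per bin or per phase); a unit is
tuned where min_w p_adj < 0.05. Zero-residual-variance units are reported
untuned with p = 1 rather than dropped. The regression runs per task
phase (on phase means) or per 50-ms bin (per-bin response against the
trial's ITI mean). Kruskal–Wallis across words (tie-corrected, chi-square
approximation) is the non-parametric alternative, FDR-adjusted across
units within each phase — note the different family: the regression's
family is the W words within a unit, Kruskal–Wallis' the units within a
phase, matching how each statistic is typically reported.

Across-session summaries use the mean ± t_{0.975, n−1}·SE confidence
interval; with one session the CI is undefined and reported as NaN.
Rest-vs-action phase comparisons are paired two-tailed t tests with
paired Cohen's d = mean(diff)/SD(diff), BH-FDR over the tested pairs
(ITI→cue, D1→internal, D2→speech).

## Word decoding

Features are phase-averaged rates (trials × units). Per fold, PCA is fit
on the training rows only and the smallest number of components whose
cumulative variance share strictly exceeds 0.95 is kept; an LDA with
equal priors and a covariance matrix shared across words is fit in that
space. Leave-one-out cross-validation refits everything per fold, so the
held-out trial can never influence the model (verified by hashing fold
models against corrupted held-out trials).

Numerical choices: when the training count is small relative to the
feature count (n ≤ q + K), the pooled covariance is shrunk toward its
diagonal; the shrinkage intensity is the analytic Ledoit–Wolf estimate
computed on the within-class-centered residuals (the analytic formula
targets a scaled identity; its intensity is reused here with the diagonal
target, which preserves feature scales while conditioning the solve). A
singular covariance falls back to the pseudo-inverse. Discriminant ties
are broken toward the lowest class index in word-list order, making every
prediction deterministic.

Significance grading repeats the entire LOO procedure on label
permutations (class counts preserved): 100 repetitions offline, 1,000 for
online runs; observed mean accuracy above the null's 97.5th percentile is
reported as p<0.05, above the 99.5th as p<0.01.

Cross-phase generalization uses the same leave-one-out folds: the fold
model is trained on the training phase's rows of the training trials and
tested on each phase's row of the held-out trial, so testing on the
training phase reproduces within-phase LOO exactly and same-trial leakage
is impossible by construction.

The online simulation replays the closed-loop protocol: a decoder trained
on internal-phase rates of all data seen so far classifies each trial of
the next run once (feedback logged), then is retrained on the accumulated
set — simple accumulation, no weighting of newer runs. The training
budget is reported as repetitions × 1.5 s of internal-phase data per word
(16 repetitions ⇒ 24 s). Online shuffle nulls permute the accumulated
training labels and re-classify the run.

## Demixed PCA

The balanced tensor X[n, t, c, w, k] (units × time × cue modality × word
× trial) is decomposed exactly as

X = X̄ + X̄_t + (X̄_c + X̄_tc) + (X̄_w + X̄_tw) + (X̄_cw + X̄_tcw) + ε,

with each term computed by ANOVA-style nested averaging
(inclusion–exclusion on the trial-averaged tensor) and ε = X − ⟨X⟩_k.
Time-independent pure terms are grouped with their time interactions
(timing, cue, word, cue×word). The decomposition reconstructs X to
machine precision and the terms are mutually orthogonal under the
balanced design — both property-tested on random tensors.

Balancing: each (modality, word) cell holds exactly k trials; an error
trial's slot is filled with the mean of the cell's remaining valid trials
(the k−1 replacement rule); over-full cells are truncated
deterministically by trial id.

Per grouped marginalization φ, the encoder F_φ and decoder D_φ minimize
‖X_φ − F_φ D_φ X‖² + μ‖F_φ D_φ‖² with μ = (λ‖X‖)², X the trial-averaged
mean-centered data matrix and ‖·‖ the Frobenius norm. The closed form is
the ridge regression of X_φ on X followed by rank-q truncation through
the SVD of the fitted values; encoder columns are unit-norm left singular
vectors (scale absorbed into D_φ), components ordered by the SVD. At
λ = 0 with a single full-data target this reduces exactly to PCA (tested
via principal angles). q defaults to 3 per marginalization. λ is chosen
by tenfold CV that holds out one trial per cell per fold and scores the
held-out marginalizations' reconstruction error.

Variance accounting: shares are fractions of the total mean-removed
variance; under the balanced design the marginalization terms (×K) plus
noise sum to it exactly. Because averaging K noisy trials leaves residual
noise in the trial average, each marginalization also carries an expected
noise floor df_φ/(TCW) · ‖ε‖²/(K(K−1)) (expected mean squares, with
df_t = T−1, df_c = T(C−1), df_w = T(W−1), df_cw = T(C−1)(W−1)); the
ledger's `signal_variance_share` subtracts it, so a word-agnostic
population reports a word signal share that is statistically zero even at
small K, while the raw share would be dominated by the floor. The floor
is exact for noise homoscedastic across cells at each (unit, bin) and a
close approximation for Poisson rates.

Pseudo-populations across sessions are formed by stacking per-session
units (units recorded in different sessions treated as if simultaneous);
the package operates per session by default and leaves stacking to the
caller.

## Pipeline and reproducibility

A single JSON config drives simulate → rates → tuning → decoding →
cross-phase → online → dPCA → report. Every stochastic stage derives its
seed from the master seed as SHA-256(master:stage:counter) mod 2³¹, so
adding or toggling a stage never perturbs another stage's randomness and
a config plus master seed regenerates all numbers exactly (manifest with
seeds and input hashes included). The report is regenerated idempotently
from whatever artifacts exist.

## Problem sizes in the test suite

The suite exercises the pipeline at sizes chosen to make the statistics
informative while keeping runs quick: sessions of 8–16 repetitions × 8
words with 10–40 units; 100-repetition shuffle nulls; 200 null sessions
(12 units each) for the false-positive calibration; 10 sessions for the
paired phase comparisons; 100 random tensors for the decomposition
identities. These mirror the emulated study's per-session scale (8–16
repetitions, tens of sorted units per array).

## Known limitations

- The tuning regression assumes homoscedastic residuals within a phase;
  Poisson rates are variance-heterogeneous across words with very
  different rates. The calibration tests bound the practical impact at
  the session sizes above.
- The dPCA noise floor assumes within-cell noise homoscedastic across
  cells; strongly word-dependent variance would bias the corrected word
  share slightly upward.
- The online simulation is a faithful offline replay of the protocol, not
  a real-time system; no latency, artifact or drift modelling.
- Cross-session pseudo-population construction is left to the caller; no
  alignment or unit-matching across days is attempted.
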