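# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `emaqc`.

## The design being evaluated

The pipeline targets a signal-contingent EMA protocol: 14 momentary days
with 4 prompts/day, each prompt issued at a uniform-random moment inside a
fixed 2-hour window (08, 12, 16, 20 h), a reminder after 30 minutes, and
expiry at the window's end — a design maximum of 56 assessments per
participant. Every assessment carries 12 common 7-point Likert items
(stress, energy, concentration, 5 positive-affect and 4 negative-affect
items); morning and evening assessments carry additional non-scored items,
which matters only for the per-assessment item count used by time-per-item.
Missingness is completion-only: a prompt is either answered inside its
window or missed; there is no item-level missingness. Internally days are
labelled 1–14; in study terms these are days 2–15, the first and last study
day being questionnaire days outside the momentary design.

## Participation and compliance

Participation = invitees with ≥1 completed assessment / all invitees.
Compliance = completed / 56, never pro-rated for late entry; summary
statistics are computed over participants, and the mode lives on the
discrete `n/56` grid. Exposure effects are estimated one exposure at a
time, always adjusting for sex, nationality, age group and field of study
(reference levels: male, Spanish, 18–21, arts & humanities):

* participation — logistic regression, reported as odds ratios;
* compliance — Poisson regression on completed counts with a constant
  `log 56` offset, reported as exp(β) (equivalent, up to that constant, to
  modelling the completion proportion; the offset formulation keeps the
  outcome a genuine count).

Wald 95% intervals on the log scale are reported for both. Counts out of 56
are not Poisson — person-level heterogeneity makes them overdispersed — so
a `robust=True` option switches to HC1 sandwich standard errors; the plain
Poisson interval remains the default reporting convention, and the test
suite uses the robust option wherever honest coverage matters.
Non-estimable models (separation, empty cells) are returned as flagged
results with a diagnostic rather than raised.

## Variance decomposition and reliability

**Two-level.** A random-intercept model splits a score's variance into
between-person σ²_B and momentary within-person σ²_W;
ICC = σ²_B/(σ²_B+σ²_W). When every person has the same occasion count the
closed-form one-way ANOVA estimator `σ̂²_B=(MSB−MSW)/n, σ̂²_W=MSW` is used —
on balanced data it *is* the REML solution, computed exactly; unbalanced
data go through REML (statsmodels `MixedLM`, warm-restarted with a tight
gradient tolerance so variance estimates are sharp to ~1e-8).

**Three-level.** Item responses follow
`y[p,t,i] = μ + P_p + T_pt + I_i + PI_pi + e_pti` with items crossed with
persons and occasions nested in persons. Balanced designs use the
expected-mean-squares solution

    σ̂²_ε = MS_E                      σ̂²_PI = (MS_PI − MS_E)/n
    σ̂²_T = (MS_T(P) − MS_E)/k        σ̂²_I  = (MS_I − MS_PI)/(a·n)
    σ̂²_P = (MS_P − MS_T(P) − MS_PI + MS_E)/(n·k)

Unbalanced data use REML with the k (≤5) items as fixed effects and
person, occasion-within-person and item-within-person variance components;
σ²_I — which enters neither reliability coefficient — is then recovered
from the spread of item means with a moment correction for the noise they
carry. Negative component estimates are truncated at 0 with a logged
diagnostic so reliabilities stay in [0, 1].

**Reliability coefficients.** From the components, the between-person and
within-person generalizability coefficients

    R_kRn = (σ²_P + σ²_PI/k) / (σ²_P + σ²_PI/k + σ²_T/n + σ²_ε/(k·n))
    R_cn  = σ²_T / (σ²_T + σ²_ε/k)

with k items per scale and n occasions per person; for unbalanced data n is
the **harmonic mean** of per-person completed-occasion counts — standard
generalizability-theory practice that reduces to the common n when
balanced. Values are clamped to [0, 1] and interpreted on the classic
bands (0.00–0.10 practically none, 0.11–0.40 slight, 0.41–0.60 fair,
0.61–0.80 moderate, 0.81–1.00 substantial), applied after rounding to two
decimals so the band edges match the printed convention.

**Per-person Cronbach α** is computed for each scale across a person's
occasions: `α = k/(k−1)·(1 − Σ s²_i / s²_total)`. It is undefined (returned
missing, never flagged as zero) for persons with fewer than 2 occasions or
zero variance in occasion totals; negative values are legitimate and
retained.

**Agreement ICC.** The stability analysis uses the two-way single-rater
absolute-agreement ICC, `(MSR−MSE)/(MSR+(k−1)MSE+(k/N)(MSC−MSE))`, not
clamped below 0 (near-zero agreement is informative); it is cross-checked
in the tests against pingouin's ICC(A,1) and a brute-force two-way ANOVA.

## Careless detection

A completed assessment is careless when time-per-item ≤ 1.0 s (the
inclusive boundary; the threshold is a config knob) or its 12 common items
have zero sample SD (equivalently 100% of items at the mode). Missed
assessments are never flagged. The thresholds are justified by
psychometric-antonym curves: the item pair with the most negative Pearson
correlation over all completed assessments (ties broken to the lowest item
indices) is re-correlated inside each suspicious subset. Straight-lined
subsets force the antonym columns to be identical, so that correlation is
reported as exactly 1 by construction.

The minimum number of valid assessments comes from a resampling stability
analysis: persons with ≥40 completed assessments contribute their first 40
in chronological order as a gold standard (a deterministic choice; a
seeded random selection is available), random subsets of sizes 2–40 are
drawn 5 times per size, each person's subset mean and SD of PA and NA are
compared to the gold standard by the agreement ICC, replicate curves are
averaged *before* thresholding, and "stabilized" is operationalized as the
smallest size from which all four averaged curves stay ≥0.90 at every
larger evaluated size. A curve that never reaches the target yields a
"not reached" result with the full curve attached.

A participant is a potential careless responder when their count of valid
(completed and unflagged) assessments falls below that minimum, or when raw
α < 0.11 on either scale (negative α counts as below; missing α is
reported but does not flag by itself). Flagged responders are marked for
sensitivity analyses, never dropped.

## The synthetic cohort generator

The generator's defaults are the study conditions the pipeline assumes:
1259-scale invitation lists with 62.1% participation; quota subsamples at
21.4/29.9/26.3/22.4% (suicidal ideation / alcohol / anxiety-depression /
control); covariate mixes matching a Spanish student EMA cohort; mean
compliance 76.9% with wide person spread (Beta-distributed person
probabilities, SD 0.27) and a −1 point/day linear trend centred mid-study;
score-level affect variances σ²_B = 0.94/0.88 and σ²_W = 0.81/0.80 for
PA/NA. Item-level components (σ²_I = 0.05; σ²_PI = 0.15/0.12;
σ²_ε = 2.0/1.3 for PA/NA) were chosen so the implied reliabilities sit at
the observed pattern — R_kRn ≈ 0.97–0.99, R_cn ≈ 0.50 (PA) and 0.59 (NA) —
and the latent person/occasion variances are derived from the score-level
targets by subtracting σ²_PI/k and σ²_ε/k, so the simulated *score*
variances land on the configured values. PA and NA latents are negatively
coupled (ρ = −0.6 between persons, −0.4 within) so antonym pairs exist.
Momentary deviations are exchangeable by default; an optional AR(1)
parameter adds serial correlation.

Honest completion timestamps use an exponential latency (median 15 min,
the observed median response delay) and lognormal time-per-item (median
3.9 s, log-SD 0.35 — at that spread the honest tail below the 1-second
threshold is ~5·10⁻⁵, so false positives at zero injection are negligible).
Careless behaviour is injected at the observed rates (0.13% fast with
uniform-random items and TPI in 0.3–0.95 s; 0.78% straight-lined), with
half of the careless budget concentrated in an 8-person cluster and the
rest spread uniformly — reproducing the observation that half of careless
responses cluster in a handful of participants.

**What the generator does not emulate:** the latent-to-Likert mapping
(round and clamp to 1–7) truncates the tails, shrinking realized score
variances by roughly 20–25% relative to the latent targets (e.g. PA
between/within ≈ 0.72/0.70 instead of 0.94/0.81) while approximately
preserving their ratio, so recovery tests target the ICC rather than the
raw components; within-person variance is homoscedastic across persons, so
per-person α concentrates near R_cn (~0.5) instead of showing the long
observed upper tail of highly reliable individuals; and there are no
context items, add-on morning/evening content beyond an item count, or
nonrandom missingness mechanisms. Passing tests therefore demonstrate that
the estimators recover the structure this model encodes — not that real
cohorts satisfy that structure.

## Problem sizes and numerics

The test suite and drivers run the two-level recovery at 600–2000 persons ×
40 occasions (balanced, closed form — seconds), the three-level REML at
100–250 persons (its cost grows with persons × occasions × items; estimates
are population-level and stabilize well below full cohort size, so the
pipeline subsamples persons for this fit by default, `three_level_max_persons`),
and the stability analysis at 5 replicates × sizes 2–40. All randomness
flows from a single integer seed via deterministic substreams; identical
configuration and seed reproduce every table and report byte for byte.
Degenerate inputs (all-constant scores, empty subsets, separation) return
flagged/missing results with diagnostics instead of raising wherever the
quantity is legitimately undefined.

## Known limitations

* Plain Poisson intervals for compliance are anti-conservative under the
  overdispersion the design produces; the robust option exists and is the
  statistically sound choice, but the naive interval is kept as the default
  reporting convention.
* The three-level REML treats items as fixed effects, so σ²_I is a moment
  approximation; it feeds no downstream coefficient.
* The careless rules are screening heuristics: nothing in the pipeline can
  externally validate that a flagged response was truly inattentive.
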