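# Methods

This note documents the statistical machinery in `clickbias`: the models
and procedures, their assumptions, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical choices that affect results.

## Archive model and filtering

An archive is a set of independent experiments (RCTs); each experiment
holds ≥1 arms (headline variations) with aggregated impression and click
counts. No individual-user data is modelled — the binomial likelihood
needs only the aggregates. Filtering applies two rules: arms with
identical headline text (exact match after trimming leading/trailing
whitespace; no case folding, since variant casing is a deliberate
editorial treatment) are merged by summing clicks and impressions, and
experiments left with fewer than two arms are removed. Merging runs
*before* single-arm removal: merging can itself collapse an experiment to
one arm, and removal last guarantees that every surviving experiment has
at least two distinct headlines. Filtering is idempotent and conserves
experiment-level totals through merging. Arms with zero impressions are
dropped with a warning rather than failing the archive; they carry no
trial information.

## Text scoring

Preprocessing lower-cases, splits on whitespace, and strips punctuation
and `#` from tokens; internal apostrophes are kept so contracted
negations (`don't`) survive as single tokens. Matching is exact unigram
membership — no stemming — which is the standard dictionary approach for
short texts.

**Negation.** A negation term puts the following 3 tokens (configurable
scope) in its scope. Polarity words in scope are counted in the opposite
list; emotion words in scope are skipped entirely (there is no "opposite"
emotion). A token governed by several negations is flipped once — the
nearest preceding in-scope negation governs, flips never stack. Scope is
counted in the post-preprocessing token stream and does not stop at
sentence boundaries by default (headlines rarely contain internal
boundaries); with scope 0 negation handling is the identity. A token
present in both polarity lists counts once in each — symmetric and
auditable. The default negation list (not, no, never, n't-contractions,
…) is user-overridable.

**Sentiment scores** are proportions of all tokens
(`n_positive/n_total`, `n_negative/n_total`); an empty headline has an
undefined score. **Emotion profiles** count hits per basic emotion over
tokens outside negation scopes and divide by the total number of
emotion-category hits, so the 8-vector sums to exactly one and a word
tagged with several emotions contributes once per emotion (the
normalization forces this per-hit denominator; counting tokens once would
not sum to one). Zero hits ⇒ profile undefined ⇒ the row is excluded from
the emotion regression. **Moral proportions** are not negation-inverted:
a negated moral word is still moralized language.

**Readability.** Gunning Fog `0.4 × (ASL + 100 × n_wsy≥3/n_w)` with
sentences split on terminal `.!?` before token stripping (a headline
without terminal punctuation is one sentence) and complex words = tokens
with ≥3 syllables, no exclusions. Syllables come from a frozen
deterministic heuristic — count maximal vowel groups (a e i o u y),
subtract a terminal silent 'e' unless it is the only group, floor 1.
Readability values are defined *relative to this heuristic*; the test
suite pins hand-applied counts. Flesch–Kincaid grade
(`0.39·ASL + 11.8·syllables/word − 15.59`) is the alternative complexity
metric for robustness runs.

## The multilevel binomial model

For arm *j* of experiment *i*: `clicks_ij ~ Binomial(impressions_ij,
θ_ij)` with `logit(θ_ij) = x_ij'β + z_ij'b_i`, `b_i ~ N(0, Σ)`. The
random effects capture story-level heterogeneity (some stories are more
clickable than any wording can fix); varying slopes on the sentiment
terms additionally let language receptivity differ across experiments.
Experiments are the single grouping level; arms within an experiment are
conditionally independent given `b_i`.

**Standardization.** Covariates are z-standardized (sample SD, n−1),
unweighted over headline rows, so coefficients are per-SD effects and
comparable across variables. A constant covariate is a degenerate input
and errors with the variable's name.

**Estimation** maximizes the Laplace-approximated marginal likelihood —
the de-facto standard for binomial mixed models. Per experiment, the
conditional mode `b̂_i` is found by a batched Newton iteration with
per-group step-halving (objective-improvement tolerance relative to the
objective scale; convergence at max-gradient ≤ 1e−8, up to 100
iterations; irrecoverable inner failure raises), and the contribution is

    ℓ_i = log p(y_i | b̂_i) − ½ b̂_i'Σ⁻¹b̂_i − ½ log det(Σ H_i),

with `H_i = Z_i'W_iZ_i + Σ⁻¹` the curvature at the mode. Binomial
combinatorial constants are included so degenerate limits match plain
binomial log-likelihoods exactly. The outer problem — fixed effects plus
a log-Cholesky parameterization of Σ (log standard deviations bounded in
[log 1e−6, e⁸]; free strict-lower-triangle entries for the `full`
structure, omitted for `diagonal`) — is solved by L-BFGS-B (max 500
iterations, ftol 1e−12, gtol 1e−6; all configurable). Starting values:
fixed effects from a no-random-effect IRLS logistic fit, covariance at
0.1·identity. Design columns are internally scaled to unit SD before
optimization and estimates mapped back — a pure reparameterization that
makes raw-scale fits as well-conditioned as standardized ones. The fit is
deterministic given data and starting values.

**Inference.** Standard errors come from the inverse numerical Hessian
(central differences) over the fixed effects at the optimum with Σ held
fixed — the usual conditional-on-variance-parameters convention. Wald
z-tests are two-sided normal; CIs default to 99%. P values are carried at
machine precision; rounding happens only in the human-readable rendering
(3 decimals for coefficients).

**Effect translation.** `100 × (e^β − 1)` is the percent change in click
odds per SD. The per-word translation divides 1/mean-length (the shift in
the raw proportion from one extra dictionary word in an average-length
headline) by the raw proportion's SD to reach the standardized scale,
then applies the odds translation. This is an interpretation layer; its
self-consistency is verified by a refit oracle (fitting on the raw
proportion and evaluating a 1/mean-length change gives the same answer),
not against any external figure.

**Two models, one verdict.** The pre-registered scheme fits the
random-intercept model and the varying-slopes model; when their
qualitative conclusions disagree, interpretive precedence goes to the
varying-slopes fit (the more flexible specification). The varying-slopes
covariance defaults to `full` (intercept–slope correlations estimated)
with a `diagonal` fallback on convergence failure.

**Validation oracles.** An adaptive Gauss–Hermite quadrature evaluator
(default 25 nodes, random-intercept model) computes the same marginal
likelihood to high accuracy and exists purely as a cross-check; with the
variance fixed at zero the fit must match plain logistic ML (checked
against statsmodels GLM). The Laplace error per experiment scales
inversely with the experiment's click information, so oracle-agreement
tests use small archives with ~10⁶ impressions per experiment, where the
two evaluators agree to ≤1e−4 in log-likelihood. Likelihood invariances
(affine reparameterization, sign flips) hold exactly at the likelihood
level; at the *fit* level agreement is limited by quasi-Newton
termination (~1e−5), which the tests acknowledge with correspondingly
looser tolerances.

## Auxiliary inference

**KS comparison.** The two-sample Kolmogorov–Smirnov D (supremum of the
absolute ECDF difference, via scipy) compares the positive vs negative
proportion distributions; the p value uses the asymptotic distribution,
appropriate at the tens-of-thousands-of-headlines scale this targets.
Exact small-sample p values are out of scope.

**Equivalence.** The pre-declared rule is CI containment: verdict
`null-supported` iff the Wald CI at the chosen level (default 99%) lies
inside the open interval (−0.001, 0.001); otherwise `inconclusive`. A
TOST p value (the larger of the two one-sided normal tests against the
bounds, consistent with Wald inference elsewhere) is reported alongside
but does not drive the verdict. Equivalence tests are triggered in the
pipeline for emotion coefficients whose two-sided p ≥ alpha
(default 0.01, the 99% convention; configurable).

## Power simulation

The bootstrap power analysis mirrors a pre-registration power study:
sample `n_experiments` experiments with replacement from a pilot feature
table (each resampled copy becomes its own group — the experiment is the
resampling unit, so all its arms move together), simulate clicks from the
multilevel model with the target coefficient forced to the hypothesized
effect, re-standardize within the simulated dataset, refit, and flag
detection. For a nonzero effect a detection must be significant *with the
configured sign* (a wrong-sign significant estimate is not a success); at
effect 0 any-sign rejection is counted, which makes the same machinery a
type-I-error calibration. Power = detection fraction; MC SE =
√(p(1−p)/n). Refit failures are excluded with a count and >10% failures
flag the result unreliable. Runs are bit-reproducible for a fixed seed
(per-dataset generators are spawned from one seed sequence, so datasets
are also identical across effect sizes — "shared seeds"). Alpha defaults
to 0.01 to match the 99%-CI convention. Desk-scale defaults are 200
datasets × 500 experiments; the published-study scale (1,000 datasets ×
22,743 RCTs) is configurable but long-running.

## Synthetic-data generator

The generator is the stand-in for a real headline-RCT archive and defines
the study conditions for every end-to-end test. Structure emulated, with
defaults:

- experiments: categorical arms-per-experiment on 3…12 with a
  geometric-ratio pmf solved to mean 4.31 (median 4);
- impressions: lognormal per experiment with mean 16,670 (log-scale SD
  0.5 — the real archive's dispersion is not published; this is a
  plausible choice, not a calibration), split ~evenly across arms by a
  multinomial;
- headlines: token strings of Poisson(15) length (min 3) drawn from
  pairwise-disjoint synthetic vocabularies (nonsense words built from 1–4
  consonant-vowel syllable units, so the readability index sees a
  realistic mix of simple and complex words) with per-token insertion
  probabilities — positive 2.8%, negative 2.6% (matching the prevalence
  ordering where positive words are slightly more common), each basic
  emotion 1.2%, moral 1%, negation 2%, remainder neutral;
- truth: intercept logit(0.014) (baseline CTR ≈ 1.4%), standardized
  coefficients positive −0.008, negative +0.015, length +0.04, complexity
  −0.004, platform age −0.309, random-intercept SD 0.3, optional slope
  SDs/correlations; dates uniform over a ~27-month window.

Ground truth is defined on the standardized scale of the *realized* data:
the generator computes each headline's features with the package's own
scoring functions, standardizes within the generated archive, applies the
true linear predictor plus drawn random effects, and simulates clicks as
Binomial(impressions, θ). Parameter recovery is therefore exact in
expectation without knowing population feature moments, and recovered
features match the generator's bookkeeping by construction — including
negation effects, since negation words are inserted independently of
sentiment words (so negation handling is exercised both with and without
in-scope targets). The truth record stores everything needed to recompute
every row's θ exactly.

What the generator does **not** emulate: grammar or any linguistic
structure (statistical structure is the contract); correlation between
sentiment and topic or date; the platform's adaptive stopping of
experiments (arms are fixed-size completed trials); heavy-tailed
impression imbalance across arms. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not robustness to real-data pathologies like dictionary sparsity
or severe arm imbalance.

Because the random intercept enters a convex region of the logistic at
low baseline rates, the realized mean CTR of a generated archive sits
slightly above the baseline logistic(intercept) (~1.5% vs 1.4% at the
defaults); simulation-mean tests compare observed CTRs against the truth
record's exact θ, not against the baseline.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks use 9-experiment, ~10⁶-impression instances
(where the Laplace approximation is sharp). Parameter recovery uses 50
archives of 500 experiments × 4 arms × ~4,000 impressions/arm — large
enough for near-nominal CI coverage, small enough for a desk run. Power
calibration uses 200 null datasets of 300 experiments (type-I error
against the 99% binomial band around alpha) and 50-dataset runs at
effects 0.01/0.03 for the shared-seed monotonicity check. The descriptive
emulation checks use a 2,000-experiment archive.

## Known limitations

- The Laplace approximation is biased for experiments with very few
  clicks; the quadrature oracle covers only the random-intercept model.
- Standard errors condition on the estimated random-effect covariance
  (no propagation of Σ uncertainty), the standard practical convention.
- The equivalence TOST p value is reported from the same Wald SEs as the
  CI; only the CI-containment verdict is authoritative.
- Topic labels are consumed, never inferred — topic modelling is out of
  scope; dummy coding uses the most frequent topic as the reference
  level.
- No multiple-testing machinery: per-coefficient tests at the 99% level
  only, matching the pipeline's reporting convention.
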