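# Methods

This note documents the models and procedures `emovar` implements, the
choices made where the problem left the design open, and what the
synthetic-data experiments do and do not demonstrate.

## Emotion scoring of short texts

A **lexicon** assigns each emotion (by default anger, anxiety, sadness)
four match classes — literal words, prefix wildcards (`abhor*` matches
any token starting with `abhor`), multi-token phrases, and emoticons —
plus a platform **base rate** `p_B(m)` in percent units. The
per-document **linguistic score** of emotion *m* is

    p_m(t) = 100 · |matched token positions| / |tokens(t)|

Matching scans token positions left to right per emotion: the longest
phrase starting at a position is tried first (a phrase counts as one
word event and consumes its tokens; its tokens still all count in the
denominator), then literal/prefix/emoticon matches on the single token.
A position counts at most once per emotion, but the same token may
count for several emotions whose lexica both contain it — the score is
computed independently per emotion.

**Tokenization.** URLs and @-mentions are removed first (the `://` in a
URL would otherwise match an emoticon); emoticons (the lexicon's set
plus a small built-in list) are then extracted verbatim in position;
hashtags keep their word part; the remainder is lowercased and split on
any character that is not a letter, digit, or internal apostrophe
(`’` is normalized to `'`). Documents that tokenize to zero tokens
(e.g. a bare URL) are *unscorable*: the score's denominator is
undefined, so they are skipped and counted, never treated as zeros.

**Daily and weekly indices.** Grouping scorable documents by calendar
date *d* (a single configurable named timezone, default UTC), the daily
index is the mean percent deviation from the base rate,

    index(d, m) = (100 / |T_d|) · Σ_{t ∈ T_d} (p_m(t) − p_B(m)) / p_B(m),

a dimensionless quantity that is 0 when the day's mean score sits at
the base rate and 100 when it sits at twice the base rate. Weekly
scores are arithmetic means of the available daily indices over
consecutive 7-day blocks anchored at a configurable start date (study
default 2020-01-21, 50 weeks) — deliberately not ISO weeks, so that
wave counting is independent of where the study starts in the calendar.
A requested week with no covered days is an error, not a silent NaN.

## Panel assembly

The behavior proxy is a trends-style relative search/shopping index on
a 0–100 scale (period maximum = 100). The reader skips leading metadata
lines until a `Day,`/`Week,` header, maps `<1` cells to 0.5, and
validates bounds and period ordering. Daily behavior data are averaged
(not summed — the index is a relative volume, not a count) over the
same 7-day blocks as the emotions. The aligned panel has fixed column
order `[behavior, anger, anxiety, sadness]`.

By default the panel fed to the VAR is **standardized** per column
(subtract sample mean, divide by sample standard deviation with
denominator T−1). Standardization makes impulse responses comparable
across variables — a "one-SD shock" reading — and since a VAR is
equivariant under per-variable affine maps, it changes no Granger test
and only rescales IRFs. The choice is recorded in the panel provenance
and reversible with `--no-standardize`.

The Pearson screen reports r with the exact two-sided t test,
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.

## VAR estimation and lag selection

The K-variable VAR(p)

    y_t = c + A_1 y_{t−1} + … + A_p y_{t−p} + e_t,  e_t ~ WN(0, Σ)

is estimated by per-equation OLS on rows p+1..T; Σ uses the
maximum-likelihood scaling (divide by T−p). Lag order is chosen on a
**common sample** (all candidates use rows p_max+1..T, so criteria are
comparable across p) by

    AIC(p) = ln det Σ_p + 2(K²p + K)/T_c,
    BIC(p) = ln det Σ_p + ln(T_c)(K²p + K)/T_c,

counting intercepts in the penalty; ties break toward the smaller
order (parsimony). Stability is the standard companion-matrix
condition: all K·p eigenvalue moduli strictly below 1, reported in
full.

## Granger causality

Non-causality of X for Y is tested by the small-sample block F-test:
the unrestricted model is Y's equation from the full K-variable system,
the restricted model removes X's p lags, and

    F = ((RSS_r − RSS_u)/p) / (RSS_u / df),  df = (T−p) − (Kp + 1).

Tests run inside the full 4-variable system by default (block
exclusion), matching the single system model the analysis fits; a
`bivariate` flag reduces to the two series involved. The six directed
hypotheses (each emotion ↔ behavior) are reported without
multiple-testing correction at α = 0.05 — correcting them is a
substantive departure from the analysis design this package
reproduces. Under the null the test is only asymptotically exact
(lagged dependent regressors); the Monte-Carlo calibration experiment
(T = 200, 2000 replicates) verifies the empirical size stays near the
nominal 5% and the null p-values are approximately uniform.

## Impulse responses and bands

MA coefficients follow the recursion Ψ_0 = I,
Ψ_h = Σ_{j≤min(h,p)} A_j Ψ_{h−j}. Orthogonalized responses use the
lower-triangular Cholesky factor P of Σ (Σ = PP'): Θ_h = Ψ_h P, whose
column k is the horizon-h response to a one-standard-deviation
orthogonal shock in variable k. The default Cholesky ordering is
`[behavior, anger, anxiety, sadness]` — the order the variables enter
the model — and is stamped into every result, because orthogonalized
IRFs are ordering-dependent. A unit-shock variant rescales P's columns
to unit impact. Default horizon is 10 weeks.

Confidence bands are a **recursive-design residual bootstrap**:
center the fitted residuals, resample rows with replacement,
regenerate the T panel rows from the first p observed rows with the
fitted coefficients, refit, recompute Θ, and take pointwise
percentile quantiles at α/2 and 1−α/2 over B replicates (default
B = 1000; an explicit seed is required, and the draw stream is fully
reproducible). The bootstrap refuses to run from an unstable point
estimate. Percentile intervals are distribution-free but can
undercover slightly at small T because of the OLS small-sample bias in
autoregressive coefficients; the coverage experiment (true VAR(1),
T = 200, B = 200, 200 replicates) measures pointwise coverage of the
true h = 1 response near but slightly below the nominal 95%.

## Synthetic-data generator

The generator is the package's ground truth. A latent weekly VAR over
`[behavior, anger, anxiety, sadness]` (scenario presets `null`,
`anxiety-driver`, `paper-like`; intercepts 0, innovation SD 12 in
index units, diagonal own-lags ≈ 0.25–0.3) is simulated with a burn-in
(default 50 weeks) from a single master seed; every downstream draw is
derived from that seed, nothing consumes unseeded entropy. The
`paper-like` preset plants the qualitative structure the analysis is
meant to detect: a strong positive anxiety→behavior coupling at lag 1,
a slight negative anger→behavior coupling at lag 3, a delayed negative
behavior→anxiety feedback at lags 2–3, and a sadness series fully
decoupled from behavior.

Emotion components of the latent state are percent-deviation indices.
For each date the generator inverts the index definition into a
per-token match probability q_m = (p_B(m)/100)(1 + target_m/100) and
emits documents of `tokens_per_doc` tokens, each token being emotion
m's designated generator word with probability q_m and a neutral
filler otherwise. Generator words are single literal words matched by
exactly one emotion, so per-document scores are exact binomial
proportions and the recovered daily index is an unbiased estimator of
the latent target with analytic standard error. Targets implying
q outside [0,1] (below −100% or extremely large) are refused as
infeasible rather than clipped. The innovation SD of 12 keeps 6–7σ
excursions of the latent indices above the −100% feasibility floor.

Daily targets expand from the weekly path by **piecewise-constant**
repetition by default: the analysis consumes only weekly means, and
constant expansion preserves them exactly, which makes the
generator/analyzer consistency property provable without edge effects.
Linear interpolation between mid-week anchors is available
(`interpolation: linear`) for smoother corpora, at the cost of small
cross-week smoothing of the recovered weekly means.

The latent behavior component is affinely mapped onto the integer
0–100 scale of the trends file format (path minimum → 0, maximum →
100, recorded in the manifest). The downstream standardization undoes
the affine map up to rounding, so the planted Granger/IRF structure is
preserved. Fixture lexicon base rates (anger 1.8, anxiety 2.4, sadness
2.1 percent) are the generator's defaults — i.e. the base rates of the
synthetic reference corpus — at the few-percent scale typical of
emotion categories in microtext.

**What the generator does not emulate:** natural language (documents
are word salads with the right match statistics), user-level dynamics,
diurnal posting patterns, document-length variation, non-English text,
and sampling biases of real platforms. Passing the end-to-end tests
therefore shows the *pipeline* recovers a known signal from text with
the assumed statistical structure — not that real social-media text
satisfies those assumptions.

## Problem sizes used in the test suite

Monte-Carlo experiments are sized so the full suite runs comfortably
on one CPU: coefficient recovery uses 50 replicates at T = 2000; lag
selection 100 replicates at T = 500; test calibration 2000 null and
500 alternative replicates at T = 200; bootstrap coverage 200
replicates with B = 200 at T = 200; and the end-to-end causal-recovery
study 50 replicated corpora of 2000 weeks at 5 documents/day × 20
tokens. The corpus size per day is deliberately small there — with
2000 weeks of panel the Granger tests are overwhelmingly powered even
under heavy measurement noise, and the experiment's purpose is
structural recovery, not index precision. The generator's *default*
corpus density (500 documents/day) matches the study-scale fixture.

## Known limitations

- Dictionary scoring has no negation handling, stemming, or sarcasm
  awareness; scores are bag-of-words percentages by construction.
- Orthogonalized IRFs depend on the Cholesky ordering; results carry
  their ordering, but no order-invariant (generalized) IRF is offered.
- Percentile bootstrap bands are pointwise, not uniform over horizons,
  and can undercover mildly at small T.
- No unit-root/cointegration pre-testing or seasonal adjustment is
  performed; the stability check is the only stationarity diagnostic.
- The trends reader accepts only the `date,value` dialect with
  optional metadata preamble.
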