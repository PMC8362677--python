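# Methods

This note records the statistical models the package implements, the
conventions chosen where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## 1. Differential search-trend measures

Each word carries two daily relative-search-volume (RSV) traces on a
[0, 100] scale, one per calendar window (baseline year and epidemic
year, Jan 1 – Apr 27 by default). A reference trace ("COVID-RSV") is
the pointwise mean of four epidemic-term traces. Four measures quantify
the epidemic-specific change in a word's association with the
reference:

- **Z_Pears** — Steiger's Z comparing r(reference, word) between the two
  years, treating the correlations as *non-overlapping but dependent*
  (all four series observed on the same aligned days):

      Z = (z1 − z2) · sqrt((n − 3) / (2 − 2·s̄)),

  with z1, z2 the Fisher transforms of the two correlations and s̄ the
  pooled-correlation ("r-bar") form of the Pearson–Filon covariance:
  s̄ = ψ(r̄)/(1 − r̄²)², r̄ = (r1 + r2)/2, where ψ is the standard
  fourth-moment term in the four cross-correlations with r̄ substituted
  for the two compared correlations. The pooled form presumes the
  compared correlations are equal — the null the test addresses; its
  type-I calibration (n = 118, 10,000 null draws) and agreement with a
  bootstrap standard error are asserted in the test suite.
- **Z_Spear** — the identical computation after rank-transforming every
  series (average ranks for ties), i.e. on Spearman correlations.
- **r_diff / ρ_diff** — Pearson / Spearman correlation between the
  word's year-difference series and the reference's year-difference
  series.

Positive values mean the epidemic-year association exceeds the
baseline-year one. Conventions: leap day dropped before pairing windows
(keeps month-day correspondence; the original handling is unstated);
interior gaps of ≤ 2 days linearly interpolated, longer gaps exclude
the word with a logged reason; correlations of exactly ±1 clipped to
±0.999999 before the Fisher transform, with a warning; two-sided
normal p-values exposed for completeness.

## 2. Stimulus selection

REL+ (REL−) words are those *consistently* in the top (bottom) 2.5%
tail: stage 1 admits words in the tail on ≥ 3 of 4 measures; if the
group of 20 is short, stage 2 admits tail-on-≥2 words ordered by
extremity. Extremity is the mean of the per-measure percentile ranks
(midranked ties); UNREL takes the 20 words with the smallest mean
|percentile − .5|, i.e. unremarkable on *all* measures (the absolute
reading matches the original description of UNREL exemplars as having
the smallest absolute correlation). Ties break lexicographically, so
selection is a deterministic function of the records. Tail thresholds
are empirical quantiles with linear interpolation, inclusive at the
boundary. Part-of-speech restriction (nouns/verbs) is applied *before*
computing tails by default — whether the original tails were computed
over all words or admissible words only is unstated, so the
alternative is a configuration switch.

## 3. Lexical regression

The outcome is ln|measure| (magnitudes floored at 1e−8, floored cases
counted — values that small do not occur on realistic input). Pearson
and Spearman zero-order correlations are reported per norms predictor
(valence, arousal, dominance, familiarity, concreteness, log word
frequency; frequency is log-transformed as is standard). The stepwise
regression is forward with removal checks: entry p < .05, removal
p > .10 (conventional defaults; only the tolerance rule is inherited
from the original analysis), and a *tolerance* guard — a candidate
enters only if every predictor in the augmented model keeps
1 − R²(predictor | others) ≥ .6. All retained tolerances ≥ .6 is an
asserted invariant. Rows with missing predictors are dropped and
counted.

## 4. Rating-shift effect sizes

Ratings are 1–9 self-assessment-manikin judgments on valence, arousal
and dominance; the normative side provides per-word mean, SD and n.

- **Reliability**: Pearson r of current vs normative item means per
  dimension, plus split-half correlations over many random participant
  halves (Spearman–Brown corrected, 2r/(1+r); median and range
  reported; odd participant counts split ⌊P/2⌋ / ⌈P/2⌉).
- **By-items paired t** per dimension, with standardized mean change
  d = t/√n (this convention reproduces the reported d's exactly from
  the reported t's) and a noncentral-t confidence interval for d.
- **Per-word Welch t** against the norms, computed from summary
  statistics (the norms publish no raw ratings); pooled-SD Cohen's d
  with large-sample variance (n1+n2)/(n1·n2) + d²/(2(n1+n2)).
- **Internal meta-analysis**: fixed-effect inverse-variance combination
  of per-word d's within stimulus group ("internal meta-analysis"
  without further qualification is read as fixed-effect); between-group
  heterogeneity Q* = Σ w_g (d_g − d_··)² with group weights w_g = Σ wᵢ,
  referred to χ²(G−1).
- **By-items Welch ANOVA** on per-word mean rating differences across
  stimulus groups (heteroscedastic F with fractional denominator df),
  with η²p = F·df1/(F·df1 + df2) — the conversion reproduces all three
  reported effect sizes from the reported F/df pairs — and pairwise
  Welch post-hocs with d and d-CIs. No multiplicity correction is
  applied across the per-word tests, mirroring the original reporting.

## 5. Crossed random-intercepts moderation models

Per dimension and covariate (PANAS−, PANAS+, FCV-19S; centered), the
model for the rating difference of participant s on word i is

    diff_si = β0 + StimType_g(i) + slope_g(i)·x_s + u_s + w_i + e_si.

For the balanced design (every participant rates every word) the fit
decomposes exactly into three orthogonal strata, which is how the
default engine computes it: word means regressed on group (StimType F
with df (G−1, W−G)), participant means regressed on the covariate
(df (1, P−2)), and the double-centered residual table for the
interaction (df (G−1, (P−1)(W−1) − (G−1))). For P=71, W=60, G=3 this
yields (2, 57), (1, 69), (2, 4128) — the published df layout, which is
why this stratified (containment) rule is the default; the df method
behind the published table is not named there and is inferred from
those dfs. The stratum mean squares are the ANOVA variance-component
estimators, which coincide with REML in the balanced case; per-group
slopes carry standard errors (V_u + V_e/W_g)/S_xx with V_u, V_e from
the matching strata. An `engine="reml"` option fits the same model by
REML (statsmodels MixedLM, crossed variance components) and applies
the same df rule to its Wald statistics; the two engines agree on
balanced data (asserted). Sum-to-zero contrasts code StimulusType; the
interaction F is invariant to covariate centering (asserted). Singular
fits are reported with a boundary flag, not raised. No random slopes,
matching the intercepts-only design.

## 6. Sensitivity power analyses

Both analyses solve for the smallest standardized effect reaching
power .80 at α = .05 by bisection of a noncentral power function
(results independent of the starting bracket; asserted to 1e−4).

**Mixed-design ANOVA** (3 groups of 20 items × 2 repeated measures,
repeated-measures correlation ρ = .80): noncentrality
λ = f²·N·m/(1−ρ) with df (m−1, (N−k)(m−1)) for the within effect (the
default target — the current-vs-normative shift) and ((k−1)(m−1),
(N−k)(m−1)) for the interaction. Effect-size conventions in this
family are not unique. The default reports the minimal effect on the
f scale together with η²p = f²/(1+f²): under this pairing the
reference configuration gives .116 with η²p = .013, matching the
published companion pair (d = .12, η²p = .014) — which is mutually
consistent only if the printed "d" is numerically the ANOVA f. The
classical two-level mapping d = 2f is available
(`d_convention="2f"`) and gives .233 for the same design.

**Crossed stimuli-within-condition design** (p participants × q
stimuli, q_c per condition, random intercepts with variance
partitioning coefficients v_P/v_S/v_E of the unit total variance):
participant intercepts cancel from the condition contrast, so the
operative test is the two-sample t on stimulus means with

    SE(d) = sqrt(2·(v_S + v_E/p)/q_c),   df = q − 2.

For a balanced design this equals the mixed-model Wald test of
condition (asserted against the REML fit), and its analytic power
matches Monte-Carlo power over 2,000 simulated crossed datasets within
.03 (asserted). The reference configuration (71, 60, .1/.15/.75)
gives d = .295. The three stimulus groups are mapped onto the
two-condition template with q_c = q/2 (the template's own design
definition); q_c is a configuration knob.

## 7. Synthetic data

- **Trends**: baseline-year series = level + seasonal sinusoid
  (random phase/amplitude per word) + AR(1) noise; epidemic-year
  series add κ_w × (logistic ramp switching on at the first-case
  date, growth rate .25/day); epidemic-term series are the ramp plus
  noise. Every series is max-normalized to 100 and floored at 0, as
  search-interest exports are. The ramp is a stylized epidemic pulse —
  only the coupling structure matters for testing, no attempt is made
  to reproduce the real 2020 curves.
- **Norms**: means drawn wide enough to span published normative
  ranges, per-word SDs ~ U(1.0, 2.3), normative n per word in the low
  thirties, log-normal frequency, noun/verb/adjective labels.
- **Ratings**: normative mean + per-group shift + per-group covariate
  slope + participant intercept + word intercept + residual, the three
  random components scaled to the requested VPCs (defaults .1/.15/.75)
  of a total variance of 1.5² rating units², then rounded to the
  9-point scale and clipped to [1, 9]. Default group shifts are the
  observed per-group lockdown shifts; questionnaire scores are drawn
  at the observed sample means/SDs. Rounding (~1/12 variance) and
  clipping attenuate realized VPCs slightly; the clipped fraction is
  reported, and recovery tests use norms with central means so the
  distortion stays ≈ 1%. What passing tests show is that the
  *pipeline* recovers planted structure under its own model; real
  ratings (ordinal, participant-specific scale use, non-Gaussian
  tails) may depart from that model in ways the generator does not
  emulate.

## 8. Problem sizes and numerics

Calibration suites run at the design's own sizes: 10,000 null draws
for the Z-test calibration, 2,000 Monte-Carlo power replicates, 200
parameter-recovery fits, 10 seeds × 1,000 words for planted-signal
recovery — the balanced-strata fitter makes the recovery loops cheap
(milliseconds per fit). Deep-tail noncentral-t values that underflow
in scipy fall back to the standard normal approximation of the
noncentral t. The log-magnitude floor (1e−8), correlation clip
(0.999999) and bisection tolerance (1e−8) are fixed constants, logged
or warned about when they bind.

## 9. Known limitations

- The published inferential statistics for the collected-data stages
  (regression R², reliability coefficients, Tables of F's) were
  computed on the deposited ratings, which the package does not ship;
  those stages are validated by printed-number consistency and
  parameter-recovery on synthetic data instead.
- The pooled Steiger covariance is a null-calibrated approximation;
  with very unequal true correlations its SE departs from the
  bootstrap SE (documented in the test suite's oracle choice).
- Forward stepwise selection inherits the known instabilities of
  p-value-driven selection; it is implemented because it is the
  procedure being reproduced, not an endorsement.
- r_diff/ρ_diff are invariant to adding a constant to any series but
  *not* to year-specific rescaling; the Z measures are invariant to
  both (each year's correlation is scale-free).
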