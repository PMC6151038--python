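# Methods

## Measurement model

All ratings are modelled with the partial credit model (PCM), the
unrestricted Rasch model for ordered polytomous responses.  An item with
m + 1 categories (here m = 4) has thresholds τ₁…τₘ, the points on the
latent continuum where adjacent categories are equally likely; the
category probability for a person at θ is proportional to
exp(Σ_{k≤x}(θ − τ_k)).  The model assumes unidimensionality, equal
discrimination across items (no slope parameters — deliberately, for
parameter separability and raw-score sufficiency), and local independence
given θ.  Thresholds are left unconstrained in order, so disordered
categories remain observable; the item location δ is the mean of the
thresholds, and the scale's translation indeterminacy is fixed by centring
Σδ = 0 within each calibration.

"Don't know" responses are recorded separately in the data model but enter
every model-based computation as missing; plain missingness and don't-know
shares are reported per item, with the < 10% data-quality rule applied to
plain missingness.

## Item calibration

Calibration uses marginal maximum likelihood: an EM algorithm integrating
over a latent normal with 49 Gauss–Hermite nodes.  The latent mean and
variance are re-estimated each cycle (the quadrature grid follows them),
so heavily off-target samples are handled without rescaling.  The M-step
takes one safeguarded Newton step per item on the expected-count tables
(analytic gradient and Hessian of the PCM log-likelihood; step length
capped at 2 logits, thresholds clipped to ±12).  Convergence is declared
when the absolute change in marginal log-likelihood falls below 1e−6, with
a 500-iteration cap; non-convergence raises an error carrying the trace.
Categories never observed for an item (structural zeros) produce a warning
and a per-item flag rather than a failure, since the adjacent thresholds
are then only weakly identified.

Standard errors come from the empirical cross-product of per-person
marginal score vectors (Fisher's identity applied to the posterior expected
complete-data scores); the location SE uses the full covariance block of
the item's thresholds.  Uncertainty in the latent-distribution parameters
is not propagated, which makes the item SEs very slightly optimistic.

A pairwise-conditional backend would be an acceptable alternative; the MML
route was chosen because its behaviour under missing-at-random data is
transparent and it needs no pairing heuristics.  Equivalence with the
software used in the original field analyses is claimed only at the level
of recovery and invariance properties, which the test suite measures
directly (location RMSE ≤ 0.1 logits at n = 2000; agreement of
calibrations across ability-split halves within sampling error).

## Person measurement

Person measures solve the score equation by bracketed root-finding on
[−15, 15] logits.  MLE solves r = ΣE_i(θ); WLE adds Warm's penalty,
solving r − ΣE_i(θ) + I′(θ)/(2I(θ)) = 0, where I is the test information
and I′ its derivative (the sum of third central category moments).  The SE
is 1/√I(θ̂) for both.  WLE is the default everywhere downstream because it
is finite at extreme raw scores (flagged, not corrected ad hoc) and less
biased than the MLE, which the suite verifies at test lengths 7 and 18.
Raw-score sufficiency is exploited computationally: rows sharing a
missingness pattern and raw score share a single solve.

## Residuals and fit statistics

Standardized residuals z_ni = (x_ni − E_ni)/√V_ni are evaluated at the
calibrated thresholds and WLE measures.  Because θ̂_n is estimated from the
same responses, E[z²_ni] is deflated by approximately d_ni = 1 − V_ni/I_n
(the item's share of the person's test information); all fit statistics
use this correction so they are centred under the model.

- **Item fit residual.**  U_i = Σ z²_ni is compared with its expectation
  m_i = Σ d_ni and variance v_i = Σ d²_ni (μ₄/V² − 1), then normalized by
  the Wilson–Hilferty cube-root transform with effective df 2m²/v.  Values
  beyond ±2.5 flag misfit.  The sign is carried by the statistic itself:
  over-discriminating items (steeper than the Rasch slope) produce
  residual sums below expectation and hence negative values,
  under-discriminating items positive values — no separate
  observed-vs-expected regression is needed.
- **Item-trait χ².**  Persons are ranked by θ̂ into G = 10 near-equal
  class intervals (ties broken by row order), giving the conventional
  df = 9.  Within each interval the summed observed-minus-expected score
  is standardized by its d-corrected variance and squared; empty intervals
  are merged by omission with df reduced and logged.  When the sample
  exceeds the adjustment size (default n = 500), the statistic is scaled
  by 500/n before the p-value is computed — mitigating the excessive power
  of large samples — while the raw statistic is reported alongside.  The
  adjustment applies to fit assessment only, not to DIF F-tests.  As
  measured in the acceptance suite, the resulting test is conservative
  (type-I rate a few percent rather than exactly 5%): grouped deviations
  with the df = G − 1 convention are under-dispersed.  This is accepted
  rather than recalibrated empirically, since the convention's
  interpretation (and its printed df) is the fixed point.
- **Local dependence.**  Pearson correlations of residual columns over
  pairwise-complete persons (pairs with fewer than 10 joint observations
  excluded and logged).  Two critical values are reported: the absolute
  rule r > 0.30 and the relative rule r > mean(all pairwise r) + 0.30.  On
  independent items the mean pairwise residual correlation is ≈ −1/(L−1),
  so the relative critical value sits below 0.30.
- **Targeting coverage** is defined as the share of person measures inside
  the span of all item thresholds.  The converse reading (share of the
  threshold span covered by persons) is not implemented; the chosen
  definition is translation-invariant and matches the "percentage of
  persons covered" phrasing used in instrument-development reports.
- **PSI** = (var θ̂ − mean se²)/var θ̂, floored at 0, computed from WLE
  measures including extreme-score persons (their WLE is finite); persons
  with zero information are excluded.

## Differential item functioning

For each item and person factor (smoking-status group, age band, sex,
education, assessment object, risk framing), a two-way fixed-effects ANOVA
of z_ni on factor × class interval is fitted with type-II sums of squares
(the quota design is near- but not exactly balanced).  The factor main
effect tests uniform DIF, the interaction non-uniform DIF, each at a
test-wise α = 0.05 (an optional Bonferroni switch exists but is off by
default, matching test-wise reporting practice).  Factor levels with fewer
than 20 persons are dropped with a warning; with fewer than two levels the
item is marked not-evaluable.  A location shift applied to *all* items of
a group is absorbed into the group's person measures and raises no DIF
flags — the test distinguishes item bias from true group differences.

Power, measured in the test suite: a 0.5-logit uniform shift is detected
essentially always at 500 persons per group.  Non-uniform DIF
(discrimination 1.5 vs 1.0) is detected with only moderate power (~0.6 at
1000 per group with ±2-logit threshold spans, less with wider spans):
slope differences are diluted when thresholds are widely spread and the
interaction spreads the signal over G − 1 degrees of freedom.  The
corresponding test therefore asserts clearly-above-type-I detection rather
than a high power figure.

## Item reduction

The reduction loop calibrates, diagnoses, flags (misfit beyond ±2.5,
adjusted-χ² p < 0.05, disordered thresholds, DIF at α, local dependence by
the relative rule), removes the worst flagged items, and recalibrates — at
most 3 iterations or until nothing is flagged.  Auto mode ranks misfit
first (by |fit residual|), then DIF (by F), then local dependence, removes
at most 6 items per pass, and never removes both members of a flagged
dependent pair in the same pass (the surviving twin is re-assessed after
recalibration, where it typically fits).  Interactive mode delegates the
choice to a callback, mirroring judgment-led reduction.  Every removal is
logged with its reasons; the loop refuses to empty a scale.

## Classical test theory

Sum scores use external 1–5 coding and complete-item respondents only — no
imputation or person-mean substitution — with the n used always reported;
observed ranges are therefore narrower than theoretical ones whenever
don't-know rates are nontrivial.  Floor/ceiling are computed on the
theoretical min/max of the administered item set; skewness is the adjusted
Fisher–Pearson standardized third moment; Cronbach's α uses the standard
variance decomposition.  On complete, well-targeted data α and the PSI
agree within 0.05 (verified in the suite).

## Scoring table

For a fixed, completely administered item set, each raw score maps to the
WLE measure solving the Warm-corrected score equation, with SE from the
information at the estimate; the solver's monotonicity is checked and a
violation raises rather than repairs.  The 0–100 map is linear,
s = 50 + 50·θ/Θ with Θ = max(|θ_min|, |θ_max|), clamped to [0, 100]: the
calibration mean (logit 0) maps to 50 and the longer extreme to its bound.
When the extreme measures are asymmetric the shorter tail does not reach
its bound; the table records this (`symmetric` flag) because a single
linear map cannot anchor 0 → 50 *and* both extremes to 0/100 unless the
extremes are symmetric.

## Validity comparisons

Known-group comparisons use the pooled-variance Student t (df = n₁+n₂−2)
with Cohen's d on the pooled SD — the convention that reproduces printed
(n, mean, SD) summary tables exactly, and the reason Welch's test is not
used.  Convergent correlations are Spearman ranks on complete pairs;
disattenuation divides by √(rel_a·rel_b) and warns (rather than truncates)
above 1.  Carry-over compares respondents who assessed an object first
against those who assessed it after others, per object and framing.

## Synthetic survey generator

The generator emulates the field design: four equal smoking-status strata
(current smokers with/without intention to quit, former, never smokers;
410 per stratum by default), five assessment objects in randomized
per-respondent sequences, both risk framings, 18 health items applicable
everywhere and 7 addiction items with the cessation-specific subset
(4 items for cessation, 6 elsewhere; never smokers skip personal-framing
NRT/cessation assessments).  Latent locations are drawn per
respondent-object-framing row from normals whose means combine
object/framing base levels with smoking-group offsets (magnitudes matching
the published group mean tables) and a common SD of 2.9 logits; responses
come from the PCM at the configured item parameters.  Don't-know responses
are MCAR at 12% per item by default (8–15% realistic range; an MNAR mode
raising the rate for never smokers on personal framings is available for
stress-testing), plain missingness at 0.1%.

Item truth: locations default to the published calibrated values;
thresholds are the location plus equally spaced offsets spanning ±3.5
logits.  The span is a convention, not an estimate — it was chosen so the
effective threshold range (≈ −4.5 to +4) and the targeting coverage band
match what a well-targeted instrument of this type exhibits; true
threshold dispersions of the real instrument are unpublished.

The auxiliary VAS is generated in two steps: a true score correlating 0.8
with θ (risk perception measured on a single global scale is a related,
not identical, construct), plus noise calibrated so the VAS reliability is
0.6.  This reproduces both stylized facts at once: observed Spearman
correlations with the scale measure around 0.5–0.7, and disattenuated
values below 1.

What the generator does *not* emulate: within-person correlation across
objects and framings (rows are independent; real respondents are
consistent across objects, which mainly affects analyses the package does
not perform, such as cross-object correlations), recruitment/quota-fill
dynamics, response styles, and MNAR missingness beyond the optional mode.
Passing tests on generator output therefore demonstrates correctness of
the algorithms under the model and design assumptions, not robustness to
real-data pathologies.

Determinism: every stochastic routine takes an explicit seed (default
20140201); identical config + seed yields byte-identical CSV output.

## Problem sizes in the test suite

The suite runs the statistical calibration checks at the sizes that make
their targets meaningful while keeping the battery practical: parameter
recovery at n = 2000 (10 replicates), χ² type-I calibration at the
adjusted n = 500 (200 replicates × 18 items), DIF power at 500/group
(20 replicates), and the full-pipeline closure check on one default-size
survey (1640 respondents, stacked to ~14,000 measurement rows).

## Known limitations

- The χ² item-trait test is conservative at small G·n; its printed-df
  convention is retained deliberately.
- Item SEs omit latent-distribution uncertainty.
- Non-uniform DIF power is modest for widely spread thresholds (above).
- CTT sum-score statistics are complete-case; with 12% don't-know rates
  per item, the complete-case fraction drops quickly with scale length,
  and the reported n should always be checked.
- The 0–100 map anchors 50 at the calibration mean; comparing scaled
  scores across differently calibrated instruments is not meaningful.
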