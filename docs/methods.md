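# Methods

`raschkit` calibrates ordinal questionnaire data with the Rasch family of
item response models and derives the standard battery of psychometric
diagnostics used to evaluate patient-reported outcome instruments:
item fit, reliability and separation, dimensionality of residuals, local
independence, item–person targeting, coverage, gaps, ceiling/floor
effects, threshold ordering, and differential item functioning (DIF).
This note records the model, the estimation and numerical choices, what
the synthetic generator does and does not emulate, and the package's known
limitations.

## Model

For person $n$ with measure $\theta_n$ and item $i$ with difficulty
$\delta_i$ and $m_i$ ordered categories $0,\dots,m_i-1$, the probability
of response $k$ is the Masters partial credit form

$$
P(X_{ni}=k) \;=\; \frac{\exp\sum_{j=1}^{k}(\theta_n-\delta_i-\tau_{g j})}
{\sum_{h=0}^{m_i-1}\exp\sum_{j=1}^{h}(\theta_n-\delta_i-\tau_{g j})},
$$

with the empty sum equal to zero.  The step thresholds
$\tau_{g1},\dots,\tau_{g,m-1}$ belong to the item's *rating-scale group*
$g$: items that share a response format share one threshold vector
(Andrich rating scale model), while an item alone in its group has its own
thresholds (partial credit model).  Mixed instruments — the SGRQ being the
motivating shape, with dichotomous Activity/Impact items next to 4- and
5-category Symptom items — are handled by giving each response format its
own group.  A dichotomous item has a single threshold fixed at 0 and
reduces to the simple logistic Rasch model.

Identification: thresholds sum to zero within each group; item
difficulties are mean-centred within the analysed domain; person measures
are free.  Each domain is calibrated separately on its own logit metric,
the convention for multi-domain profile instruments whose domains are not
assumed to share one trait.

## Estimation

Joint maximum likelihood (JMLE), the method of the Winsteps lineage,
chosen for comparability with the bulk of the published Rasch literature
on health questionnaires.  The algorithm alternates damped Newton updates
of $\theta$, $\delta$ and $\tau$ (diagonal observed information), each step
capped at 1 logit and halved (up to six times, then rejected) if it fails
to increase the joint log-likelihood; $\delta$ is re-centred each sweep and
$\tau$ re-centred with the shift compensated into $\delta$ so step
locations are unchanged.  Iteration stops when the largest parameter
change falls below `tol` (default 0.005 logits) or after `max_iter`
(default 200) sweeps; non-convergence is flagged on the result, and any
parameter passing 30 logits raises a divergence error.  Standard errors
are inverse square roots of the per-parameter observed information.
Missing cells contribute nothing to any likelihood, expectation or
information sum; no imputation anywhere.  Estimation uses no random
numbers.

Starting values come from the classical PROX normal approximation
(log-odds of score proportions with variance expansion).

**Extreme scores.**  Persons and items at their minimum or maximum
possible raw score carry no information about their own parameter and are
removed from iteration (iterated, since removing an item can make a person
extreme).  Extreme persons receive finite extrapolated measures: the
$\theta$ whose expected total score sits `extreme_adjustment` (default 0.3
score points) inside the boundary.  These extrapolated measures are
included in targeting, coverage and ceiling/floor statistics — ceiling
effects are precisely about such respondents — but excluded from
residual-based fit statistics and from reliability.

**Null categories.**  A category with zero observations across a whole
scale group (among the persons entering estimation) has no estimable
threshold; left in place it diverges.  The model squeezes such categories
out — observed categories are renumbered contiguously and the effective
category count reduced — iterating with extreme-score removal to a fixed
point, and records the recode.  This mirrors the "squeeze null categories"
convention of the reference software.  The same recode is applied to
subgroup data during DIF re-estimation.

**Bias.**  JMLE estimates are consistent only as both facets grow; at
fixed test length $L$ the logit metric is inflated by roughly $L/(L-1)$
(about 7 % at $L=20$, visible as a recovery regression slope of ~1.05–1.10
in the validation studies).  An optional $(L-1)/L$ multiplicative
correction of item difficulties exists (`bias_correction`, off by default
for comparability with common practice).

## Diagnostics

* **Standardized residuals** $z_{ni}=(x_{ni}-E_{ni})/\sqrt{W_{ni}}$ with
  $E$ and $W$ the model conditional mean and variance; cells with zero
  variance report a missing residual.
* **Infit** $\sum (x-E)^2 / \sum W$ (information-weighted, dominated by
  persons near the item) and **outfit** (plain mean of $z^2$, sensitive to
  outliers), per item and per person.  Bands: below 0.6 overfit, above 1.4
  misfit (configurable).  Mean squares only; ZSTD standardization is not
  computed.
* **Reliability and separation**: adjusted variance = observed variance of
  the measures minus mean squared SE (floored at 0); $R$ = adjusted over
  observed, $G=\sqrt{R/(1-R)}$.  Bands: $R>0.7$ good; $G$ in 1.5–2.0
  acceptable, above 3.0 excellent.
* **Dimensionality**: principal components of the inter-item correlation
  matrix of standardized residuals (pairwise-complete; items with constant
  residuals dropped with a warning).  Eigenvalues are in item units (they
  sum to the number of items).  The unidimensionality cut on the first
  contrast defaults to 3.0 and is configuration, not a constant: published
  practice accepts first contrasts well above the older 2.0 rule, so the
  package does not hard-code a verdict.  KR-20 (= Cronbach's alpha on 0/1
  data, listwise deletion) supplements the residual PCA for dichotomous
  domains.
* **Local independence**: item pairs with residual correlation $|r|>0.3$
  (configurable), sorted by magnitude.

## Scale-level evaluation

Targeting is mean person measure minus mean item difficulty (zero is
perfect; $|t|<0.5$ good, 0.5–1 slight, $>1$ substantial mis-targeting).
The threshold range spans all step locations $\delta_i+\tau_{gj}$;
coverage is the percentage of persons (extrapolated extremes included)
inside it, with 95 % the adequacy criterion, reported alongside the
2.5th–97.5th percentile person limits.  Gaps are adjacent differences of
item difficulties (the mean of an item's step locations, which equals
$\delta_i$ because thresholds are centred) at or above 1 logit.  Ceiling
and floor are the percentages strictly above the highest / strictly below
the lowest step location, flagged at 15 %; persons exactly on a boundary
count as in range, so floor + coverage + ceiling partition the sample
exactly.  An item is reported as having disordered thresholds when its
group's thresholds are not strictly ascending.  One documented quirk of
the published banding conventions: a targeting index like −0.14 falls in
the "good" band numerically even where a report narrative might call it
slight difficulty; the package follows the numeric bands.

## Differential item functioning

Persons are split by a covariate rule — age below/at-or-above 75, or GOLD
stage {0,I,II} vs {III,IV}; both the age cut and the stage partition are
configurable, as is an arbitrary predicate.  Default anchoring fixes
person measures at their pooled-calibration values and re-estimates item
difficulties within each subgroup with thresholds held at pooled values
(only difficulty moves, since DIF is reported on difficulty).  The anchor
measures are first shrunk by the $(L-1)/L$ JMLE bias factor: anchored on
the raw (inflated) metric, subgroup difficulties inherit the ~7 %
inflation, which would de-calibrate a pure magnitude criterion.  The DIF
contrast is $\hat\delta_A-\hat\delta_B$, flagged when its magnitude
exceeds 0.5 logits — a size criterion, not a significance test, so no
multiple-testing adjustment applies.  Items extreme within a subgroup get
a missing contrast.  An alternative anchoring — two independent
calibrations linked by mean-item equating, matching the
scatter-of-two-calibrations display — is available via
`dif_anchor="equate"`.  Summaries report flagged counts per domain as
"n (pct %)"; exports include scatter coordinates with the identity line
and ±criterion bands.

A practical caution the validation studies quantify: with ~150 persons per
group, per-group difficulty SEs are ~0.2 logits for well-targeted items
and ~0.3 for items 3 logits off target, so the 0.5-logit rule false-flags
a substantial fraction of off-target items from noise alone.  The DIF
power study in the acceptance suite therefore uses a bank targeted within
±1.5 logits of the sample; the magnitude-only rule should be read with
item targeting in mind on real data too.

## Synthetic data

The generator emulates the analysed SGRQ structure: 6 polytomous Symptom
items (four 5-category sharing one format, two 4-category), 16 dichotomous
Activity items spanning a wide difficulty range (−6.4 to 4.5), and 26
Impact items (two 5-category, one reversed 4-category, 23 dichotomous,
−1.9 to 1.75), N = 240 by default with age ~ N(70.4, 7.9²) clipped to
46–88 and GOLD stages drawn with probabilities matching a severe-skewed
COPD outpatient sample.  Which Symptom items carry 4 vs 5 options is an
illustrative assignment.  Person measures default to N(0, 1.5²) plus a
+0.5-logit shift for stages III–IV, so severity-related differences in
trait level exist independently of any injected DIF.  Responses are drawn
cell-by-cell from the model at the true parameters; DIF is injected as a
group-specific difficulty shift at generation time; a second latent trait
with chosen correlation can drive a subset of items.  One seed sequence
with per-component substreams (covariates / traits / responses /
missingness) makes output byte-reproducible and insensitive to added
analysis steps.

What the generator does **not** emulate: response styles, careless or
acquiescent responding, missing-not-at-random patterns, item wording
effects, local dependence from shared item stems, or real COPD symptom
dynamics.  Passing parameter-recovery and null-fit tests therefore shows
the estimator and diagnostics are correct under the model, not that real
SGRQ data satisfy the model.

## Validation study sizes

The acceptance studies (also run by `scripts/acceptance.py`) use: an
8-person × 5-item complete dichotomous matrix checked against exhaustive
0.01-logit grid maximization of the same likelihood (agreement within 0.02
logits); 10 replicates of N=300 persons × 20 dichotomous items with
difficulties on [−3, 3] for recovery (r ≥ 0.98, RMSE ≤ 0.30, slope
0.90–1.15) and null item fit (mean infit 0.9–1.1); 20 replicates of two
~150-person groups with one item shifted +1.0 logit for DIF detection
(≥ 90 % detection, ≤ 10 % null false flags, bank targeted on [−1.5, 1.5]
as discussed above); and 10 paired seeds of N=500 with a 10-item
orthogonal second dimension for the residual-PCA power check.  These sizes
were chosen as the smallest designs at which the expected properties are
comfortably resolved.

## Limitations

Equal discrimination is assumed (no 2PL/3PL); no CML or MML estimation; no
confirmatory factor analysis indices; no uniform/non-uniform DIF
decomposition, logistic-regression DIF, or Mantel–Haenszel cross-check;
no test-information curves or adaptive testing support.  JMLE bias at
short test lengths is documented above rather than corrected by default.
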