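# Methods

## Model

All scales are scored under Samejima's graded response model.  Item *j*
with *m* ordered categories has discrimination *a_j* > 0 and strictly
increasing thresholds *b_{j1} < … < b_{j,m−1}* on the latent trait θ;
boundary curves are logistic, P(X ≥ k | θ) = expit(a_j(θ − b_{jk})), and
category probabilities are adjacent differences.  No 1.7 scaling constant
is used: simulator, calibration and scoring all share the logistic metric,
and every reported quantity (t-scores, crosswalks, reliability) is
invariant to that convention as long as the two sides agree.

The anchor metric is defined by the anchor scale's fixed item parameters,
with t = 50 + 10·θ: mean 50 and SD 10 in the anchor calibration
(reference) population, which is standard normal on θ by construction.

## Calibration

`calibrate` maximizes the marginal likelihood by EM over a fixed
quadrature grid (61 equally spaced nodes on [−6, 6], weights proportional
to the latent normal density and renormalized; oracle computations use
2,001 nodes).  The E-step accumulates expected category counts per item;
the M-step maximizes each free item's expected complete-data
log-likelihood by L-BFGS with analytic gradients on the reparameterized
surface a = exp(α), b_k = b_1 + Σ_{l≤k} exp(γ_l), which enforces threshold
ordering.  Start values are a = 1 and thresholds from inverse-normal
transforms of cumulative category proportions.  Convergence is declared
when the largest absolute parameter change falls below 10⁻⁴ (cap 500
cycles); non-convergence is flagged on the result and propagated as
crosswalk metadata, never silent.

*Identification.*  With no fixed items the latent density is pinned to
N(0, 1).  In fixed-parameter calibration (anchor items held at supplied
values) the latent mean and SD are freed and re-estimated each M-step from
the posterior, so freely estimated target items land on the anchor metric.
A normal density was chosen over an empirical histogram: it is simpler,
identifiable and sufficient for metric transfer at these sample sizes.

*Missing data* are ignored item-wise in every likelihood (MAR treatment);
no imputation.  *Empty categories* of free items are collapsed into the
adjacent category toward the middle of the scale, with the recode map
recorded on the result; a strict mode fails instead.  Collapsing changes
the achievable raw range, so linking warns when it occurs.

## Scoring prior

Summed-score EAP tables (Lord–Wingersky recursion, then Bayes over the
grid) and the pattern-level EAP "actual" scores are computed under the
anchor *reference* density N(0, 1), not the sample density estimated
during calibration.  This makes a crosswalk a function of the item
parameters alone — portable across populations, and invariant when a
subgroup's trait distribution shifts — which is the property the
subgroup-invariance analysis verifies.  The freed sample density is still
what places target parameters on the anchor metric; it is reported in the
crosswalk metadata.  A different scoring prior can be passed explicitly.

## Linking

**IRT route** (`irt_link`): fixed-parameter calibration of the target
items → summed-score EAP table on the target items → t_s = 50 + 10·θ̂_s
with SE 10·se_s → expected anchor raw score r_s from the anchor's test
characteristic curve evaluated at θ̂_s.

**Equipercentile route** (`equipercentile_link`): mid-point
percentile-rank continuization of both raw-score distributions
(Kolen–Brennan), inverse continuized anchor CDF at each target percentile
rank, with zero-frequency scores carried as flat CDF segments whose
inverse is the segment midpoint.  t-scores come from linear interpolation
in the anchor's raw→t table.  Log-linear (polynomial Poisson) presmoothing
is available but off by default, since the degree is a modeling choice the
analyst should own; no SE is attached to equipercentile rows.

**Cut-points** (`closest_cutpoint`): published cut-points are raw-score
rules (≥27 on the 0–54 anchor, ≥10 on the 0–30 anchor) with companion
t-scores.  The equivalence search therefore minimizes distance on the
predicted *anchor raw score* column when the raw cut is supplied — the
rule that reproduces all published equivalencies, including the
depersonalization pair where t-distance alone would select the
neighbouring row — and falls back to t-distance otherwise.  Ties break
toward the lower raw score (favouring sensitivity).  Cross-target
equivalences require both crosswalks to share an anchor metric; comparing
across metrics raises an error.

**Inclusion rule** (`filter_missingness`): respondents with at most one
missing item per scale on every scale are retained; a retained
respondent's raw total with one missing item is prorated as
round-half-up(observed mean × item count).

## Evaluation

**Cross-validation**: folds are stratified on target raw-score quantile
bins (5 by default) to stabilize sparse score levels; the crosswalk is
rebuilt on the training folds only, and pooled held-out predicted t
(crosswalk at the target raw score) is compared with actual t
(pattern-level EAP on the anchor items — the stricter comparator — under
the fixed anchor parameters).  Metrics: Pearson r, mean difference
(predicted − actual) and SD of the difference.  `select_method` declares a
winner only when one method is weakly better on all three metrics for
every item set; otherwise the comparison is reported as indeterminate
rather than forced.

**Assumption screen**: inter-scale Pearson r ≥ 0.75 between (prorated) raw
totals, and essential unidimensionality of the pooled item set as
λ₁/λ₂ ≥ 3 on the polychoric correlation matrix (two-step ML per pair;
a pair whose likelihood fails to optimize falls back to the Pearson
correlation of the codes with a warning, so the eigen decomposition stays
defined).  The eigenvalue screen stands in for a full ordinal
confirmatory factor analysis, which is out of scope; it is reported
descriptively with its thresholds.

**Conditional reliability**: rel(θ) = 1 − 1/I(θ), the unit-population-
variance convention consistent with t-metric reporting, floored at zero;
curves are tabulated on t ∈ [20, 80] in steps of 0.5, with 0.70/0.90 the
conventional group/individual adequacy thresholds.

**Subgroup invariance**: full re-linking within each subgroup and
row-wise comparison of the t columns; flagged when max |Δt| exceeds a
3 t-unit margin.  The margin is a documented package default (roughly the
crosswalk SEs at interior scores), not an established criterion.

## Synthetic data

The generator emulates the single-group design: per item set, a target
driver and an anchor driver drawn bivariate normal with construct
correlation 0.9 by default (the single-item screen shares the exhaustion
construct exactly), two anchor constructs correlated 0.6, GRM responses,
MCAR missingness at 1% (the real survey's rate is not characterized; this
is a labelled guess), and a random binary responder label.  Fixture item
parameters are invented — discriminations in [1, 2.5], thresholds spread
over [−2.5, 2.5] — and deterministic given the seed; they are synthetic
stand-ins, not any published calibration.

These defaults put the multi-item inter-scale raw correlations near
0.75–0.78.  The single-item screen's correlation tops out near 0.70–0.73:
with one 5-category item and discrimination capped at 2.5, its marginal
reliability bounds the attainable raw-score correlation below the ~0.76
observed for real screening items, so the fixture sits at the assumption
screen's 0.75 boundary by construction.  Test knobs exist for invariance
studies: a latent mean shift for one subgroup (which must *not* flag
invariance) and a target-threshold shift (which must).

What passing tests on this fixture do **not** show: robustness to
non-normal trait distributions, informative missingness, multidimensional
content, response styles, or real-item parameter configurations.  The
fixture validates the machinery, not the published crosswalk values,
which derive from confidential survey data and an external anchor
calibration; those printed tables ship as reference data and are tested
as worked examples.

## Problem sizes

Default analysis and test sizes were chosen as the smallest at which the
statistical behavior under test is stable: n = 1,355 for the simulated
survey (the study-scale default), n = 2,000 for free-calibration recovery,
n = 5,000 for fixed-calibration density recovery and cross-validation
ceilings, n = 2,000 per subgroup for invariance runs, 10⁶ only for the
Monte-Carlo EAP oracle (vectorized).

## Known limitations

- Normal latent density only (no empirical-histogram estimation).
- Unidimensional GRM; no 2PL/3PL/nominal models, no DIF analysis.
- Equipercentile SEs are not computed.
- Category collapse changes the raw-score support of a crosswalk rather
  than mapping collapsed scores back to the original codes.
- The polychoric fallback (Pearson on codes) slightly attenuates the
  eigenvalue screen when a pair fails to converge.
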