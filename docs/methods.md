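# Methods

This note documents the models and numerical choices behind `zetacomm`,
what the synthetic-data generator does and does not emulate, and the
design decisions taken where several defensible options existed.

## Incidence as the common currency

Metabarcoding read counts are unreliable abundance proxies for metazoans
(primer bias, body-size effects), so every statistic here operates on
presence/absence. The pipeline converts a MOTU × sample × PCR-replicate
read table into a binary sample × MOTU matrix with a replicate-consistency
rule: presence requires at least `min_reads` reads in at least
`min_replicates` of the 3 PCR replicates. The defaults (3 reads in all 3
replicates) encode a restrictive false-negative-over-false-positive
stance; `min_replicates` is configurable for sensitivity analysis, read
as "in at least k replicates". Control subtraction is global: a single
read of a MOTU in any negative/extraction control removes it from the
whole dataset, which is the conservative reading of blank-based
decontamination. Both operations are idempotent.

Dieback classification applies the field rule — high: ≥ 1 dying tree and
> 60% affected; medium: no dying tree and > 60% affected; low: no dying
tree and ≥ 40% healthy-or-resilient — with precedence high > medium > low.
The source rule does not state that the affected and healthy counts are
complementary, so without precedence a plot could satisfy both the medium
and low clauses; the precedence order makes the rule a partition
(grid-enumerated in the tests) and anything falling through all three
clauses is reported "unclassified" rather than forced into a class.
Deadwood items use the plain cylinder volume π(d/2)²·L for items longer
than 1 m; "very large" trees require dbh strictly above 67.5 cm; canopy
cover is the mean over five 68-point densiometer counts, openness its
complement; basal area sums π(dbh/2)² over living trees per hectare.
Taxonomic consensus keeps a rank only when all candidate paths agree on a
single non-empty name and truncates below the first disagreement; a
species-rank name additionally requires ≥ 0.97 best-match similarity.
Only order/family/genus/species ranks are modelled.

## Richness estimation

All estimators consume incidence frequencies (Q_k = species in exactly k
of R units). Chao2 uses the classical form with the (R−1)/R correction
and the bias-corrected variant when Q₂ = 0; Jackknife1 is S_obs +
Q₁(R−1)/R. Interpolated richness is the exact hypergeometric expectation
over t-unit subsets, computed with log-gamma arithmetic for stability and
verified against exhaustive subset averaging (tolerance 1e-10 in the
tests, achieved at ~1e-14). Extrapolation follows the Chao2-based form
S_obs + Q̂₀[1 − (1 − Q₁/(Q₁+R·Q̂₀))^(t−R)]; when Q̂₀ = 0 the curve is flat,
not an error. Coverage uses the incidence coverage estimator at t = R,
its hypergeometric analogue below R and its geometric extension above.
Confidence bands are a bootstrap over sampling units (200 resamples by
default) with a symmetric normal interval; this is approximate and
documented as such — the asymptotic variance formulas are deliberately
out of scope. Reported percentages (temporal core, district overlap)
round half-up to match integer/1-decimal reporting conventions.

## Zeta diversity

The exact ζ_i = Σ_s C(n_s, i)/C(N, i) is the expectation of the
shared-species count over all i-subsets, computed via log-gamma ratios.
The Monte-Carlo path enumerates exactly whenever C(N, i) ≤ `sam`
(default 5000) and otherwise averages over `sam` uniform i-subsets,
drawn without replacement within a subset and independently across draws.
The nearest-neighbour (NN) scheme builds one combination per focal site —
the site plus its i−1 nearest neighbours by planar Euclidean distance,
ties broken by site order — which is the standard construction for
geographically structured surveys; coordinates are treated as planar
because the districts sit ~100 km apart and great-circle corrections add
nothing at that scale.

Decline regressions fit log ζ_i by OLS on i (exponential) or log i
(power-law), by convention from order 2 upward, truncating at the first
zero ζ (zeros are never log-transformed). AIC uses the Gaussian
log-likelihood linear-model convention n·log(2π) + n·log(RSS/n) + n +
2(p+1) with p = 2, so the two forms are compared consistently; absolute
AIC values are convention-dependent and not comparable across software.
An RSS at float-rounding level (≤ 1e-12) is reported as a perfect fit
with a −∞ sentinel, and identical AICs are reported as a tie rather than
silently broken. Group retention curves restrict the matrix to a plot
category and a MOTU group while keeping zero-richness plots, so a group's
curve is comparable to the whole-community mean curve of the same plots.

## Multi-site generalized dissimilarity model

The response of an i-site combination is its Sørensen-equivalent zeta:
shared-species count divided by the mean single-site richness of the
combination, bounded in [0, 1]; combinations whose sites are all empty
are dropped and counted. Each environmental predictor is the mean of
pairwise absolute differences of the min-max-rescaled variable over the
combination's sites; geographic distance is the mean pairwise Euclidean
distance rescaled over the sampled rows. Rescaling happens per round,
over the sampled design.

The monotone basis is an I-spline family (integrated M-splines), built as
reverse cumulative sums of a clamped B-spline design matrix: order 2 with
one interior knot at 0.5 gives three basis functions per variable, each
non-decreasing with I(0) = 0 and I(1) = 1. The model is

    response = a₀ − Σ_v Σ_j c_{vj} I_j(x_v),   c_{vj} ≥ 0,

solved by bounded least squares (free intercept), i.e. a Gaussian fit on
the similarity scale in which every variable's contribution to
*dissimilarity* is monotone non-decreasing. Non-negativity via bounds
rather than penalties keeps the fit exactly nested (adding a predictor
never increases RSS, which the tests assert). A variable's amplitude is
its fitted curve at the full rescaled range, Σ_j c_{vj}; amplitudes rank
drivers. Averaging over rounds (default 30) refits on independent
seeded combination samples and averages curves and amplitudes; in the
exact-enumeration regime the spread is identically zero.

Variance partitioning fits the full, environment-only and distance-only
models: environment-only fraction = r²_F − r²_D, distance-only =
r²_F − r²_E, shared = r²_E + r²_D − r²_F, unexplained = 1 − r²_F. The
four fractions sum to 1 by construction; a slightly negative shared
component (possible with constrained nested fits) is clipped to zero,
flagged, and absorbed into the larger unique fraction so the identity
holds to 1e-9.

## Community statistics

Richness GLMs are log-link Poisson fits (IRLS via statsmodels) with the
quasi-Poisson dispersion estimated as Pearson χ²/df. Type-II tests drop
one factor at a time from the additive model and refer the
dispersion-scaled deviance difference to an F distribution on
(Δdf, df_resid); a deviance difference at rounding level (including the
degenerate perfectly-fitting case) is reported as F = 0, p = 1. The
calibration test simulates 1000 null datasets with overdispersed
(negative-binomial) richness and checks the 5% level within binomial
Monte-Carlo tolerance.

IndVal uses the group-size-equalized specificity (the "IndVal.g" flavour)
because the dieback classes are unbalanced (18/15/23-style);
A_k = m̄_k / Σ_k' m̄_k' with m̄_k the mean incidence in class k, B_k the
occupancy fraction of class k, statistic √(A·B) maximized over classes.
Plain (non-equalized) weighting is available via a flag. p-values come
from permuting plot labels, p = (1 + #{perm ≥ obs})/(1 + n_perm) with
n_perm = 999 by default, Holm-corrected across species within a run, and
10 independently seeded runs are reported as a p range. Note the
resolution constraint inherent to this construction: with 999
permutations the smallest attainable p is ~0.001, so Holm significance
at 5% is only reachable when at most ~50 species are tested — recovery
fixtures are sized accordingly.

Rarity scores bootstrap the plot set with replacement (100 draws of the
full plot list, global rather than stratified; a `stratified` flag gives
the per-category alternative). A MOTU's score in a category is its
occurrence frequency among the *drawn* plots of that category — dividing
by the realized draw count rather than its expectation, so that a MOTU in
every plot of a category scores exactly 100/3 under the three-way
rescaling (each dieback class depicting one third of the dataset) and
exactly 100 in total when present everywhere; district scores skip the
rescaling.

## The synthetic generator

`generate_dataset` emulates the *shape* of a two-district Malaise-trap
survey: 56 one-ha plots split 28/28 across districts whose centres sit
~100 km apart (planar km coordinates, 4 km within-district scatter);
4 monthly samples per plot with 2 lost (222 field samples); dieback
classes mixed 18 low / 15 medium / 23 high with survey counts generated
to satisfy the classification rule exactly; low-dieback plots are
"healthy" stands, the rest split disturbed/salvaged. Eight environmental
covariates load weakly on the dieback axis with independent noise so all
pairwise correlations stay well below the 0.7 collinearity bar (asserted
per seed); altitude is district-based and independent of the stand
covariates. Species occupancy follows a log-series (θ = 0.95) by
default — many singletons, few ubiquitous species — with geometric and
uniform alternatives; district pools share a configurable fraction
(default 0.45, echoing the survey's ~45% shared fauna). With
`niche_strength` > 0, presence probability is an un-normalized Gaussian
in a designated covariate, re-scaled to preserve each species' expected
occupancy. Phenology is a contiguous activity window of 1–4 months,
skewed short. Reads per present MOTU and replicate are gamma-mixed
Poisson (shape 1.5, mean 60) with 10% independent per-replicate dropout,
so the 3×3 filter has realistic inconsistency to act on; controls are
empty unless `contamination_rate` > 0. All draws flow from one
`numpy` Generator seeded by the config, and the planted truth (per-plot
presence, pools, optima, contaminants) is returned for recovery tests.

`generate_niche_incidence` is the model-selection fixture: plots on a
1-D gradient, Gaussian responses whose widths are lognormally dispersed
(σ = 2) around the `niche_breadth` median and whose heights are U(0, 1).
The width dispersion matters: it mixes narrow specialists with broad
generalists, giving the heavy-tailed occupancy distribution under which
the shared-species decline is a power law; a single fixed width produces
a geometric cut-off that masquerades as exponential decay. The
driver-recovery fixture plants turnover on altitude (niche strength 1.0,
geometric occupancy, 300 species): altitude is generated independently of
the dieback-loaded covariates, so the experiment tests driver *ranking*
rather than the model's behaviour under confounded predictors — with a
canopy-openness driver, correlated stand covariates absorb part of the
signal at high orders, which is an honest property of observational
dissimilarity modelling, not a defect of the fit.

What the generator does **not** emulate: sequences, chimeras, tag
jumping, clustering error (the synthetic world begins at the MOTU table);
abundance structure beyond presence; temporal autocorrelation between
months beyond the activity window; spatial autocorrelation within
districts beyond niche structure. Passing tests therefore demonstrate
that the statistics recover structure *of the kinds planted here*, not
that they are robust to every artefact of real sequencing data.

## Problem sizes

The test suite and the acceptance script run the chain at desk scale,
chosen as the package's own defaults: 300-species communities (the
motivating survey held ~3000 MOTUs), 500–5000 sampled combinations and
5 msgdm rounds where the method's field defaults are 5000 and 30 (the
averaging spread shrinks with both, which a test verifies), 999
permutations, 100–1000 simulation replicates. Oracle comparisons
(exhaustive enumeration) are restricted to ≤ 10 units where the subset
count is small.

## Known limitations

- Rarefaction bands are bootstrap-normal, not the analytic variance.
- The msgdm response family is Gaussian on the similarity scale; a
  logit-link variant would respect the [0, 1] bounds more strictly and
  is a natural extension.
- NN combinations are deterministic given coordinates; with heavy ties
  (gridded designs) the index tie-break imposes an arbitrary order.
- The IndVal permutation floor (1/(1+n_perm)) bounds achievable Holm
  significance; raise `n_perm` for large species sets.
- Exact zeta uses log-gamma arithmetic; beyond ~10⁴ units the C(N, i)
  ratios underflow for mid-range orders and the MC path should be used.
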