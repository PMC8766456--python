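# zetacomm

Community-turnover statistics for DNA-metabarcoding incidence data, built
around the analysis chain of Malaise-trap insect surveys across
environmental gradients (e.g. drought-induced forest dieback): from raw
MOTU × PCR-replicate read tables to richness estimates, zeta-diversity
decline, environmental-driver models and indicator/rarity analyses — with
a seeded synthetic-data generator so every stage is testable without any
sequencing data.

## Who it is for

Ecologists analysing presence/absence community matrices from
metabarcoding (or any multi-site incidence survey) who need the
multi-site turnover toolkit — zeta diversity, multi-site generalized
dissimilarity modelling, incidence-based richness estimation — as a
single tested Python library.

## What it computes

**MOTU cleaning** (`zetacomm.pipeline`). A MOTU is retained in a sample
only with ≥ 3 reads in each of its 3 PCR replicates (configurable); any
MOTU with a single read in a negative or extraction control is discarded
everywhere. Taxonomy is resolved to the unambiguous consensus of
candidate paths (a species name requires ≥ 97% similarity), MOTUs sharing
a species name are merged, and samples collapse to plots/months/districts
by logical OR. Field-survey helpers derive dieback class, canopy
openness and stand-structure covariates.

**Richness** (`zetacomm.richness`). With Q_k the number of species found
in exactly k of R units, U = Σ k·Q_k:

- Chao2: S_obs + ((R−1)/R)·Q₁²/(2Q₂) (bias-corrected when Q₂ = 0)
- Jackknife1: S_obs + Q₁·(R−1)/R
- Rarefaction S(t) = S_obs − Σ_s C(R−Y_s, t)/C(R, t), Chao-style
  extrapolation beyond R, and incidence sample coverage
  Ĉ = 1 − (Q₁/U)·[(R−1)Q₁/((R−1)Q₁+2Q₂)]

**Zeta diversity** (`zetacomm.zeta`). ζ_i, the expected number of species
shared by i sites, computed exactly (ζ_i = Σ_s C(n_s, i)/C(N, i)) or by
Monte-Carlo over ALL subsets / nearest-neighbour (NN) combinations.
Declines are fitted on the log scale to exponential (log ζ_i ~ i) and
power-law (log ζ_i ~ log i) regressions and compared by AIC: a power-law
decline — retention ζ_{i+1}/ζ_i rising with i — indicates niche-driven
turnover with persistent generalists, an exponential decline indicates
stochastic assembly.

**Multi-site GDM** (`zetacomm.msgdm`). The Sørensen-equivalent zeta of
each site combination (shared species ÷ mean single-site richness) is
regressed on monotone I-spline transforms of mean pairwise environmental
differences and geographic distance, with non-negative coefficients and
30-round averaging; explained variance is partitioned into
environment-only, distance-only, shared and unexplained fractions.

**Community statistics** (`zetacomm.stats`). Additive quasi-Poisson GLMs
of plot richness with type-II dispersion-scaled tests; group-size-equalized
IndVal √(A·B) with permutation p-values, Holm correction and a p-range
over 10 independent runs; and category-rescaled bootstrap rarity scores
(an omnipresent MOTU scores 100/3 per dieback category, 100 in total).

**Synthetic data** (`zetacomm.simulate`). A generator shaped like the
motivating survey — 56 one-ha plots in 2 districts, 4 monthly Malaise-trap
samples (2 lost → 222), triplicate PCRs with gamma-Poisson reads and
dropout, long-tailed occupancy, district species pools, optional Gaussian
niche structuring along a covariate — returning the planted truth for
recovery tests.

## Worked example

`examples/zeta_decline.py` contrasts a niche-assembled community with a
stochastic one (56 plots, 300 species each):

```
niche-assembled community:
  zeta_2..zeta_6: [24.78 15.92 11.55  8.9   7.1 ]
  retention rates: [0.64 0.73 0.77 0.8  0.82]
  AIC exponential   -11.70 | power-law   -22.60 -> power-law selected
stochastic community:
  zeta_2..zeta_6: [27.49  8.33  2.53  0.77  0.23]
  retention rates: [0.3  0.3  0.3  0.3  0.31]
  AIC exponential   -71.09 | power-law    52.04 -> exponential selected
```

Both communities share ~25 species between random plot pairs, but they
decay differently: the niche community's retention rate climbs from 0.64
toward 1 — species shared by many plots are ever more likely to be shared
by one more — selecting the power law, while the Bernoulli community
retains species at a constant 0.3 (its occupancy probability), the
exponential signature. The other scripts in `examples/` walk through
filtering (`simulate_and_filter.py`), richness estimation
(`richness_estimation.py`), environmental-driver ranking
(`msgdm_drivers.py`) and indicator/rarity analyses
(`indicators_and_rarity.py`).

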