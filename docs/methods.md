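# Methods

## Outcome definition and coverage estimation

A child's immunization status is reduced to four course-completion
indicators — BCG (1 dose), DTP (3 doses), OPV (3 doses), MCV (1 dose) — and
their conjunction, the full-immunization indicator. Any missing dose of a
course leaves that course incomplete; any incomplete course leaves the
child not fully immunized. Children with a missing dose indicator are
excluded (with a logged count) rather than imputed: the analysis targets
the complete-information subset, and in DHS-style data that subset is
typically ~98% of children. Card-verified and recall-based reports are
treated identically for estimation; the `source` flag is carried through
for reporting only.

All coverage estimates are Hájek ratios `Σ w_i y_i / Σ w_i`, so they are
invariant to rescaling the weights; groups are countries (national) or
(country, region) pairs (subnational). The age restriction is a closed
interval in months, default [15, 35] (allowing catch-up after the MCV dose
scheduled at 9–13 months), with [24, 35] exposed as a sensitivity window.

## Concentration indices

Wealth enters only through its ordering. The weighted fractional rank of
child *i* is the cumulative normalized weight of strictly poorer children
plus half the child's own normalized weight; tied wealth values all receive
the midpoint rank of their tied block, which makes the rank (and every
downstream index) invariant to record order. With this midpoint rule the
covariance form of the concentration index,

    C = (2/μ) cov_w(h, r),

is algebraically identical to twice the signed area between the 45° line
and the concentration curve; the test suite verifies the two routes agree
to 1e−8 on random weighted instances with ties.

For a binary outcome, C is confined to [μ−1, 1−μ]. The two standard
corrections are reported together: Wagstaff `W = C/(1−μ)` and Erreygers
`E = 4μC`, linked by `E = 4μ(1−μ)W`. E satisfies the mirror property
exactly (recoding h to 1−h negates it); W in this binary form does too,
while raw C does not (it picks up a factor μ/(1−μ)), which is one reason
raw C is not the headline statistic.

When a group's outcome is degenerate (μ ∈ {0, 1}) the bounds collapse to a
point and no index value is meaningful; the operations raise, and the
pipeline records the group as degenerate (NaN index columns) rather than
imputing 0.

### Inference

Standard errors come from the convenient-regression formulation: weighted
least squares of a rescaled outcome on the fractional rank has the target
index as its slope (y = 2σ_r² h/(μ(1−μ)) for W; y = 8σ_r² h for E). The
variance is a cluster-robust sandwich by PSU with the Stata-style
small-sample factor G/(G−1)·(N−1)/(N−k), matching the default family of
the Stata `conindex` implementation this design follows; a
heteroskedasticity-robust (HC1) fallback runs, with a warning, when only
one PSU is present, and a non-clustered option is exposed
(`cluster=False`). 95% bounds are estimate ± 1.96·SE. Point estimates are
taken from the covariance formulas (identical to the regression slopes in
exact arithmetic); the regression is used for variance only. The sandwich
is verified against statsmodels' WLS cluster-robust covariance in the test
suite, and its calibration is checked by simulation: under a null wealth
gradient (n = 2,000 children, 80 PSUs), the 95% interval for W covers zero
in 93–97% of 1,000 replicates.

The ranks are treated as fixed in the variance (standard practice for
these indices); uncertainty from rank estimation is ignored.

## Theil decomposition

Dispersion of subnational estimates is summarized by the Theil-T index
(generalized entropy with α = 1), `T = Σ s_i (x_i/μ) ln(x_i/μ)` with the
convention 0·ln 0 = 0, decomposed exactly into within- and between-country
parts. The default is unweighted across subnational units — each
administrative region counts equally, reflecting the reading that the
subnational estimates themselves are the analysis units — with a
sample-size-weighted option exposed for sensitivity. GE(1) is defined for
nonnegative values with a positive mean, so Theil rows for the W and E
indices (which can legitimately be negative) are computed over the
positive-valued units only; the output's `n_used` column makes the
exclusion visible. Scale invariance and the exact additivity
`total = within + between` (to 1e−12) are property-tested.

## Spatial clustering

Queen contiguity is computed from the polygon layer with shapely: two
regions are neighbors iff their boundaries share at least one point (edge
or vertex — "common border" is read as the formal queen rule). Adjacency
is evaluated across the whole pooled layer, so regions of different
countries that touch are neighbors; a per-country mode is available
because multi-country layers can also be analyzed separately.

Gi* uses binary weights with self-inclusion, in the standardized Ord–Getis
form; p-values use the two-sided normal approximation (no conditional
permutation). Two degenerate cases get explicit conventions:

- constant field (zero global variance): all z = 0, p = 1, with a warning;
- a neighborhood that spans the entire layer (e.g., the center of a 3×3
  lattice under queen contiguity): the numerator and the variance term
  n·W_i − W_i² are *identically* zero — the statistic carries no
  information — so z is defined as 0. Isolated regions (no neighbors) get
  missing z/p and the `isolated` label.

Because the many local tests are dependent, hot/cold labels are assigned
only where the Benjamini–Hochberg adjusted q-value is ≤ α (default 0.05);
BH is the step-up procedure as implemented in statsmodels. On synthetic
10×10 lattices with a planted 2×2 high-uptake block (+2.5 logits), at
least 3 of the 4 planted regions are labeled hot in ≥ 90% of replicates.

Bivariate coverage-by-inequality classes cut both statistics at their
empirical terciles (ties to the lower tercile, so a constant field lands
in the lowest class); the low-coverage/high-inequality corner is flagged
as the double-disadvantage class.

## Missed-vaccine sets

The 16 subsets of {BCG, DTP, OPV, MCV} partition the sample: a vaccine is
in a child's missed set iff its course is incomplete, counting once per
vaccine regardless of how many doses are missing (a dose-level view exists
via the dose columns but the vaccine-level rule is primary). The empty set
is exactly the fully immunized children, so shares sum to one and the
empty-set share equals FIC — both are asserted in tests. Scaling shares to
population counts multiplies by a user-supplied table of children in the
age band per country and assumes coverage is unchanged since the survey
year; no population data is fetched.

## Synthetic-data generator

The generator emulates the features the estimators rely on:

- **Design**: regions × PSUs × children, with per-PSU lognormal
  selection-probability multipliers inverted into weights and normalized
  to mean 1 per country (DHS weights are relative). This is a stand-in for
  a true PPS design, not a DHS weight emulator.
- **Wealth**: PSU-level normal mean (SD `wealth_sd_between_psu`, default
  0.5) plus child-level standard normal noise; only the within-country
  weighted rank enters the outcome model, mirroring the relative
  semantics of asset-index scores.
- **Uptake**: per-dose Bernoulli on a logit linear in (dose intercept +
  region effect + β·(rank − ½)), with doses 2 and 3 of DTP/OPV conditional
  on the previous dose, so sequential dropout makes the course-ending
  doses and MCV the most-missed vaccines — the qualitative pattern seen in
  survey data. Default intercepts (2.2, 2.2, 2.4, 2.2, 2.2, 2.4, 2.0, 1.0
  logits) put BCG near 90% and FIC near 35–40% at the median rank; the
  default β = 1.5 (odds ratio ≈ 4.5 richest vs poorest) produces a
  realistic pro-rich gradient.
- **Spatial structure**: region effects follow a SAR field
  `e = (I − ρA)⁻¹ε` on the row-standardized rook adjacency of the region
  lattice (ρ = `spatial_rho`, default 0.6; ε ~ N(0, 0.5²)); optional
  planted hot/cold square blocks at opposite lattice corners add fixed
  logit shifts. Countries sit on separate lattices with a one-unit gap so
  planted clusters cannot merge across borders (cross-border contiguity
  remains supported by the spatial module whenever polygons touch).
- **Ground truth**: region coverage is the exact expectation of the
  full-course probability over rank u ~ U(0,1), by 32-node Gauss–Legendre
  quadrature — not a plug-in at the mean rank — so the recovery invariant
  (weighted region FIC within 0.03 of truth at ≥ 2,000 children/region)
  holds without linearization error.

What it does **not** emulate: recall misclassification, household
non-response, stratified urban/rural sampling, country-specific schedule
timing, or realistic polygon geometry. Passing tests therefore demonstrate
estimator correctness and calibration under a known data-generating
process, not robustness to those real-data complications.

## Problem sizes and determinism

Simulation-based checks use the sizes at which their properties were
designed to hold: 1,000 replicates of n = 2,000 for CI calibration, 50
replicates of a 10×10 lattice (48 children/region) for cluster recovery,
100 replicates of n = 5,000 for gradient detection, 50,000 children for
the null-gradient magnitude check, and a 4-country × 25-region survey for
the end-to-end run. All randomness flows through a single
`numpy.random.default_rng(seed)` per generated survey; identical configs
give byte-identical CSV output, hashed into the run manifest.

## Known limitations

- The normal approximation for Gi* is anti-conservative on very small
  layers; no permutation option is provided.
- Rank-estimation uncertainty is ignored in index SEs (as in standard
  implementations).
- The Theil decomposition treats subnational estimates as error-free
  inputs; sampling noise in small regions inflates the within component.
- Population scaling propagates no uncertainty.
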