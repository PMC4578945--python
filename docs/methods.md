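# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Dissimilarity decomposition

All pairwise statistics derive from the quantitative A/B/C components
(A = Σ min, B and C the two surpluses).  The percentage difference
d = (B+C)/(2A+B+C) is computed in closed form from one city-block distance
matrix and the row totals — B + C = Σ|y1 − y2|, |B − C| = |T1 − T2|,
2A + B + C = T1 + T2 — so the additive identity
d = replacement + difference holds to machine precision for every pair, and
a 546-observation table decomposes in well under a second.

Conventions for degenerate pairs: two all-zero observations are treated as
identical (d = 0); a pair with exactly one empty observation has d = 1,
assigned entirely to the abundance-difference component (there is nothing
to replace).  This keeps the decomposition continuous as an observation's
total quantity approaches zero.

d itself is not Euclidean-embeddable, but √d is.  Ordinations and the
multivariate test statistics therefore operate on √d: principal coordinates
are obtained by eigen-decomposition of the Gower-centered matrix of
−½·(√d)² = −½·d, axes with eigenvalues below 10⁻¹² of the leading one are
dropped, and a warning is raised if any eigenvalue is more negative than
10⁻⁸ of the leading one (expected when ordinating the raw d or the
component matrices, which are emitted as-is, without any re-embedding
transformation).

## SS_total, BD_total, LCBD

SS_total = (1/N)·Σ_{i<j} d_ij uses the raw d values because they are the
*squares* of the embedded distances; BD_total = SS_total/(N−1) is then the
total community variance, bounded by 0.5 for the percentage difference
(the bound is attained by mutually disjoint observations).  LCBD values are
the diagonal of the Gower-centered −½·d matrix divided by SS_total; the
trace identity (diagonal sum = SS_total) is asserted on every fit.
Significance is assessed by permuting each species column independently
across observations — the null of no observation-level uniqueness with
species-level abundance distributions preserved — with
p = (exceedances + 1)/(n_perm + 1).

## Stratified summaries

Stratifying by site yields the temporal response (within-site pairs differ
in time); by time step, the spatial response.  Two reporting scales are
computed, because both appear in practice and they answer slightly
different questions: mean-pairwise triplets (similarity, replacement,
difference), which sum to one and live in a ternary triangle; and the
BD/variance scale SS_comp/(n_g − 1), on which replacement + difference =
total exactly and component *fractions* are defined.  The 95 % CIs on mean
triplets use t quantiles over pair values; pairs sharing an observation are
not independent, so these are labelled descriptive, not inferential.

## Trajectory models

Three candidate mean structures for a univariate response over time:
linear; quadratic on orthonormal polynomial contrasts (QR of the centered
Vandermonde matrix — the vertex time is reported from the equivalent
raw-basis fit when the parabola is concave); and the two-asymptote logistic
step Y(t) = Y_b + (Y_a − Y_b)/(1 + e^{(T−t)/σ}), fitted by
Levenberg–Marquardt-style bounded least squares.  Start values: Y_b from
the mean of the first three time points, Y_a from the last three, T at the
median time, σ = range/10 with σ ∈ (10⁻³, range].  These are robust on
collapse-shaped data; non-convergence is reported as a flag, never an
exception.  AIC is computed from the Gaussian log-likelihood with the error
variance counted as a parameter, identically across the linear and
nonlinear families, so the values are comparable; the quadratic-vs-linear
comparison is additionally reported as a nested F test at α = 0.05.

The island-wide stepwise regression (time, time², site, time:site,
time²:site, season) is bidirectional on AIC and respects marginality: an
interaction may enter only when its main effects are present and blocks
their removal.  The report uses sequential (type-I) sums of squares in the
canonical term order, justified by the balanced survey design, with F
against the final model's residual mean square.  Note that AIC stepwise is
not a test: on pure noise it retains a small spurious term in a sizeable
fraction of runs (a 1-df term enters whenever its F exceeds ≈ 2).  The unit
tests characterize exactly this behavior.

## Space–time inference

The two-way crossed multivariate ANOVA runs on the PCoA coordinates of √d
(so the partitioned variance is the dissimilarity variance).  For the
balanced site × time design the total SS partitions orthogonally into
site, time, interaction and residual; pseudo-F uses the full-model residual
mean square.  P-values come from reduced-model residual permutation: each
main effect is tested by permuting the residuals of the model that excludes
it, the interaction by permuting the residuals of the main-effects model.
Species-level RDA (scores, per-species shares of the shift R²) runs on the
√-biomass matrix directly, where axes are species; with a two-level factor
the single canonical axis makes each species' score proportional to its
centroid difference, signed positive when the species is higher after the
shift.

## MRT and chronological clustering

The multivariate regression tree grows by greedy binary splits minimizing
within-node SS.  Ordered predictors split at value boundaries; categorical
predictors with ≤ 15 levels are searched exhaustively over binary level
partitions (≤ 2¹⁴ candidate partitions, evaluated from level centroids);
above 15 levels the levels are ordered by their centroid projection on the
first principal axis and treated as ordered, flagged as heuristic in the
output.  Each accepted split is tested by permuting the node's response
rows and recomputing the best attainable split R² (α = 0.05, 999
permutations by default); growth stops at `max_leaves` or the first
non-significant split.  This permutation criterion replaces the
cross-validated relative error rule of the classical MRT software: it is
deterministic given a seed and directly interpretable as a test of the
division, at the cost of not optimizing predictive error.  Chronological
clustering is the tree restricted to time with a single split: the best of
the n_distinct − 1 temporally contiguous boundaries, whose R² equals (and
is tested as) the RDA R² of the induced pre/post factor.

## Indicator species and selection

IndVal_sg = A_sg·B_sg with specificity A (share of the species' mean
abundance in group g) and fidelity B (its occurrence fraction in g);
the species value is the maximum over groups, tested by joint label
permutation.  IndVal is computed on untransformed biomass (specificity is
scale-free per species; the √ transform would only reweight observations
within groups).  "Sequential Bonferroni" is implemented as Holm's
step-down.  A practical granularity constraint follows: with m species
tested jointly, any Holm-significant species needs raw p ≤ α/m, so the
permutation count must satisfy n_perm + 1 > m/α — with 227 species and
α = 0.05 the default is n_perm = 4999.  Species selection intersects
Holm-significance with an occurrence-frequency floor (default 0.1 %,
excluding vanishingly rare species whose indicator status is an artifact of
a handful of records) and ranks by |RDA score|; per-species shares of the
shift R² are reported per site along with their mean across sites, since
no single canonical aggregation exists across per-site models.

## Synthetic survey generator

The generator emulates a two-block coastal monitoring design: 9 "NE" and 4
"W" sites, 14 surveys (twice-yearly 2004.0–2009.0, wet season at year + 0.0
and dry at year + 0.5, then annual 2010–2012), 3 replicate transects, 227
species.  (The twice-yearly window ends at the 2009 wet season; that is
what makes the count 14 and N = 546.)  Habitat: per-site logistic cover
collapse with Y_b ~ U(32, 59) %, Y_a ~ U(1, 7) %, T ~ U(2007, 2009),
σ ~ U(0.3, 0.8) y, observed as a binomial 50-point count per transect.

Community structure: a lognormal species-abundance distribution
(σ = 1.2 on the log scale, putting the top species near 8 % of total
biomass, the dominance level typical of species-rich reef fish
communities), per-site lognormal jitter (σ = 0.25), per-species occupancy
U(0.3, 0.95) with a 20-species rare tail (U(0.01, 0.08)), site baseline
totals U(125, 358) g·m⁻², and a small additive dry-season bump (3 % of
baseline).  Observed biomass = expected × lognormal noise (σ = 0.6) zeroed
with one minus occupancy — multiplicative, right-skewed noise is what
motivates the √ transform in the analysis.

Each block has 7 driver species (disjoint between blocks — the spatial
heterogeneity of the response): two large decreasers (10 % and 8 % of site
baseline biomass) that collapse to a 5 % floor through a block-level shift
gate (logistic in time; NE centered at 2007.25, W at 2009.5, σ = 0.15 y,
placed between sampling dates so the programmed pre/post boundary is
unambiguous), and five smaller increasers (1.5 % down to 0.5 %) with
occupancy 0.98.  Under the *compensatory* regime the increasers absorb
exactly the occupancy-weighted expected loss of the decreasers (a ≈ 4.4×
gain), so each site's expected total biomass is constant over time while
composition turns over; under the *synchronous* regime every species'
expected biomass is instead multiplied by the site's relative habitat
trajectory cover(t)/Y_b; the *null* regime has no temporal structure.  All
randomness flows from one seed through named habitat / structure / noise
streams.

Regime signatures are evaluated on untransformed biomass, the scale on
which the regimes are defined (the √ transform deliberately compresses
total-biomass differences and so dilutes the synchronous signature).

**What the generator does not emulate** — and hence what passing tests do
not establish about field data: species interactions and temporal
autocorrelation beyond the programmed trend (noise is i.i.d. across
observations), observer and detectability error structure, recruitment
pulses, within-transect spatial structure, and gradual multi-species
responses (all non-driver species are strictly stationary).  Recovery rates
measured here are for the programmed, well-separated effects; they are
upper bounds on what equally sized field effects would yield.

## Problem sizes used in the checks

The acceptance-style checks run the full 546 × 227 design where the claim
is about the survey scale (regime signatures, boundary recovery over 100
draws, driver recovery at n_perm = 4999) and small randomized instances
where the claim is algebraic or distributional (1,000 random pairs for
additivity, 50 tables for the embedding, 10,000 for the BD bound, 200
simulations for the calibration envelopes and the logistic recovery).
`scripts/acceptance.py` reports boundary recovery over 50 draws.

## Known limitations

* The crossed ANOVA requires a balanced design; unbalanced data must be
  aggregated to cell means first.
* CIs on stratified triplets are descriptive (pair dependence).
* The categorical-split heuristic above 15 levels is not exhaustive.
* Permutation p-values are bounded below by 1/(n_perm + 1); joint Holm
  significance over many species requires correspondingly many
  permutations.
* The stepwise report's sequential SS depends on the canonical term order;
  with the balanced design the main-effect blocks are orthogonal, but
  interaction terms are attributed in order.
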