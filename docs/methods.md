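# Methods

## Study design and the synthetic-data generator

The pipeline targets a nested cytotoxicity design: 4 donors × 2 clonal
ECFC lines per donor, 8 chemicals arranged as 4 toxic/nontoxic pairs, 9
two-fold serial-dilution titers per chemical in duplicate wells, 32
untreated control wells per clone per 384-well plate, and 3 independent
experiment days. The generator (`ecfctox.design`) reproduces this layout
exactly (4,224 wells per study) and emulates the data-generating process
as follows.

**Ground truth.** Each chemical's true concentration-effect curve is a
Hill decline parameterized on the transformed scale t = log₂(1 + μM):
viability(conc) = 100 / (1 + (conc / (2^(m+δ) − 1))^h), where m is the
true log₂(1 + IC50) location, h > 0 the Hill slope, and δ the summed
random-effect shift. Toxic chemicals have locations and slopes chosen to
land in realistic ranges (TBT ~1.7 μM IC50 with a shallow slope,
arsenite ~7 μM, cadmium ~15 μM, menadione ~17 μM with a steep slope
h = 5.5, so its IC10 sits close to its IC50). Nontoxic counterparts share
overlapping dilution ranges but have m placed far enough above the top
titer that true viability stays above ~99% everywhere tested; for
shallow-sloped chemicals this requires more than the minimal two t-units
of separation, since the margin needed for "no 10% loss in range" scales
like 9^(1/h) in concentration.

**Random effects.** Donor, clone and day effects shift m additively on
the t scale (a shift of 1 ≈ a two-fold change in 1 + IC50), drawn once
per unit: δ = donor + clone + day(clone, day). Day shifts are independent
per clone × day, so they appear downstream as within-clone variability.
Defaults sd_donor = 0.25, sd_clone = 0.12, sd_day = 0.18 were chosen once
to sit in a realistic intermediate regime — donor effects largest but not
overwhelming, day-to-day effects comparable, clone effects smallest; no
published effect magnitudes exist on this parameter scale, so these are
design choices of the generator, not estimates.

**Well noise.** Fluorescence = baseline × viability/100 × (1 + ε) with
ε ~ N(0, sd_well²), truncated at zero; default sd_well = 5%, a typical
proportional-error level for plate readers. Randomness is organized as
named substreams keyed by (seed, unit name) via CRC-32 hashing, so
regeneration is bit-identical and independent of iteration order.

**What the generator does not emulate:** spatial plate effects (edge
wells, gradients), baseline drift along the titer axis, optical
cross-talk, chemical-specific variance structure (one global set of
variance components applies to all chemicals), or missing wells. Passing
tests therefore demonstrate correctness of the statistical machinery
under a clean version of the design, not robustness to those artifacts.

## Plate normalization

Per clone/day, control wells are screened by an iterative two-sided
Grubbs test (α = 0.05) with flagging capped at 10% of wells; with fewer
than 4 controls no flagging is attempted. Replicate treated wells are
averaged per titer, then divided by the retained-control mean × 100.
Viability is deliberately not clipped at 100 — values above 100 are noise
the curve fit absorbs. By default all 32 of a clone/day's controls pool
into one denominator (a more stable estimate); a per-chemical mode
normalizes against the chemical's own flanking control pairs when a
`control_for` annotation is present, as the drift-sensitive option. No
explicit drift model is applied.

The original analysis used an unnamed GraphPad outlier routine, reported
only as flagging "< 10%" of control wells; iterative Grubbs with a 10%
cap is this package's concrete choice reproducing that property, and its
flags are not expected to match the original's on real data.

## Monotone penalized-spline curve fit

The curve model, objective and defaults are given in the README. Details
the model statement leaves open were fixed as follows:

- **Basis/knots:** cubic B-splines (order 4), K = 20, clamped knots with
  equally spaced interior knots on [0, T], T = the largest observed t for
  the profile.
- **Quadrature:** all curve integrals use cumulative composite Simpson on
  a fixed 501-point grid over [0, T], with linear interpolation of the
  cumulative integral at off-grid points; the exponent is clipped at ±60
  before exponentiation. Beyond T the integrand is extended flat (used
  only for the 2% grid extension and shared-grid evaluation).
- **Optimizer:** exact analytic gradient and Hessian of PENSSE in the
  coefficients (the Hessian exploits the B-spline band structure), Newton
  steps with Levenberg-style ridge escalation when the Hessian is not
  positive definite, Armijo backtracking, convergence at relative
  objective change < 1e-8, max 200 iterations, and an L-BFGS-B polish as
  fallback if Newton stalls. Refits are deterministic.
- **Initialization:** constant log-integrand w ≡ log(1/t_mid) with t_mid
  the empirical 50%-crossing titer (interpolated); when the data never
  cross 50%, w is set so the curve meets the last observed viability at
  the last titer. This places the c = 0-family curve near the data.
- Profiles are fit separately per clone × chemical × day, never pooled;
  inputs are unweighted and unclipped. All-identical viabilities are fit
  but flagged degenerate.

λ is fixed at 0.01; no cross-validation is provided, and no confidence
bands on individual curves.

## IC extraction

ICs are read off a 300-point grid over [0, T_grid] with
T_grid = 1.02 × the top tested t ("slightly higher" made concrete as a
2% extension, configurable), by bracketing and linear interpolation;
IC = 2^t̂ − 1 μM. The effect level is a viability threshold: ICxx is
where viability crosses 100 − xx. Thresholds never reached on the grid
yield undefined estimates, which are excluded from all downstream
summaries and partitions (with group sizes reported). Per-clone summaries
are mean ± sample SD over available days; the cross-clone summary is the
unweighted mean ± SD of per-clone means. An SD over a single observation
is reported as 0 and flagged.

## Functional ANOVA and permutation test

The additive model is fit by ordinary least squares independently at each
grid point with reference coding (α₁ = β₁ = 0); SE(β̂_j)(t) uses the
residual variance with (I−1)(J−1) degrees of freedom. Coefficient
smoothing across t is available but off by default — the p-value and the
95% envelopes are grid-pointwise. The global statistic is the max over
t > 0 of |β̂_j|/SE (the t = 0 point is excluded because all curves equal
100 there and the SE degenerates; exactly tied points below 1e-8 in both
β̂ and SE contribute ratio 0). Permutations shuffle day labels
independently within each toxicant, sampled uniformly with replacement
from the (J!)^I space; p = (1 + #{null ≥ observed})/(1 + B), so
p ≥ 1/(B+1). B = 1,000 by default.

Note a structural limit of this design: a day shift common to all I
toxicants is exactly reproduced by any permutation aligning every
toxicant on one slot, which happens with probability J·(1/J)^I under the
null — with 4 toxicants and 3 days, ≈ 3.7%. Global p-values below that
level require more toxicants (the full 8-chemical panel gives ≈ 0.05%).

## Variance partition

Sequential (Type-I-style) nested decomposition with donor entered before
clone-within-donor, computed from group means; exact for unbalanced data,
and the three components sum to the total SS about the grand mean by
identity. Partitioning is done on the μM IC scale by default (a t-scale
switch exists): the magnitudes of the published component tables are
consistent with raw-scale ICs, but the original scale is not stated, so
this is a documented assumption. All-equal inputs report zero percentages
with a flag; rows where a donor contributes no defined IC are flagged
incomplete.

## Pipeline, problem sizes and determinism

The orchestration layer runs the stages in order, writing per-stage CSV/
JSON artifacts and a manifest (config hash, seed, versions, row counts);
identical configs reproduce non-plot artifacts byte-for-byte. Composite
report curves are point-by-point means across donors of per-donor mean
curves with pointwise 95% t-intervals across donors.

Simulation-based checks use deliberately scaled problem sizes chosen as
this package's own defaults: parameter recovery uses 20 seeded replicates
of a 9-titer duplicate-well Hill profile with 2% well noise;
permutation-test calibration uses 200 Monte-Carlo replicates at B = 500
on 4 × 3 collections over 50 grid points; regime discrimination uses 20
seeds per regime of a single-chemical (menadione-like) study with the
full 4 × 2 × 3 donor/clone/day structure, with variance components set to
donor-dominant (0.5 vs 0.05) or day-dominant (reversed) to make the
regimes unambiguous.

## Known limitations

- The fitted-curve SE structure is not propagated into IC estimates; ICs
  are treated as point values in the partition, as in the original
  analysis.
- The t = log₂(1+μM) scale compresses high concentrations; IC
  interpolation error is second-order in grid spacing but grows where the
  curve is flat (very shallow declines near a threshold).
- With J = 3 days the permutation space per toxicant has only 6 elements;
  global p-value resolution relies on the number of toxicants.
- The generator's single global variance-component set cannot reproduce
  chemical-specific regime differences within one study; regime tests
  therefore vary the components across studies instead.
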