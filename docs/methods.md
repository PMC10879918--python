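# Methods

## The model

The pipeline treats a gene's control-subtracted mean log2 expression as a
function of exposure concentration c (µM) and time t (h) on the design
grid, and models the collection of such surfaces across genes as

    y_gct = Σ_{r=1..p} w_gr · f_r(c, t) + e_gct

with orthonormal factors f_r and per-gene loadings w_gr, fitted by an
uncentred singular-value decomposition of the genes × grid-cells matrix.
The working assumption — checked, not imposed — is that one factor
dominates: responsive genes rise or fall together, each a rescaling of a
single common surface f̂(c, t). The relative first eigenvalue quantifies
how true that is for a given dataset; the isoBMR machinery uses only the
first factor and is only meaningful when its share is large.

Responses are deviations from time-matched vehicle controls, so the model
has no intercept and the decomposition is deliberately *uncentred*: the
common part must vanish where the response vanishes. A mean-centred
variant (`center=True`) exists for comparison with the classical
covariance convention; on data whose mean response is itself close to the
first factor the two give similar spectra.

The factor sign is fixed by requiring Σ_ct f_1 ≥ 0 (ties broken by the
largest-magnitude grid cell), which makes the common surface
predominantly non-negative so the sign of a loading reads directly as
up-/down-regulation, and makes fits bit-reproducible.

## Benchmark levels and isoBMR curves

Gene g reaches its benchmark response where its fitted response
|ŵ_g|·f̂(c,t) equals `bmr_factor · σ_g`, i.e. on the contour

    f̂(c, t) = bmr_factor · σ_g / |ŵ_g|

σ_g is the gene's noise SD on the log2 scale: by default the sample SD
across vehicle-control replicates at each time point, averaged over time
points (a pure noise estimate, in line with control-SD-based benchmark
response definitions; `method="replicate"` pools within-cell SDs across
all treatment cells instead). σ is floored at 1e-6 so the division is
always finite. The default BMR factor 1.349 is the number of SDs spanned
by the central 50% of a normal distribution.

The absolute value |ŵ_g| is used for down-regulated genes as well: their
fitted response is a negative rescaling of the same surface, so they
cross the same response *magnitude* at the same common-factor level, and
a signed level would have no solution on a non-negative surface. Genes
with |ŵ_g| ≤ 1e-8 are excluded from level computation (the division is
meaningless for a gene that does not follow the common factor).

The median of the per-gene levels defines the median isoBMR curve; other
percentiles (numpy's linear-interpolation quantile) give the percentile
fan. Because every curve is a contour of the same surface at a different
level, curves never cross — the "parallelism" the percentile
interpretation relies on.

Contours are extracted per time point on a 200-point log-spaced time
grid: a 256-point coarse scan in log10 c brackets the lowest crossing,
then Brent bisection refines it to 1e-6 log10 units. Taking the lowest
crossing on a non-monotone surface is the conservative choice for a BMC;
times with multiple crossings are flagged on the curve object. A level
above the surface maximum yields an empty curve (reported, not an
error). `bmc_at_time` projects a BMC at any time inside the curve's span
by log-linear interpolation; extrapolation beyond the design window must
be requested explicitly and fits a power law to the curve tail.

## Smoothing

Raw 8 × 5 response matrices carry replicate noise that shows up as
spurious jumps between adjacent design cells. Each gene's matrix is
therefore smoothed with a thin-plate spline minimising

    rho · Σ residual² + (1 − rho) · bending energy

in transformed coordinates u = log10 c, v = log10 t (the design is
geometric in concentration and near-geometric in time; raw scales would
pile the low doses into a corner). The solver is scipy's RBF machinery
(`thin_plate_spline` kernel, degree-1 polynomial tail, ridge parameter
(1−rho)/rho), so rho = 1 interpolates exactly and affine functions of
(u, v) are always reproduced — which is also why a Haber-rule surface
(affine in u+v) survives smoothing unchanged. The default rho is the
customary scattered-TPS heuristic 1/(1 + h³/6) with h the mean
nearest-neighbour node spacing; on the standard 8 × 5 grid this lands
near interpolation with mild damping. Missing design cells are omitted
from the node set, never imputed; the factor model then reads the
smoothed surface back on the full grid, so the decomposition always sees
a complete matrix.

The continuous evaluator for f̂ needed by the level-set solver is a
rho = 1 thin-plate interpolant of the factor's grid values — after the
SVD the factor exists only on the grid, and the interpolant is the
minimal-bending surface through it. Evaluation outside the design
rectangle is refused by default.

## Differential-expression selection

Williams' trend statistic compares the amalgamated (isotonic-regression)
mean of the highest dose group against control:

    t̄ = (μ̂*_K − ȳ₀) / (s · √(1/n_K + 1/n₀))

with pool-adjacent-violators estimating μ̂*_K under monotonicity and s²
the pooled within-group variance. P-values come from Monte-Carlo
permutation of sample labels (default 999 permutations, seeded) rather
than Williams' tabulated critical values: the tables cover few designs,
while permutation adapts to any replicate layout and is directly
testable. The two-sided p doubles the smaller one-sided p and caps at 1;
with 999 permutations the achievable two-sided levels are 2k/1000, which
makes the test very slightly conservative at α = 0.05 (expected null
rejection ≈ 0.048). Degenerate inputs are mapped explicitly: all values
identical → p = 1; zero pooled variance with unequal means → statistic
±∞, p = 1/(B+1).

A gene is retained for a chemical when at ≥ 1 time point p < α (0.05)
and max |log2 FC| vs the time-matched control exceeds 1 (strict). The
two conditions are conjunctive; no across-gene multiplicity correction
is applied by default (the selection feeds a robust median downstream).
Technical and biological replicates are pooled into the test groups;
per-replicate testing is a configuration switch. All genes at one time
point share one permutation sequence — valid, since a permutation test
conditions only on the data permuted — and the batch path is
cross-checked against the scalar path in the tests.

## Synthetic data

The generator runs the factor model backwards: mean log2 CPM =
baseline_g + w_g · f(c, t) (baseline alone for controls) plus Gaussian
log-scale noise, converted through the library size to an expected count
and drawn negative-binomially (dispersion → 0 collapses to Poisson).
Truth surfaces: `haber` (s·max(0, log10(c·t/k)), slope −1 isoeffect
lines), `hill_time` (Hill curve in c with a midpoint that falls with t),
and `separable` (g(c)·h(t)). The full plate layout is enumerated —
8 concentrations split 4 + 4 over two plates per time point, 6 vehicle
controls per plate, well positions permuted per biological replicate —
and the reference parameterisation yields exactly 1980 samples.

Defaults, chosen once as a realistic targeted-panel scenario: 2000 genes,
baseline log2 CPM ~ N(6, 2) truncated at 1, library size 3 × 10⁶ reads,
NB dispersion 0.01, log-scale noise SD 0.15, 15% up- and 5%
down-regulated genes with |w| ~ U(0.5, 1.5), Haber surface s = 1,
k = 10 µM·h. At these settings the top-dose, 48-h effect of a responsive
gene is 1.2–3.6 log2 units (signal-to-noise ≥ 10 against the ~0.15–0.2
total per-replicate SD).

What the generator does *not* emulate: plate/well position effects (the
reference design randomised layouts precisely to cancel them; a
`plate_offset` hook exists for robustness studies), probe-level
structure, alignment artefacts, and — importantly — deviations from the
rank-1 assumption. Passing recovery tests therefore demonstrate that the
pipeline inverts its own generative model at realistic noise, not that
any real chemical follows a one-factor Haber response. One real-data
effect the generator *does* reproduce is CPM compositional bias: when a
sizeable fraction of the panel responds strongly, library-size
renormalisation shifts all genes by a common offset; this moves absolute
responses but barely moves the first factor's shape or the curves.

## Numerical choices

- Inclusive ≥ threshold in the mean-reads filter; pseudocount 1 CPM
  inside the log (finite at zero counts, exposed as a parameter).
- Quantiles: numpy linear interpolation, fixed and documented.
- Level-set bisection tolerance 1e-6 log10 c; curve grid 200 times ×
  256 scan points (configurable).
- SVD backend: numpy LAPACK; rank-deficient requests are truncated with
  a warning rather than erroring.
- Seeds: every stochastic component (permutations, simulation) takes an
  explicit seed; identical config + seed gives byte-identical output
  tables.

## Problem sizes

The test-suite and the acceptance script run the method at the sizes the
workflow is designed for: the full 1980-sample design enumeration, a
2000-gene single-chemical simulation over the complete 8 × 5 × 9 design
for end-to-end recovery, and 2000 replicates for the null calibration of
the trend test. A complete run of everything takes well under a minute
on one core.

## Known limitations

- The one-factor summary is only as good as the first eigenvalue share;
  the package reports the spectrum but deliberately offers no automatic
  factor-count selection beyond it.
- σ_g's definition ("SD averaged over exposure times") admits several
  readings; the control-replicate reading is the default, the pooled
  replicate reading a switch. With 6 controls per time point the sample
  SD carries small-n bias (c₄ ≈ 0.95 at n = 6), which cancels in curve
  *comparisons* but not in absolute levels.
- Curves are single-valued in concentration by construction (lowest
  crossing); genuinely non-monotone concentration responses are flagged
  but not traced as closed contours.
- CPM normalisation is the only normalisation offered; strongly
  compositional datasets may prefer an external normalisation before
  import.
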