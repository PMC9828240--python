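# Methods

## Preference model

An alternative is scored by the additive value function
v(x) = Σᵢ wᵢ·vᵢ(xᵢ) with weights **w** on the unit simplex. Partial value
functions vᵢ map each attribute's natural scale onto [0, 1] with the worst
level at 0 and the best at 1, and are linear throughout: a harm is simply a
scale with `worst > best`, and the one interpolation formula
(x − worst)/(best − worst) covers both directions. Only weight *ratios*
carry meaning; the normalization constant is fixed at 1, with construction
renormalizing any vector whose sum is within 1e-9 of 1.

## The MDT questioning procedure

The simulated respondent answers deterministically from a known weight
vector with no response error (exactly the conditions of the estimator
comparison study). Swing ranking reduces, under linear partial value
functions, to sorting the attributes by descending weight; exact ties —
measure-zero under any continuous population model — break by ascending
attribute index.

Each consecutive pair (i, j) in the ranking is then bisected. The bisection
bracket lives on the partial-value scale of attribute i, starting at
[0, 1]; each question poses the target at the bracket midpoint (mapped to a
natural level through the inverse partial value function, so a 50–90 scale
asks 70, then 80 or 60). The reference alternative has worst-i/best-j, the
target has midpoint-i/worst-j, and attributes outside the pair sit at their
best level in both alternatives — their contribution cancels, so the
constraints are unaffected by that convention. The respondent picks the
target exactly when its additive value is strictly larger; indifference
resolves to the reference (again measure-zero). After s questions the
bracket [v_lo, v_hi] translates to bounds 1/v_hi ≤ wᵢ/wⱼ ≤ 1/v_lo
(upper bound +∞ while v_lo = 0), and the true ratio is inside the bounds by
construction. The feasible weight space is the ranking cone intersected
with all ratio bounds, every constraint written homogeneously as a·w ≥ 0.

An optional total-question budget truncates trailing trade-offs whole (a
trade-off is either fully bisected or not asked); how a budget should split
across trade-offs is genuinely open, and this is the simplest rule
consistent with asking the most important pairs first.

Reconstruction of the feasible space from a stored response record replays
the bisection on the recorded answers only — with linear partial value
functions the bounds depend on nothing else — so elicitation and fitting
can run on different machines.

## Polytope sampling

Sampling runs in the (n−1)-dimensional affine coordinates of the simplex
(drop the last weight; simplex bounds become explicit inequalities), since
hit-and-run needs a full-dimensional interior. The chain starts at the
Chebyshev center of the inequality system (a single small LP, always
strictly interior when the region has volume — a simpler and equally valid
choice than averaging region vertices); default burn-in is 100·(n−1) steps
with no thinning. These settings are not canonical anywhere; they are
validated by the uniformity tests (cone means against the order-statistics
closed form (11/18, 5/18, 2/18) within batch-means Monte Carlo standard
errors, and sample splits against accept-reject volume ratios). All
constraints are treated as weak; boundaries have measure zero. Volume
fractions are estimated by accept-reject from flat-Dirichlet simplex draws
and serve diagnostics and oracle tests only.

## Dirichlet model and fitting

The population model is Dirichlet with α = φ·μ (mean μ on the simplex,
precision φ > 0). Weight vectors are clamped to the interior at 1e-12 and
renormalized before any log-density evaluation or fit, since the density is
zero or unbounded on the boundary. Both fitters optimize in unconstrained
coordinates — a multinomial-logit transform of μ (last component as base)
and log φ — with L-BFGS-B, which keeps the contract "returned parameters
score at least the initializer" automatic. The exact-data MLE works from
the sufficient statistic (mean log-weights) and initializes at the
method-of-moments estimate; non-finite objective values during line
searches are mapped to a large penalty.

The SML fit freezes m uniform hit-and-run draws per respondent before
optimization (common random numbers: the simulated likelihood surface is
smooth and deterministic in the parameters) and maximizes
Σⱼ log((1/m) Σᵢ f(w̃ᵢⱼ)), computed with log-sum-exp because densities span
hundreds of orders of magnitude when φ is large and a region sits far from
μ. The per-respondent constants that would complete each log P_j (region
volume fractions over (n−1)!) are parameter-free, hence omitted; the test
suite verifies that supplying them changes the objective by an exact
additive constant and the fitted parameters by nothing beyond optimizer
tolerance (~1e-6 — finite-difference gradients of a shifted objective are
not bitwise identical). Initialization defaults to the centroid-based fit
on the same draws (for a single respondent, where no centroid MLE exists,
to a moment fit of the pooled draws). The default m = 500 keeps
study-scale fits in seconds while passing the parameter-recovery tests;
the estimator comparisons are insensitive to m well below that.

The centroid baseline fits the exact-data MLE to the Monte Carlo centroids
of the regions, discarding within-region uncertainty — which is exactly why
it overestimates φ when regions are wide (few bisection steps).

For two attributes every region is an interval for w₁, so the model reduces
to an interval-censored Beta likelihood with closed-form CDF differences;
the tests use this as an independent oracle for both the region
probabilities and the full SML fit, plus a brute-force (μ, φ) grid search
for the single-respondent case.

## Simulation study

Population models are drawn with μ uniform on the simplex, rejected until
max(μ)/min(μ) < 10 (no effectively irrelevant attribute), and
φ ~ U(5, 10). For each model and sample size N, true weights are sampled
once and pushed through MDT at each bisection-step setting; three
estimators (exact-information reference, centroid, SML) are fitted per
cell, and errors are reported as the Euclidean distance of the estimated
mean from the truth and the relative precision error (φ̂ − φ)/φ. Seeds are
spawned hierarchically (master → model → cell → respondent/sampler), so any
cell reproduces independently and the whole results table is a pure
function of the master seed. A failed fit is recorded per row
(`converged = False`), not fatal to the batch.

The default profile runs 10–20 models per cell at n = 4, N ∈ {100, 300},
m = 500 — the estimator comparisons (SML ≈ reference, SML below centroid,
centroid precision inflation at one step, centroid-at-three-steps ≈
SML-at-one-step) are already stable at 20 models, and larger grids only
narrow the boxplots. The full-scale grid (100 models per attribute count,
n ∈ {4, 6}) is available through `ExperimentConfig`/`mdtfit experiment`
flags.

## What the simulator does and does not show

The generator reproduces the idealized study conditions: error-free,
instantly consistent respondents whose weights follow the population
Dirichlet exactly. Passing tests therefore demonstrate properties of the
*estimators* under region censoring, not robustness to response error,
preference instability, attribute-scale misperception, or model
misspecification (e.g. multimodal weight populations) — none of which the
Dirichlet-with-deterministic-answers setup can exhibit. Real studies also
face nonlinear partial values and nominal attributes, both outside the
scope of thresholding with linear value functions.

## Known limitations

- Hit-and-run mixing is tuned for the low-dimensional (n ≲ 6),
  well-conditioned regions MDT produces; very thin regions from many
  bisection steps at high n would need longer burn-in or thinning
  (both configurable).
- No standard errors or posterior uncertainty for (μ, φ); the fitters
  return point estimates only.
- Dirichlet regression with covariates is out of scope.
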