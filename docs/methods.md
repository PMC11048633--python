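# Methods

## Model

The package implements a non-parametric Bayesian network (NBN): a DAG
whose nodes carry empirical marginal distributions and whose dependence is
a Gaussian copula in normal-score space. The assumptions are therefore
(i) the stated metamodel DAG is a credible hypothesis of the direct
dependencies, (ii) after transforming every variable to normal scores, the
joint dependence is multivariate normal, and (iii) marginals are whatever
the data say — no distributional family is imposed on any single trait.
Assumption (ii) is testable and tested (see Validation below); (i) is a
scientific input, not an output: the package performs no structure
learning.

### Empirical marginals

The CDF of a variable uses average-rank plotting positions
`F(x_(k)) = rank_k / (n+1)`, which keeps F strictly inside (0, 1) so that
normal scores `z = Φ⁻¹(F(x))` are always finite. Continuous quantile
functions interpolate linearly between order statistics and clamp at the
observed extremes; ordinal (0–3) variables use the step inverse of the
ECDF, so any sampled value belongs to the observed support. An ordinal
evidence value maps to the normal score of the midpoint of its ECDF step
(the average-rank position), which is symmetric and deterministic. A
variable with all observations identical is rejected outright — it
carries no dependence information and would make every rank correlation
undefined.

Evidence outside the observed support is clamped to the extreme plotting
positions `1/(n+1)` or `n/(n+1)` with a warning. This is a deliberate
modelling stance, not a numerical fallback: an empirical marginal has no
mass beyond its observed range, so "what if fluctuations were 50 cm" can
only mean "as high as ever observed". It produces the saturation plateau
visible in the scenario engine — pushing a beneficial trait past its
observed maximum yields no further predicted gain.

### Latent correlation estimation

For two continuous variables, the Spearman rank correlation is converted
with the exact bivariate-normal relation `r = 2 sin(π ρ_s / 6)`. For
pairs involving a 0–3 ordinal trait this conversion is biased: coarse
discretization attenuates rank correlations (measured ≈5% for
ordinal–continuous and ≈9% for ordinal–ordinal pairs at ρ = 0.5 with four
levels), which would propagate into every arc touching an anthropic or
hydrological severity score. The fitter therefore uses a two-step
polyserial estimator (ordinal–continuous) and a one-dimensional
polychoric maximum-likelihood estimator with thresholds fixed at the
marginal cumulative proportions (ordinal–ordinal). Measured arc bias of
the combined estimator is below 0.01 at n = 10⁴. The pure rank route
remains available as `fit_nbn(..., method="spearman")` for comparison
with rank-only workflows. If sampling noise leaves the assembled pairwise
matrix indefinite, it is repaired by eigenvalue clipping
(statsmodels' `corr_clipped`); exactly singular boundary cases (a perfect
rank agreement between two variables) are kept and flagged rather than
repaired.

### Arc correlations and the joint matrix

For a child with parents `p_1 … p_k` in arc-list order, the arc
`(p_j → c)` carries the normal-space correlation of `p_j` and `c` given
`p_1 … p_{j−1}`. The conditioning order is fixed by the arc list of the
DAG config and is significant; the shipped default DAG orders the
direct-to-sink arcs by decreasing magnitude of their expected direct
effect. The joint R is rebuilt from the arc values by the vine recursion
`c_j = r_j √(1 − Σ_{m<j} c_m²)` on a Gram–Schmidt basis of the parents,
which (a) reproduces the arc conditional correlations exactly, (b) gives
every non-adjacent pair the correlation implied by the DAG factorization
(roots independent), and (c) is positive semi-definite for *any* arc
values in [−1, 1] — fit failures can then only come from degenerate
parent blocks, which raise with a pointer to the arc order.

### Conditionalization and prediction

Evidence → normal scores → standard conditional-MVN mean and covariance →
the sink's conditional normal is sampled (default 10⁵ draws, seed
required and recorded) and mapped through the sink's empirical quantile
function. The Monte-Carlo route is used because the quantile function is
piecewise linear — no closed form exists for its image moments. With 10⁵
draws the Monte-Carlo standard error of a reported mean is ≪ 0.1 species.
Local (single-wetland) predictions are additionally rounded to an integer
species count for report tables; the unrounded mean is retained in
machine output.

## Effects

`E_D` is the arc correlation to the diversity node (0 if absent); `E_I`
sums the products of arc correlations over all simple directed paths of
length ≥ 2; `E_T = E_D + E_I` holds exactly by construction. These are
effects in the operational path-sum sense on the stored arc values — no
do-calculus identification is claimed, and no standard errors are
attached. The decomposition is checked against an independent oracle: in
a standardized linear Gaussian system whose coefficients equal the arc
values, the total effect of any *root* trait must equal the analytic
trait–sink correlation (Wright path tracing); the suite verifies this to
10⁻⁶ on dozens of random DAGs.

## Validation

`D_E` is the determinant of the empirical Spearman matrix of the data.
The reference distribution resamples the *fitted* joint law at the
observed sample size (default: the fitted n, i.e. 16), maps every
replicate through the empirical marginals — so ordinal ties occur in the
replicates exactly as in the data — and computes the same rank-matrix
determinant. Like-for-like construction is what makes the band
calibrated: measured coverage of the 90% band is 0.90–0.94 over 200
model-generated studies. A constant column in a replicate (possible at
n = 16 with skewed ordinals) contributes zero correlations instead of
erroring; constant columns in observed data still raise. The printed
product form `Π(1 − ρ²)` over recursive partial correlations is
implemented as a verification identity (`determinant_product_form`,
agreeing with the direct determinant to 10⁻¹⁰); the direct determinant is
primary because the product form depends on an elimination order.

## Scenario engine

Two scopes with deliberately different semantics: **regional** scenarios
condition only the scenario variables, leaving all other traits
distributed as fitted ("all else being equal" across the wetland
population); **local** scenarios condition all of a wetland's listed
baseline traits with the scenario overrides merged on top. Percent deltas
are computed against the baseline scenario of the same scope. Defaults:
10⁵ draws, seed 20160701, both recorded in every output row.

## Synthetic ground truth

The default generator emulates the targeted study design: 16 coastal
wetlands; lognormal sizes (median ≈ 27 ha); gamma water-level variables
(most fluctuation values < 10 cm, a tail to ~30); four-level ordinal
severities with all levels represented; a species-richness sink
`AD = round(exp(2.756 + 0.639 z))` giving mean ≈ 19.3 and SD ≈ 13.7
(overdispersion SD/mean ≈ 0.7). Arc signs and magnitudes are a stylized
emulation of the published effect pattern (size and fluctuations strongly
positive, diversions negative through the hydrological pathway, coast
distance positive through tourism and salinity, discharges with opposed
direct and indirect contributions). What the generator does *not*
emulate: spatial autocorrelation between neighbouring wetlands,
measurement error in expert ordinal scoring, and any species-level
structure (richness only). Passing tests therefore demonstrate the
machinery is correct under the stated copula model at the stated sizes —
not that real wetland data satisfy the copula (that is what the
validation module asks of each dataset).

## Problem sizes and numerical choices

The test suite and the acceptance script run at: n = 16 for study-scale
fits, n = 10⁴ rows × 20 trials for recovery bias, 50 trials for the
n = 16 RMSE report, 2000–4000 resampling replicates for validation bands,
200 trials for band-coverage calibration, 10⁶ draws for the
rejection-sampling conditional-normal oracle, and 10⁵ Monte-Carlo draws
per scenario. These sizes make the documented tolerances comfortably
resolvable (e.g. 2/√n ≈ 0.02 at n = 10⁴) while keeping a full run fast.

Known limitations, measured honestly: at n = 16 the arc estimates for
children with many parents are extremely noisy — arc RMSE up to ≈ 0.6
across repeated synthetic studies — so at the study scale arc *signs* and
the qualitative lever ranking are the robust read-outs, not arc
magnitudes. The polychoric estimator assumes the latent-normal
discretization model; grossly non-copular data are the validation
module's job to flag, not the fitter's.
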