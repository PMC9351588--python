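# Methods

This note documents the statistical model behind `qdnet`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the known limitations.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The quasi-dynamic axis

A cross-sectional samples × taxa table has no time axis.  The habitat
index `H_i` — sample `i`'s total abundance, computed as the exact row sum —
serves as a surrogate dynamic variable: habitats are ordered by how much
total biomass they carry, and all curves are expressed along this
gradient.  Samples with zero total abundance are dropped at load time
(`H > 0` is required); exact ties on the sorted grid are separated by
`1e-9` of the range so the axis is strictly increasing.

Each taxon's abundance is related to the habitat index by the allometric
power law `y_j = alpha_j * H**beta_j`.  The default fit is ordinary least
squares of `log y` on `log H` over the samples with `y > 0` (closed form;
an optional original-scale nonlinear refinement starts from it and can
only improve its objective).  R² is reported on both scales, because both
conventions are common and the choice matters for heteroscedastic data.
Zeros are dropped rather than pseudocounted by default; a `pseudocount`
option exists for sparse tables.

## Component decomposition

For a focal taxon `j` with selected partner set `d_j`, the fitted model is

    y_j(H_i) = y_j(H_(1)) + G_j(H_i) + sum_{j' in d_j} G_jj'(H_i) + e_j(H_i)

* `G_j`, the **independent component**, is a Legendre series (degree
  `self_order`, default `order + 3`) in the focal's smoothed power-law
  curve.  Two details matter:
  * *Leave-self-out habitat:* when partners are present, the smoothed
    curve is evaluated at `H − y_j` (the capacity provided by the rest of
    the community).  Because `H` is the row sum, `y_j = H − sum(others)`
    is an exact identity; a self term evaluated on the full `H` hands the
    regression that compositional tautology as a zero-residual solution
    (we measured exactly this failure: exhaustive best-subset selected
    every decoy).  Isolated fits (no partner terms) have no such identity
    to exploit and keep the strict smoothed-curve form.
  * *Extra flexibility:* the independent block is deliberately more
    flexible than the partner kernels (`order + 3` vs `order`) so that the
    focal's entire smooth trend is absorbed by the intrinsic term and
    partner groups compete only over partner-specific variation.
* `G_jj'`, the **dependent components**, are constrained Legendre series
  `{P_k(u) − P_k(u0), k = 1..order}` in the partner's abundance, with `u`
  the affine map of the partner's value range onto [−1, 1] and `u0` the
  image of zero abundance.  Every basis function vanishes when the partner
  is absent.  This constraint does double duty: it encodes "no partner, no
  influence", and it removes the constant polynomial that would otherwise
  be exactly collinear between the self block and every partner block,
  which is what makes the independent/dependent split identifiable.
* Two engines share this contract.  The default (`engine="pointwise"`)
  evaluates partner kernels at the partner's observed abundance sample by
  sample — the form under which partner-specific variation identifies the
  support (see *Identifiability*, below).  `engine="integral"` takes the
  strict dynamic reading: kernels are functions of the smoothed curves and
  each trajectory is the classical-RK4 integral of its own kernel along
  `H` (step-halving changes trajectories by < 1e-6 relative; the suite
  checks this).
* Because kernel arguments are known data rather than unknown states, the
  least-squares criterion is an exact quadratic in the coefficients and
  the optimum is closed-form weighted least squares — deterministic, no
  iterative optimizer, no restarts.
* Boundary convention: at the smallest habitat index the whole observed
  abundance belongs to the independent component and every dependent
  trajectory is zero; the fitted curve interpolates that sample exactly.
  For *reporting* (network edge weights, decomposition tables), dependent
  components use the zero-abundance-anchored **level** instead, whose sign
  carries the promotion/inhibition meaning even for partners whose
  abundance declines along `H`; the decomposition table's independent
  column is `fitted − sum(levels)`, so additivity stays exact under either
  anchoring.

Residual variance is `RSS/n` on unweighted residuals; the joint Gaussian
log-likelihood across taxa uses the same-sample covariance structure
`Sigma = C ⊗ I_n`, evaluated via `log det C` and a trace identity (no
dense `nm × nm` matrix).  Non-positive-definite plug-in covariances are
repaired by shrinking off-diagonals toward zero; taxa whose fit
interpolates (residuals at numerical zero) have their covariances dropped
rather than letting noise-scale correlations leak into the likelihood.

## Weight functions

The penalized selection criterion carries a prescribed non-negative
diagonal weight `z(W)` vanishing at the smallest and largest habitat
index.  The default is a *plateau* (`1 − v**8` on the affinely mapped
axis): it honours the boundary-zero requirement while discarding almost no
information, unlike the parabola `(W−W_1)(W_n−W)` (also available), which
wastes roughly a third of the effective sample size.  An `adaptive`
variant divides by the squared smoothed curve (variance stabilization for
strongly heteroscedastic data).  The likelihood stage (component fits, LR
test) is unweighted: the weights belong to the penalized criterion, not to
the Gaussian likelihood, and boundary-zero weights would let per-context
fits waste their boundary samples.

## Sparse partner selection

Stage 1 minimizes the group-penalized weighted least squares with uniform
group weights; stage 2 (adaptive) reweights groups by the inverse stage-1
norms, permanently excluding groups at zero.  The solver is proximal
gradient descent with the exact group soft-thresholding operator, warm
starts along a 50-point log-spaced descending λ grid (down to `1e-3` of
the critical λ), and the unpenalized intercept block concentrated out by
orthogonal projection.

Model selection scores every *distinct support* visited along the path by
a refit-OLS BIC,

    n log( RSS / (n − df − p0) ) + df log n   [ + 2γ log C(G, k) for eBIC ],

where `df` counts active columns and `p0` the intercept columns.  The
degrees-of-freedom-adjusted variance keeps the score honest when `df`
approaches `n`; the textbook `RSS/n` plug-in rewards saturated models so
strongly that it selects nearly every group on `p ≈ n` problems (we
measured mean selected sets of ~15 of 19 candidates).  A greedy add/drop
*polish* then walks from the path-chosen support to a local optimum of the
same criterion, which closes most of the gap to an exhaustive best-subset
search; reported coefficients are the unpenalized refit on the final
support (relaxed-LASSO style).

## Identifiability on cross-sectional data

Three structural facts shape what this method class can and cannot
recover, and they drove the design:

1. **Smoothed predictors carry no identifying information.**  All smoothed
   curves `alpha H**beta` are smooth monotone functions of the same `H`;
   after projecting out the focal's own (flexible) smooth term, every
   partner's smoothed curve explains as much of the residual as any decoy.
   Partner kernels therefore default to *observed* abundances
   (`predictor="observed"`): the sample-to-sample variation a partner
   actually shows is the signal that identifies its influence.  A
   `"smoothed"` variant is kept for the purely shape-based reading.
2. **The compositional tautology** (`y_j = H − sum(others)`) is removed by
   the leave-self-out habitat argument described above.
3. **Simultaneity.**  Least-squares regression on a coupled community
   estimates conditional dependence (the Markov blanket: partners plus
   co-parents), not the structural adjacency, and the coupling strength a
   stable community can carry is bounded (the response amplification
   `(I − S)^{-1}` must stay finite).  Within those bounds the per-link
   detection statistic scales as `s * sqrt(n)` with `s` the log-scale
   coupling; at the stability-limited `s ≈ 0.5` and `n = 60` this sits
   near the noise floor of a 19-candidate search.  An exhaustive
   best-subset oracle on the same data recovers only about half the
   planted links — support recovery at these sizes is information-limited
   for *any* correct method, and the benchmark numbers report what is
   actually attainable rather than an aspiration.  Sign recovery on the
   links that *are* selected is accurate (the selected links are the
   well-identified ones).

## Functional clustering

Taxa are clustered by curve shape under a finite mixture of power curves
fitted on the **log scale**, where the power law is exactly the line
`log alpha + beta log H` and multiplicative noise becomes homoscedastic
(the original-scale isotropic Gaussian mixture is misspecified for
abundance data: its BIC kept splitting modules to chase the
heteroscedasticity).  E-steps use responsibilities via log-sum-exp;
M-steps are closed form (the weighted line fit reduces to OLS on the
responsibility-weighted mean profile), so the EM log-likelihood is
monotone by construction.  Initialization is k-means on the per-taxon
(log alpha, beta) allometric features, jittered across restarts; mixtures
with an emptied module are restarted, and `L` is chosen by
`BIC = −2 loglik + (4L − 1) log(nm)`.  Non-positive abundances get half
the minimum positive value before the log (with a warning).  Module
profiles are arithmetic means of member columns; recursive splitting to a
trackable module size (default 15 taxa) is available.

## Networks

Edges are the per-pair mean dependent level over an evaluation sample
subset ("all", one gut position, one subject, or a single sample for an
instantaneous personalized network); edge support comes from selection, so
subsets change weights, never topology.  The neutrality threshold defaults
to 5% of the target taxon's mean observed abundance over the subset —
below it an edge keeps sign 0, participates in pair classification (the
one-sided interaction types need a neutral direction) but is excluded from
the degree counts behind node roles.  The 3×3 thresholded sign table maps
exactly onto mutualism, antagonism, commensalism, amensalism, parasitism,
altruism and neutral; leader = more outgoing than incoming links, hub =
outgoing links above mean total connectivity, solitary = total links
strictly below it (an edgeless graph has mean zero, so everyone is
ordinary).  The two-layer assembly runs the full chain on module mean
profiles (coarse) and on each module's member submatrix (fine);
two-member modules carry both directed links forward without a selection
step, and singleton modules yield a single-node network.

## Context comparison

The null model fits one coefficient set to all samples pooled; the
alternative refits per context with the link support and smoothers held
fixed (support is a model-class choice — varying it across permutations
would break exchangeability, and a pooled-selection support is also what
makes the permutation null well defined).  `LR = −2(ll_pooled − sum_c
ll_context)` with plug-in covariances; small negative values from plug-in
noise are floored at zero with a warning.  Calibration reshuffles labels
uniformly preserving group sizes; the threshold is the nearest-rank 95th
percentile and the p-value uses the add-one convention.  Because every
fit is closed form and context designs are row subsets of precomputed
global design matrices (differenced at the subset's own first sample), a
200-permutation test on a 24-sample, 4-taxon community runs in ~0.1 s,
and the full 100-replicate calibration study in seconds.

## The synthetic generator

The generator is the package's ground-truth instrument; it emulates:

* a drawn habitat axis (log-uniform over `[1, 6]` by default) — drawn, not
  derived from column sums, because abundances are generated *along* the
  axis; the discrepancy between the drawn `H` and realized row sums is
  recorded in the truth bundle (the circularity between the two is a real
  property of habitat-index methods and is left visible);
* per-taxon baseline power curves with exponents spanning decreasing and
  increasing scaling, optionally grouped into modules with configurable
  within-module jitter;
* *biological variation*: each taxon's realized independent component
  multiplies its baseline by a lognormal factor (`sigma_bio`, default
  0.25, scalar or per-taxon) — the sample-to-sample variation real
  communities show, and the signal that propagates through interactions;
* a paired interaction topology (each taxon gets `n_partners` undirected
  partners; each direction its own sign) in the log-linear
  Lotka–Volterra equilibrium form: per sample, log-deviations solve
  `delta = eps + S delta`, so promotion lifts the target when its partner
  sits above its habitat-expected abundance, abundances are positive by
  construction, and the planted system is solved exactly.  Stability is
  enforced by rejection (redraw until `Re(eig(S)) < 1 − margin` and
  `I − S` is well conditioned; margin 0.3);
* optional per-context multipliers or sign flips on chosen links;
* measurement noise last (multiplicative lognormal `sigma_log`, default
  0.05, plus optional additive Gaussian).

Per-link signal-to-noise is recorded as sd(dependent component) /
sd(measurement noise); biological variation is *not* counted as noise
because it is the carrier of interaction signal.  The truth bundle stores
the first-order additive attribution `dep = A_target * s * delta_source`
per link, the realized independent components, module labels, context
labels and the adjacency.

What the generator does **not** emulate: sequencing count noise and
zero-inflation, compositional closure (abundances are absolute-scale),
temporal autocorrelation, and taxonomically structured interaction
preferences.  Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
every artifact of real amplicon data.

## Benchmark study sizes

Chosen so the full battery runs in about a minute on one core: power-law
recovery with 20 taxa × 50 samples at log-noise 0.1 (habitat range two
decades centered on unity, so the intercept is interpolated, not
extrapolated); conservation on 100 random matrices; component additivity
on a 10-taxon, 30-sample system; link/sign recovery on 20 replicates of a
20-taxon, 60-sample community with 3 partners per taxon; best-subset
agreement on 20 replicates of 6-partner problems with two planted
signals; module recovery on 20 replicates of 30 taxa in 3 shared-curve
modules; LR calibration on 100 replicates with 200 permutations each
(scaled down from the conventional 1,000 used for a single real
analysis); and a byte-identity check of two pipeline reruns.

## Known limitations

* Support recovery on cross-sectional data is information-limited (see
  *Identifiability*); treat inferred partner sets as hypotheses ranked by
  evidence, not as the recovered truth.  Sign and strength of the
  selected links are substantially more reliable than the support itself.
* The habitat index inherits every bias of total abundance: with relative
  (compositional) data it is constant by construction and the method does
  not apply unless abundances are scaled to absolute (e.g. by total
  load).
* The LR test holds link support fixed from pooled selection; a context
  effect that cancels in the pool (a perfect sign flip of an otherwise
  unsupported link) can escape selection and hence the test.
* Per-context fits need enough samples per group relative to the
  parameter count (`self_order + 1 + order × |d_j|`); the implementation
  guards degenerate covariances but cannot conjure power from 3-sample
  contexts.
* The interaction taxonomy is threshold-dependent: the neutrality factor
  (default 0.05) decides how much one-sided structure becomes
  commensalism/amensalism rather than mutualism/antagonism.
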