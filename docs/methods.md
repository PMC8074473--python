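# Methods

## The regression model

Each target node is modelled by a Bayesian piecewise linear regression
on the lag-1 values of its candidate parents.  T+1 equidistant time
points yield T observations; observation t (1-based) belongs to segment
h when τ_{h−1} < t ≤ τ_h, with pseudo changepoints τ_0 := 0 and
τ_H := T so that every observation is covered and "changepoint at t"
means t is the last observation of its segment.  (Conventions that start
the recursion at τ_0 := 1 leave the first observation unassigned; we use
the zero-based convention throughout and document changepoints 1-based
in all file formats.)

Within segment h,

    y_h | w_h, σ²  ~  N(X_h w_h, σ² I),      w_h | μ_h, Σ_h, σ² ~ N(μ_h, σ² Σ_h),

with a first design column of ones for the intercept and a shared noise
variance with conjugate prior 1/σ² ~ Gam(α_σ, β_σ).  Reusing σ² in the
coefficient prior makes the model fully conjugate: σ² and every w_h have
standard full conditionals, and the marginal likelihood with all w_h and
σ² integrated out is available in closed form,

    log p(y|θ) = lgΓ(T/2+α_σ) − lgΓ(α_σ) − (T/2)·log π + α_σ·log(2β_σ)
                 − ½ Σ_h log det C_h − (T/2+α_σ)·log(2β_σ + Δ²),

with C_h = I + X_h Σ_h X_hᵀ and Δ² = Σ_h (y_h − X_h μ_h)ᵀ C_h⁻¹ (y_h − X_h μ_h).

Numerics: everything is computed in the log domain; C_h is never formed
or factorised at size T_h × T_h.  The determinant lemma and the Woodbury
identity reduce all quantities to the (k+1) × (k+1) inner matrix
A_h = Σ_h⁻¹ + X_hᵀX_h (k ≤ fan-in = 3), which is Cholesky-factorised.
The residual quadratic is clamped at zero against roundoff.  The same
algebra is implemented twice: a pure-numpy reference
(`nhdbn.regression`, `nhdbn.models`) that defines the semantics and is
compared against dense-matrix and numerical-integration oracles in the
tests, and numba kernels (`nhdbn._kernels`) used by the sampler's hot
loop; the two paths are cross-checked to ~1e−12 in the test suite.

## The four coupling priors

* **M1 (uncoupled)**: μ_h = 0, Σ_h = λ_u I for every segment.  λ_u is a
  signal-to-noise parameter shared across segments.
* **M2 (fully coupled)**: segment 1 as in M1; for h > 1 the posterior
  expectation w̃_{h−1} = A_{h−1}⁻¹(Σ_{h−1}⁻¹μ_{h−1} + X_{h−1}ᵀy_{h−1}) of
  the previous segment becomes the prior mean, with Σ_h = λ_c I.  w̃ is
  treated as a fixed hyperparameter where it is used, so the recursion
  runs forward once per state.
* **M3 (partially segment-wise coupled)**: a binary δ_h per segment
  h ≥ 2 selects μ_h = δ_h·w̃_{h−1} and Σ_h = λ_c^{δ_h} λ_u^{1−δ_h} I;
  δ_1 := 0 is a fixed constant.  The δ_h are iid Bernoulli(p) with
  p ~ Beta(a, b) integrated out, giving the exchangeable marginal prior
  p({δ}) = B(a+Σδ, b+Σ(1−δ))/B(a, b).
* **M4 (generalised coupled)**: as M2 but with a separate coupling
  strength λ_h per segment h ≥ 2.

λ updates are Gibbs draws of the precisions: shape α + (#segments
involved)(k+1)/2, rate β + σ⁻²‖w_h − μ_h‖²/2 summed over the segments
the parameter governs.  When no segment is coupled (M3, δ ≡ 0) the λ_c
conditional reduces exactly to its prior.  The δ_h are updated by
collapsed Gibbs: both candidate values are scored by the closed-form
marginal likelihood times the marginal indicator prior, with the w̃
chain recomputed from segment h onward because δ_h enters the prior
means of all later segments.

## RJMCMC over parent sets and changepoints

One iteration = Gibbs sweep over θ (σ² collapsed over w → w draws → λ
draws → δ sweep for M3), then one parent-set move, then one changepoint
move (skipped when the segmentation is user-fixed).  Move types are
drawn uniformly from {addition, removal, exchange} resp. {birth, death,
re-allocation}; a drawn type that is unavailable in the current state
counts as a rejection, which keeps the standard Hastings ratios
HR_A = (n−|π|)/|π*|, HR_R = |π|/(n−|π*|), HR_E = 1,
HR_B = (T−1−|τ|)/|τ*|, HR_D = |τ|/(T−1−|τ*|), HR_R = 1 valid without
boundary-correction bookkeeping.  Birth positions are uniform over the
unoccupied positions 1..T−1; re-allocation proposes uniformly and
symmetrically between the two neighbouring changepoints.  Proposals that
would leave a segment with fewer than `min_seg_len` (default 2) valid
observations are rejected.

Trans-dimensional bookkeeping: segments that stay identical keep their
parameters.  For M3, every newly formed segment (both children of a
birth split, the merged segment of a death, both segments around a
re-allocated changepoint) gets a fair coin flip for its indicator —
except segment 1, whose indicator is the constant 0 — and the acceptance
ratio carries the indicator prior ratio times 2^(forward flips − reverse
flips); that factor works out to 2 for births and 1/2 for deaths at
every split position, and 1 for re-allocations.  For M4, new segments
draw 1/λ_h from its Gam(α_c, β_c) prior, and the proposal and prior
terms cancel in the acceptance ratio.

Correctness of the whole transition kernel is validated by a
successive-conditional (Geweke) simulator (`nhdbn.calibration`):
alternating model-generated responses with transitions must leave the
prior invariant, and the test suite checks the long-run means of
1/λ_u, 1/λ_c, |π| and H against their prior expectations within 4
autocorrelation-robust standard errors for all four variants.  The
calibration harness uses α_σ = β_σ = 2 instead of the default 0.005:
the default noise prior is so heavy-tailed that simulated responses
overflow floating point, and kernel correctness does not depend on the
hyperparameter values.

## Defaults

| parameter | default | meaning |
|---|---|---|
| α_σ = β_σ | 0.005 | vague inverse-Gamma noise prior |
| (α_u, β_u) | (2, 0.2) | 1/λ_u prior; E[1/λ_u] = 10 |
| (α_c, β_c) | (3, 3) | 1/λ_c (and 1/λ_h) prior; E[1/λ_c] = 1 |
| (a, b) | (1, 1) | flat Beta hyperprior on the coupling probability |
| p_cp | 0.05 | geometric changepoint-distance hyperparameter |
| fan-in | 3 | maximal parent-set size |
| V, burn-in, thinning | 100,000, 50%, 10 | retains W = 5,000 samples |
| min_seg_len | 2 | smallest admissible segment (configurable to 1) |

Chains start deterministically from the empty parent set, the empty (or
user-fixed) changepoint set, δ ≡ 0 and the λ's at their prior harmonic
means; with 50% burn-in the initialisation is immaterial.  Per-node
chain seeds are derived from the master seed and a CRC-32 of the node
*name*, and the network layer runs the per-node chains in a canonical
name-sorted order, so permuting input rows permutes the edge-score
matrix and nothing else, and re-running a node subset reproduces the
full-run chains.

## Synthetic benchmarks

`generate_study1` emulates regime switches on the RAF signalling
topology (11 nodes, 20 edges; consensus structure from the flow-cytometry
literature): H = 4 segments of m = 10 observations, per node a unit-norm
standard-Gaussian coefficient vector for segment 1 and w_h = ±w_{h−1}
(coupled/uncoupled per scenario) afterwards, observation noise σ = 0.05.
`generate_study2` uses the five-gene synthetic yeast (IRMA) topology
(5 nodes, 8 edges) with w_1 = w_2 = w_♦ (unit norm) and
w_3 = w_4 = (w_♦ + w_⋆)/‖w_♦ + w_⋆‖, ‖w_⋆‖ = 0.5 — an identical pair, a
moderate transition, and a second identical pair.  Both topologies are
transcribed from the source publications (Sachs et al.; Cantone et al.)
as commonly reproduced in the benchmarking literature; node and edge
counts are enforced as test invariants.

Values are generated recursively: each time point responds to the
*observed* (noisy) parent values of the previous time point, which is
how measured expression data behave; a non-recursive flag propagates a
noise-free latent trajectory instead.  Nodes without parents evolve as
intercept plus noise.  What the generators deliberately do not emulate:
mRNA degradation kinetics, measurement-platform effects, unobserved
regulators, or non-linear dose-response — so passing benchmarks here
demonstrates correct inference under the model's own assumptions, not
performance on arbitrary real data.

## Evaluation

Edge scores are posterior edge frequencies over the W retained graph
samples.  The precision-recall curve thresholds scores strictly
("score > ξ") with ξ running over the distinct score values plus a value
below the minimum, so the empty and full predictions are both endpoints;
ties enter the curve as a single point.  The area uses the trapezoidal
rule over the (recall, precision) points after prefixing a
(0, first precision) endpoint; a step-function rule is available via
`interpolation="step"`, and since no single interpolation convention is
universal, third-decimal AUC agreement with other implementations is not
claimed.  Degenerate case: if all scores are equal the curve is a single
point (R, P) and the area is defined as P·R.  Top-k network predictions
break score ties lexicographically for reproducibility.

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` run the studies at
5 replicates per configuration and V = 10,000 iterations per gene — the
run length at which independent chains already agree almost perfectly on
edge scores (cross-seed correlation > 0.99 is itself one of the checks) —
with the segmentation fixed at the generating truth for the RAF study,
mirroring the protocol the studies define.  Full-length runs
(V = 100,000, 25 replicates) are a matter of the `iterations` setting
and replicate count.

## Known limitations

* Homoscedastic Gaussian noise shared across segments; no non-Gaussian
  likelihoods, segment-specific variances, or missing-data handling.
* The fan-in prior is uniform-with-cutoff; no richer structure priors.
* Coupling is segment-wise: all coefficients of a segment couple or
  uncouple together (edge-wise partial coupling is out of scope).
* Model choice across M1–M4 is by network-reconstruction accuracy, not
  by marginal-likelihood comparison across variants.
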