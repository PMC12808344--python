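# Methods

## Model and procedure

The package analyzes a single converged t-SNE embedding of a data matrix
`Y ∈ R^{N×D}` (vectorized row-major as `y ∈ R^{ND}`; the embedding
`Z ∈ R^{N×P}`, `P = 2` by default, vectorized as `z ∈ R^{NP}`).

**t-SNE cost.**  Input affinities are Gaussian conditionals
`p_{j|i} ∝ exp(−‖y_i−y_j‖² / 2σ_i²)` with per-point bandwidths `σ_i`
calibrated by bisection so that the conditional distribution's perplexity
`2^{H(p_{·|i})}` equals a user target; joint affinities are the
symmetrization `p_ij = (p_{j|i}+p_{i|j})/2N`.  Embedding affinities use the
Student-t kernel `w_ij = (1+‖z_i−z_j‖²)^{-1}`, normalized over ordered
pairs.  The cost is the KL divergence `C = Σ_{i≠j} p_ij log(p_ij/q_ij)`,
with the standard analytic gradient
`∂C/∂z_i = 4 Σ_j (p_ij−q_ij) w_ij (z_i−z_j)`.

**Sensitivity Jacobian.**  At a stationary point `∇_z C(y*,z*) = 0` the
Implicit Function Theorem gives `J = ∂z*/∂y = −H⁺ M` with
`H = ∂²C/∂z²` and `M = ∂²C/∂y∂z`.  Both blocks are evaluated in closed
form.  Writing `u_ij = z_i−z_j`, `Z_w = Σ w`, `s_i = Σ_j w_ij² u_ij`, the
Hessian splits into pairwise `2×2` blocks (for `i ≠ m`)

    B_im = (8 p_im w_im² − 16 w_im³/Z_w) u u^T + (4 w_im²/Z_w − 4 p_im w_im) I

with diagonal blocks `B_ii = −Σ_m B_im` (exact translation invariance by
construction), minus the rank-one term `(16/Z_w²) s s^T`.  For the mixed
block, `C` depends on `y` only through `p`, so
`M = 4 Σ_j (∂p_ij/∂y) w_ij u_ij`.  The conditional affinities depend on `y`
both directly through the squared distances `d²_il` and implicitly through
the calibrated bandwidths: differentiating the entropy constraint
`H(p_{·|i}) = const` gives, with `β_i = 1/2σ_i²`,
`b_l = d²_il − E_i` (centred squared distances under `p_{·|i}`) and
`V_i = Var_{p_{·|i}}[d²]`,

    ∂p_{j|i}/∂d²_il = −β_i p_{j|i}(δ_jl − p_{l|i}) + β_i p_{j|i} b_j p_{l|i} b_l / V_i ,

the second term being the implicit-bandwidth contribution (dropped in the
`freeze_sigma` fallback).  The chain rule through
`∂d²_il/∂y = 2(y_i−y_l)(δ-terms)` yields dense `M` and matrix-free
JVP/VJP contractions in `O(N²D)`.  All derivative blocks are validated
against central finite differences in the test suite (relative errors
~1e-7 … 1e-10 on small instances).

`H` is singular: the cost is invariant under the `P` translations and
`P(P−1)/2` rotations of the map, so for `P = 2` the null space is
three-dimensional at a generic stationary point.  The Moore–Penrose
pseudoinverse (eigendecomposition; modes with `|λ| ≤ rank_tol·max|λ|`
zeroed, `rank_tol = 1e-8`) fixes this gauge by assigning rigid motions zero
sensitivity.  The null dimension is always reported, never silently
truncated: more than three near-null modes is a warning signalling
structural instability (see *Degenerate geometry* below).  A matrix-free
assembly mode builds `J` column-by-column from conjugate-gradient solves
deflated against the analytic rigid-motion generators; it reproduces the
dense result to ~1e-10 and avoids materializing `H` and `M`.

**Summaries.**  Feature influence `s_k = Σ_i |J_ik|` (columns), coordinate
sensitivity `r_i = Σ_k |J_ik|` (rows), and per-sample sensitivity
`S_j = r_{2j−1} + r_{2j}`.  The three summaries conserve `Σ|J|` exactly.
Scores are reported raw; a z-scored per-feature view exists behind a flag
for cross-dataset comparison.

**Propagation.**  For `y ~ N(y*, Σ_y)`, first-order propagation gives
`Σ_z = J Σ_y Jᵀ`; the diagonal-Σ_y case is computed as `(J·v) Jᵀ` without
materializing `ND×ND`.  `Σ_z` is singular by construction (rigid motions
carry no variance), so its square root uses the eigendecomposition with
negative eigenvalues within `−1e-10·λmax` clipped (Cholesky would fail;
larger negativity is an internal error).  Hypothetical outcomes are draws
`z* + Lξ`; the animation path uses two draws combined as
`z* + L(cosθ ξ_a + sinθ ξ_b)`, `θ_k = 2πk/K`, so every frame is marginally
`N(z*, Σ_z)` while the path is cyclic and C∞-smooth.  Confidence ellipses
come from the per-point `2×2` marginal blocks at a configurable χ²
quantile (default 0.68).

## Optimization and the convergence certificate

The IFT is only valid at a stationary point, so convergence is certified:
every embedding records the final gradient max-norm and downstream stages
refuse uncertified inputs (`force=True` overrides with a warning).

Optimization is two-phase.  Phase one is momentum gradient descent
(momentum 0.5 → 0.8 at iteration 250) with mild early exaggeration (×4 for
100 iterations), run until the cost decrease over a 50-iteration window
falls below 1e-9 relative (a stall at the basin bottom) or `max_iters`
(default 20 000).  Phase two polishes with damped Newton steps through the
eigendecomposition of the analytic Hessian: eigenvalues are inverted
sign-preservingly (the target is stationarity, not minimality — polishing
a perturbed solution must follow the same solution branch even if it is a
shallow saddle), with a magnitude floor of `1e-8·λmax`, a step-norm cap of
0.3× the embedding spread, backtracking on the gradient max-norm, and an
abort if the spread triples.  This reaches max-norms of 1e-11 … 1e-16 in a
handful of iterations; plain-descent polish is available via
`polish_method="gd"` but asymptotes far above such thresholds.

The optimizer defaults (learning rate 20, exaggeration ×4/100) are chosen
for the desk-scale problems this tool targets (N up to a few hundred).
The large-N conventions (learning rate ~200, exaggeration ×12 for 250
iterations) overshoot small problems into a degenerate regime — see next
paragraph — which is why they are not the defaults here.

**Degenerate far-field geometry.**  When some pairwise affinities are very
small (well-separated clusters at low perplexity), the exact-KL optimum
places the corresponding points at distances `~(Z_w·p_min)^{-1/2}`, which
can be enormous.  In that regime all kernels enter their `1/d²` tails, the
cost becomes asymptotically scale-flat, the gradient is small everywhere,
and each far-apart cluster acquires its own nearly-free rigid modes — the
Hessian null space is then effectively larger than three and the spectrum
carries no information.  The polish safeguards (step cap, expansion abort)
prevent the optimizer from certifying such points; the cure at the problem
level is to analyze data/perplexity combinations where all affinities
remain numerically significant, which is the natural regime for the
small-sample use cases (time courses, pseudo-bulk profiles) this analysis
is designed for.  The cluster fixture generator therefore defaults to
moderate separation (centroid distance 2 with unit within-cluster sd),
keeping embeddings compact and the null space cleanly three-dimensional.

## Numerical choices

* Perplexity calibration: bisection on the precision `β_i` with bracket
  doubling, entropy tolerance 1e-12 bits, up to 200 iterations with a
  bracket-collapse early exit.  The near-machine tolerance is required for
  consistency: the mixed partials differentiate the entropy constraint
  analytically and assume it holds exactly at the certified embedding.
  Exactly duplicated input rows are an error (reported with the offending
  pair); a `jitter` flag breaks ties with 1e-10 noise.
* Rigid alignment: least-squares orthogonal Procrustes (rotation +
  translation, no scaling).  Aligning a perturbed re-optimized embedding
  onto `z*` removes the rigid-motion components — to first order the same
  gauge the pseudoinverse fixes, which is what makes finite-difference
  Jacobians comparable to `−H⁺M`.
* Finite-difference oracle: central differences with per-entry re-polish
  from `z*`; step 1e-4× the data scale (the error bowl is checked in the
  tests); columns whose perturbed embedding moves >50× the median
  displacement are flagged as probable basin jumps.
* Heatmap size guard at 2×10⁶ cells; beyond that only summarized views are
  offered.
* All randomness flows from integer seeds (`numpy.random.default_rng`);
  same seed ⇒ bit-identical embeddings, samples and figures.

## Synthetic data: what it emulates and what it does not

`make_clusters` draws Gaussian blobs at regular-simplex centroids
(optionally with one pair moved closer to create an ambiguous boundary),
emulating cell-type structure with partially overlapping populations.
`make_timeseries` simulates a replicated log2-scale expression course —
T=8 timepoints × R=3 replicates × G=60 genes by default, a 6-gene switch
block gaining `log2(8) = 3` units from timepoint 5 onward over a per-gene
`N(5,1)` baseline, with entry-wise `N(0, 0.25²)` noise — the structure of
a bacterial metabolic-switch experiment at reduced gene count.
`replicate_moments` reduces the tensor to replicate means (point estimate)
and the unbiased variance of the mean (`s²/R`, ddof = 1), the standard
preparation for diagonal-Σ_y propagation.

These are Gaussian caricatures: no counts, overdispersion, dropout,
library-size or batch effects, and independent noise across entries.
Passing tests therefore demonstrate the correctness of the differential
machinery and the statistical behavior of the propagation on well-posed
Gaussian inputs — not robustness to the full noise structure of real
sequencing data, where the Gaussian input-uncertainty model is itself an
approximation.

## Validation summary (computed by the test suite and acceptance script)

* Analytic gradient/Hessian/mixed partials vs central finite differences
  on N=6 instances (max relative error well below 1e-4).
* Analytic Jacobian vs perturb/re-optimize/align central differences on an
  N=12, D=3 cluster fixture (median columnwise relative error ≲1e-6).
* Hessian null-space dimension exactly 3 on the converged N=30 3-cluster
  fixture (eigenvalue count below 1e-8×λmax).
* `Σ_z` vs the empirical covariance of 200 small-noise re-optimized,
  aligned embeddings (ε = 1e-3 of the data scale, 100 antithetic pairs).
  Note the comparison's resolution limit: a 200-sample covariance estimate
  in 24 dimensions with effective rank 3–4 itself carries an RMS Frobenius
  error of `√((r_eff+1)/200)` ≈ 15–25%, so values in that range are
  consistent with a correct linearization; at 1000 replicates the
  discrepancy falls to ~9%.
* Invariances: conditional/joint/low-dim affinity normalizations to 1e-12;
  `J`·(uniform per-feature shift) = 0; rigid-motion quadratic forms of
  `Σ_z` ≤ 1e-8·tr(Σ_z); loop-path frames marginally `N(z*, Σ_z)` (pooled
  over 4000 seeds).
* Feature attribution: switch-block genes at post-onset timepoints are
  enriched in the top decile of influence scores (one-sided permutation
  test over gene labels, p ≈ 1e-4).
* Conservation: `Σ s_k = Σ r_i = Σ S_j = Σ|J|` to 1e-10 relative.

## Design choices where the design was open

* **Differentiating through the calibration** is the default (`σ_i(y)`
  treated as implicitly defined by the entropy constraint, differentiated
  in closed form — exact, cheap, independent of bisection iteration
  count); `freeze_sigma=True` treats bandwidths as constants, for
  comparison with implementations that differentiate the cost at fixed
  affine parameters.
* **Newton polish** instead of plain-descent polish: descent asymptotes
  orders of magnitude above the certification thresholds the IFT stage
  needs, while the analytic Hessian is available anyway.
* **Sample covariance with antithetic pairs** for the re-optimization
  ensemble: pairing (ξ, −ξ) cancels the leading even-order nonlinear bias
  in the deviations at no extra cost.
* **Eigendecomposition square root** of `Σ_z` (not Cholesky): `Σ_z` is
  singular by construction.
* **Two-draw cos/sin loop** for the animation: the simplest construction
  whose every frame is exactly equiprobable with C∞ cyclic continuity.
* The qualitative boundary-sensitivity effect (ambiguous samples between
  two under-separated clusters scoring higher than well-separated ones) is
  regime-dependent at small N — point-density effects can dominate when
  the pair fully merges — so its regression test pins a fixture in the
  partially-resolved regime where ambiguity dominates.

## Known limitations

* Exact `O(N²)` affinities and dense `O((NP)³)` eigendecompositions: the
  intended scale is N ≲ ~2000; no tree/interpolation approximations.
* The analysis is local to one optimum: it quantifies robustness of the
  given map to small input perturbations, not run-to-run variability under
  re-initialization (a complementary, global question).
* First-order propagation: `Σ_z` inherits the local-linearity assumption;
  it degrades as input noise grows beyond the scale where the solution
  map is approximately affine.
* Sensitivities with respect to perplexity or other hyperparameters, and
  second-order corrections to the solution map, are out of scope.
* `P > 3` embeddings are accepted but untested; perplexity annealing and
  approximate t-SNE variants are unsupported.
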