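# tsne-sensitivity

Post-hoc sensitivity analysis and uncertainty propagation for converged
t-SNE embeddings of omics data (bulk expression time courses, proteomics,
pseudo-bulk single-cell profiles).

A t-SNE map answers "what does my data look like?" but not "which features
put each point where it is?" or "how would the map move if I had measured
slightly different values?".  This package answers both for a *single,
converged* embedding, without modifying the t-SNE algorithm or resampling.

## The idea

t-SNE minimizes the KL divergence `C(y, z)` between input-space affinities
`p_ij(y)` (Gaussian kernels, bandwidths calibrated per point to a target
perplexity) and embedding affinities `q_ij(z)` (Student-t, one degree of
freedom).  At a converged embedding the stationarity condition

    ∇_z C(y*, z*) = 0

implicitly defines the optimal embedding as a function of the data.
Differentiating it (Implicit Function Theorem) gives the full sensitivity
Jacobian

    J = ∂z*/∂y = − H⁺ · ∂²C/∂y∂z,     H = ∂²C/∂z²,

an `NP × ND` matrix saying how every embedding coordinate responds to every
input entry.  `H` is singular — the cost is invariant under translations
and rotation of the map, so `H` has a three-dimensional null space for
`P = 2` — and the Moore–Penrose pseudoinverse fixes that gauge by assigning
the rigid motions zero sensitivity.  Both second-derivative blocks are
evaluated in closed form, including implicit differentiation of the
per-point entropy (perplexity) constraint that defines the bandwidths
`σ_i(y)`.

From `J` the package derives:

* **feature influence** `s_k = Σ_i |J_ik|` — which input entries shape the
  whole map (reshapable to, e.g., timepoints × genes);
* **sample sensitivity** `S_j = Σ_k (|J_{2j-1,k}| + |J_{2j,k}|)` — which
  points sit on fragile positions;
* **uncertainty propagation**: for Gaussian input uncertainty
  `y ~ N(y*, Σ_y)` (e.g. replicate variances of the mean), the embedding
  covariance `Σ_z = J Σ_y Jᵀ`, visualized as confidence ellipses, static
  hypothetical-outcome overlays, or a smooth cyclic animation whose every
  frame is an equiprobable embedding.

Because the method differentiates optimality conditions rather than the
optimizer, it applies to any embedding that can be polished to a certified
stationary point of the exact cost — convergence is checked, not assumed.

## Worked example

A replicated expression time course (8 timepoints × 3 replicates × 60
genes, log2 scale) with a 6-gene "switch" block induced 8-fold from
timepoint t5 onward; replicate means are the point estimate and replicate
variances of the mean the input uncertainty:

```python
import numpy as np
from tsne_sensitivity import (TimeSeriesSpec, make_timeseries, replicate_moments,
                              TsneConfig, optimize_embedding, sensitivity_jacobian,
                              feature_influence, sample_sensitivity,
                              propagate_covariance)

spec = TimeSeriesSpec(seed=3)          # 8 timepoints x 3 replicates x 60 genes
data, unc = replicate_moments(make_timeseries(spec))
emb = optimize_embedding(data, TsneConfig(perplexity=5.0, grad_tol=1e-10, seed=3))
print(f"converged: {emb.converged}  (grad max-norm {emb.final_grad_maxnorm:.2e})")

jac = sensitivity_jacobian(data, emb)   # 16 x 480
print(f"Hessian null-space dimension: {jac.spectrum.null_dim}")

scores = feature_influence(jac).reshape(spec.T, spec.G)
top = np.unravel_index(np.argsort(scores, axis=None)[-5:], scores.shape)
for t, g in zip(*top):
    print(f"influence {scores[t, g]:8.3f}  timepoint t{t+1}  gene g{g}")

S = sample_sensitivity(jac).per_sample
print("most sensitive timepoint:", data.sample_names[int(np.argmax(S))])

cov = propagate_covariance(jac, unc)
sd = np.sqrt([np.trace(m) for m in cov.point_marginals])
print("positional sd per timepoint:",
      "  ".join(f"{n}:{s:.3f}" for n, s in zip(data.sample_names, sd)))
```

Output:

```
converged: True  (grad max-norm 6.16e-17)
Hessian null-space dimension: 3
influence    0.368  timepoint t6  gene g5
influence    0.374  timepoint t5  gene g1
influence    0.376  timepoint t8  gene g4
influence    0.379  timepoint t7  gene g1
influence    0.477  timepoint t6  gene g1
most sensitive timepoint: t7
positional sd per timepoint: t1:0.063  t2:0.059  t3:0.045  t4:0.052  t5:0.068  t6:0.052  t7:0.066  t8:0.055
```

Every top-influence entry is a switch-block gene (g0–g5) at a post-onset
timepoint — the feature attribution recovers the planted driver of the
map's main separation.  The per-timepoint standard deviations are the
propagated replicate noise: how far each point would plausibly move under
remeasurement.

The same pipeline runs from the shell:

```bash
tsne-sensitivity simulate --kind timeseries --seed 3 --out run/sim
tsne-sensitivity embed --data run/sim/data.tsv --perplexity 5 --seed 3 --out run/emb
tsne-sensitivity sensitivity --data run/sim/data.tsv \
    --embedding run/emb/embedding.tsv --out run/sens
tsne-sensitivity propagate --data run/sim/data.tsv \
    --embedding run/emb/embedding.tsv --uncertainty run/sim/variances.tsv \
    --out run/prop            # ellipses.png, overlay.png, animation.gif
```

Estimator-style interfaces (`ExactTSNE`, `TSNESensitivity`) follow
scikit-learn conventions (`fit`, `fit_transform`, `get_params`, fitted
attributes with trailing underscores) and compose with sklearn tooling.

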