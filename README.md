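# fixfit

**How many parameters of a mechanistic model can data actually pin down?**

Many simulation models in biology and physics are *sloppy*: distinct
combinations of their native parameters produce identical outputs, so
fitting the native parameters to data yields broad, ambiguous solution sets.
`fixfit` estimates the number of *uniquely identifiable* latent parameters
of a forward model, characterizes how the native parameters drive them, and
fits them to data:

1. **Bottleneck sweep** — train encoder–bottleneck–decoder networks that
   predict model outputs from normalized parameters at bottleneck widths
   k = 1, 2, …, N. The validation error saturates once k reaches the number
   of identifiable parameter combinations; the selected k\* is the smallest
   k whose replicate errors are not statistically worse than the best k
   (one-sided Welch t-test, α = 0.05).
2. **Global sensitivity** — push the sampled parameters through the trained
   encoder and compute the uncorrelated SCSA index of each latent parameter
   y_j with respect to each input x_i,

   S<sup>unc</sup><sub>ij</sub> = Σ_s f<sub>ij</sub>(x_i<sup>(s)</sup>)² / Σ_s (y_j<sup>(s)</sup> − ȳ_j)²,

   where f_ij is the first-order HDMR component function fitted on a cubic
   B-spline basis. Rows of near-zero indices expose fully redundant inputs.
3. **Global fitting** — infer latent coordinates from output data by
   basin-hopping over a bounded hypercube (Metropolis acceptance
   P = exp(−Δf/T), step 0.2, L-BFGS-B local refinement), with the trained
   decoder as a differentiable forward map.

Three bundled forward models exercise the pipeline end to end on synthetic
data:

| model | native parameters | outputs | known structure |
|---|---|---|---|
| Kepler two-body orbit | m₁, m₂, r₀, ω₀ | ln r(θ) on 100 angles | 2 composites (e, l); m₁ fully redundant |
| βIG glucose regulation | C, S_i, p, α, γ, u_ext | 24 h glucose trace, 5-min grid | S_i·p product known inseparable |
| Larter–Breakspear brain network | 11 neural-mass parameters | FC upper triangle (3003 values at 78 regions) | explored at cluster scale |

## Worked example

```python
from fixfit import bottleneck, datagen, sensitivity

batch = datagen.generate_kepler_batch(n_target=2529, seed=1)
sw = bottleneck.sweep(lambda k: bottleneck.NetworkSpec.kepler(k), batch,
                      k_range=range(1, 5), replicates=3, base_seed=11,
                      config=bottleneck.TrainConfig(epochs=1000, patience=100))
print(sw.means, "k* =", sw.k_star)

model = min(sw.results[sw.k_star], key=lambda r: r.min_val_mse).model
latents = sensitivity.encode(batch.norm_params, model)
print(sensitivity.scsa_unc(batch.norm_params, latents,
                           input_names=batch.param_names).to_frame().round(3))
```

Output from one run:

```
{1: 0.008655, 2: 0.001425, 3: 0.001029, 4: 0.000717} k* = 2
           L1     L2
m1      0.000  0.000
m2      0.161  0.024
r0      0.077  1.472
omega0  0.519  0.103
```

The error drops by ~6× from k = 1 to k = 2 and then saturates — two latent
parameters describe the orbit family, matching the closed-form (e, l)
composites. The sensitivity matrix shows m₁ drives nothing (it cancels in
the equation of motion), r₀ dominates one latent axis, and ω₀ (with m₂)
loads on the other, reflecting their ω₀²/m₂ degeneracy. Because the
eccentricity filter correlates the retained inputs, the uncorrelated
indices partition shared variance by regression and a single index can
exceed 1 (its correlated complement is negative).

The same pipeline is available from the shell:

```bash
fixfit run-all config.yaml     # simulate → sweep → select-k → sensitivity → fit
```

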