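# omnik

Kernel machine regression for jointly testing **main** and
**treatment-interaction** effects of microbial (or any high-dimensional)
variants on a health response — from an input kernel alone — with the
**OmniK** multi-kernel min-P omnibus test.

## The problem

Microbiome association studies ask whether community composition X influences
a response y directly (main effects β₁) and/or by modifying a treatment's
effect (interaction effects β₂), adjusting for the treatment T and covariates
Z:

    y = α₁ + T α₂ + Z α₃ + f(X) β₁ + (f(X) ⊙ T) β₂ + ε

(logistic for a binary y). Community similarity is measured by ecological
kernels — Jaccard, Bray–Curtis, unweighted/generalized/weighted UniFrac —
for which the transformed variants f(X) are unknown, so interaction terms
f(X) ⊙ T cannot be written down directly. This package extracts **surrogate
variants** X\* = U D from the kernel's eigendecomposition K = U D² Uᵀ
(X\* X\*ᵀ = K), builds three endogenous kernels — K^M = X\*X\*ᵀ,
K^I = (X\*⊙T)(X\*⊙T)ᵀ, K^B = K^M + K^I — and tests H₀: β₁ = β₂ = 0 with
variance-component score statistics rᵀKr of null-model residuals, calibrated
by a single shared permutation plan. Minimum-p statistics recalibrated
against their own permutation null combine the three targets per kernel and
then all targets across kernels (OmniK), controlling the family-wise error
that naive Fisher/Brown/Simes combination inflates. See `docs/methods.md`
for the full construction.

## Worked example

Simulate a study where the microbiome modifies the treatment effect
(interaction-only signal in one phylogenetic cluster), then test:

```python
from omnik import omnik_test
from omnik.simulation import SimulationScenario, simulate_dataset

scen = SimulationScenario(n=60, p=60, effect="interaction_only",
                          cluster_id=3, f_transform="standardize")
ds = simulate_dataset(scen, seed=42)
res = omnik_test(table=ds.table, tree=ds.tree, meta=ds.meta, R=2000, seed=7)
print(res.to_dict())
```

Output (abridged):

```
"kernels": {
  "jaccard":       {"P_M": 0.868,  "P_I": 0.3465, "P_B": 0.7275, "P_minp": 0.526},
  "braycurtis":    {"P_M": 0.0005, "P_I": 0.0,    "P_B": 0.0,    "P_minp": 0.0015},
  "uwunifrac":     {"P_M": 0.244,  "P_I": 0.0755, "P_B": 0.132,  "P_minp": 0.1075},
  "gunifrac:0.5":  {"P_M": 0.0,    "P_I": 0.0,    "P_B": 0.0,    "P_minp": 0.001},
  "wunifrac":      {"P_M": 0.0,    "P_I": 0.0,    "P_B": 0.0,    "P_minp": 0.001},
  ...
},
"omnibus": {"P_M": 0.002, "P_I": 0.0025, "P_B": 0.002, "P_OmniK": 0.003}
```

Reading it: per kernel, `P_M`/`P_I`/`P_B` are the permutation p-values of the
main, interaction and combined score tests (resolution 1/R; 0 means below
1/2000 here), and `P_minp` is the kernel's min-P recalibrated p-value. The
abundance-weighted phylogenetic kernels detect this linear signal strongly;
the presence-absence Jaccard kernel does not — which is why the omnibus
matters. `P_OmniK = 0.003` is the single overall answer across all kernels
and effect targets, properly adjusted for having looked at 21 tests.

The same analysis runs from files on disk:

```sh
omnik test --counts counts.tsv --tree tree.nwk --meta meta.tsv \
    --response bmi --treatment diet --covariates age,sex \
    --family gaussian --perms 3000 --seed 1 --out result.json
omnik simulate --scenario scenario.yaml --reps 500 --perms 1000 --seed 1 --out rates.tsv
```

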