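# splash

Spatially adaptive activation mapping for task fMRI: parcel-localized
thin-plate spline regression on GLM coefficients, with AR(p) feasible-GLS
fitting, BIC-selected spatial resolution, and two-stage selective FDR
group inference. Gaussian-kernel-smoothing comparators and a synthetic
spherical-surface simulation harness are included.

## The problem

Task fMRI analyses fit, at every vertex or voxel `v`, the linear model

```
y_v = X β_v + ε_v,        X ∈ R^{T×KB},  ε_v ~ N(0, Σ_v)
```

where the columns of `X` are stimulus trains convolved with B hemodynamic
response basis functions for each of K conditions. Fitting each location
independently ignores spatial structure and yields fragmented, noisy maps.
The common remedy — Gaussian kernel smoothing (GKS) of the BOLD data,
`ỹ_v = Σ_u K_h(v,u) y_u` — is provably biased toward the local weighted
average of the true activation field and deflates the residual variance
estimator by `Σ_u K_h(v,u)²` (both closed forms are implemented as oracles
in `splash.gks`).

This package instead smooths **in coefficient space**. Within each atlas
parcel of V locations, the activation field for a given (condition, basis)
pair is expanded in a low-rank thin-plate regression spline basis,

```
(β_kl(1), …, β_kl(V))ᵀ = S γ_kl,        S ∈ R^{V×M},
```

so the stacked parcel model is `Y = Z P Φ Γ + ε` with `Z = I_V ⊗ X`,
`Φ = I_KB ⊗ S`, and `P` the location-major → basis-major permutation. The
estimator is feasible GLS with per-location AR(p) temporal noise
(Yule–Walker estimates, banded-Cholesky whitening in O(Tp)),

```
Γ̂ = (AᵀΣ̂⁻¹A)⁻¹ AᵀΣ̂⁻¹Y,        A = Z P Φ,
```

computed without materializing `A` via the Kronecker structure
`AᵀΣ̂⁻¹A = Σ_v (XᵀΣ̂_v⁻¹X) ⊗ s_v s_vᵀ`. Under iid noise this reduces
exactly to OLS and is exactly unbiased with finite-sample unbiased
variance estimates. The spatial resolution M is chosen per parcel by BIC,
so smoothing adapts to each region's heterogeneity.

Group inference is two-stage: parcels are screened by Benjamini–Hochberg
(BH) on one-sample t-statistics of the subject parcel means at level
`α_parcel`, then vertex-level BH runs inside each selected parcel at the
selective level `q_p = α_voxel·|S|/P`, which bounds the expected average
FDR over the selected parcels by `α_voxel`.

## Worked example

```python
from splash.simulate import SimulationConfig, run_study

cfg = SimulationConfig(seed=7)   # 2000-vertex sphere, 20 parcels, N=30
df = run_study(cfg)
print(df[df.task == 1][["method", "mse", "fpr", "fnr", "auc", "m_median"]].round(4))
```

prints

```
method    mse    fpr    fnr    auc  m_median
   glm 0.0021 1.0000 0.0000 0.9777       NaN
   gks 0.0088 1.0000 0.0000 0.9968       NaN
  agks 0.0043 1.0000 0.0000 0.9976       NaN
splash 0.0020 0.0006 0.4597 0.9796      18.0
```

Reading the rows: `mse` is the mean over subjects of the squared error of
each subject's estimated Task-1 activation map against that subject's own
true field — here the spline model (`splash`) matches the unsmoothed GLM
and is 4× more accurate than fixed-bandwidth kernel smoothing (`gks`),
whose bias dominates. In this replicate the shared between-subject random
effect drew a large positive value, so the flat vertex-wise BH used by the
comparators rejects essentially everywhere (`fpr = 1.0`); the two-stage
procedure's parcel screen absorbs the shift and keeps the false positive
rate at 6×10⁻⁴ at the cost of missing the weaker half of the active
vertices. `m_median` is the median BIC-selected spline dimension across
parcels (out of ~100 vertices per parcel).

A command-line interface mirrors the library
(`splash simulate | fit | infer | run-study | evaluate`):

```
splash simulate --seed 3 --out data/
splash fit --data data/ --method splash --out maps.npy
splash infer --maps maps.npy --labels data/parcels.tsv --out results/
```

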