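# Methods

This note documents the statistical model, the estimators, the synthetic
data generator, and the numerical choices made where the design was open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Temporal model and design construction (`splash.hrf`)

The BOLD series at a location is `y = Σ_k Σ_l β_kl (s_k * b_l) + ε`: each
condition's stimulus train `s_k` (boxcars; zero-duration events are unit
impulses) is convolved with B temporal basis functions `b_l`. Supported
bases: the canonical double-gamma HRF (peak delay 6 s, undershoot delay
16 s, unit dispersions, undershoot ratio 1/6, 32 s support, peak-normalized
to 1 — the de facto standard parameterization), FIR indicator bins tiling
the response window, and cubic B-splines (clamped knots, partition of
unity). Convolution runs on an internal grid oversampled at TR/16 and is
decimated to the T volume times, which keeps off-grid onsets alias-free;
volumes are indexed from 0 and all timing is in seconds. Design columns
are ordered condition-major. Nuisance regressors are stored separately,
never counted in KB, and projected out of both the data and the task
columns before any fit.

## Spatial basis (`splash.tps`)

Within a parcel with coordinates `x_1..x_V` (d = 2 or 3; spherical
surfaces use their 3-D embedding, i.e. chordal distances), the V×M design
matrix S is the eigen-truncated thin-plate spline basis: form
`E_ij = η(‖x_i − x_j‖)` with `η(r) = r² log r` (d = 2) or `η(r) = −r`
(d = 3; unit proportionality constants — they only rescale the spectrum),
keep the `M − (d+1)` leading eigenvectors by |eigenvalue|, and append the
polynomial null space `[1, x₁, …, x_d]`. Columns are orthonormalized with
the polynomial block first (greedy modified Gram–Schmidt that skips
near-dependent directions), so:

- the affine null space is always inside the span;
- bases are nested in M (the rank-M basis is the first M columns of the
  rank-V one), making BIC sweeps cheap;
- `M = V` spans R^V exactly, so the spline fit degenerates to the vertex
  GLM — an identity the tests assert to 1e-9;
- determinism: eigenvector signs are fixed by making each vector's
  largest-magnitude entry positive.

The basis is used **unpenalized**; M itself is the regularizer, selected
by BIC. Duplicate coordinates are collapsed with a warning. Parcels with
fewer than d+3 vertices fall back to the vertex GLM, flagged.

## Estimation (`splash.model`)

`fit_vertex_glm` is per-location OLS via QR with a rank check that names
collinear columns; `σ̂²_v` uses T − KB − J degrees of freedom.

Temporal noise is AR(p) per location (default p = 1, configurable),
estimated by Yule–Walker on the vertex-GLM residuals with biased
(positive-definite) autocovariances, which guarantees stationarity;
constant residual series are flagged degenerate and given unit whitening
weights. Whitening applies the exact banded Cholesky factor of the AR
precision: rows ≥ p are scaled innovations, rows < p use the order-t
predictors from the Levinson–Durbin recursion, so `L Σ Lᵀ = I` holds
exactly in finite samples (asserted to 1e-10 against dense Toeplitz
covariances). Cost is O(Tp) per series.

`fit_splash` accumulates the structured normal equations
`H = Σ_v (X̃_vᵀX̃_v) ⊗ s_v s_vᵀ`, `b = Σ_v (X̃_vᵀỹ_v) ⊗ s_v` without
materializing `A = ZPΦ`; coefficient indices follow the documented maps
(location-major `v·KB + c`, basis-major `c·V + v`, spline `c·M + m`).
FGLS is one-step: AR parameters from the vertex-GLM residuals, then a
single GLS pass. With `estimator="ols"` (common iid variance) the
estimator reduces to projecting the vertex-GLM coefficient field onto S,
with the pooled `σ̂² = RSS/(TV − KBM)` and
`Var̂(β̂_sp[v,c]) = σ̂² (XᵀX)⁻¹_cc ‖s_v‖²` — finite-sample unbiased under
iid errors, verified by a 1000-replicate Monte-Carlo calibration test.
Singularity is declared at relative condition 1e12.

BIC is `−2ℓ̂ + k log n` with `n = TV`, `k = KBM`, and `ℓ̂` the Gaussian
log-likelihood — concentrated over the common variance for OLS, evaluated
under the fitted AR model for FGLS. (The likelihood form, n and k are this
package's documented choice.) M is selected per parcel, shared across
subjects, by summed BIC with ties to the smaller M; the default candidate
grid is geometric with ~8 points from d+2 to min(V, 100). BIC targets
predictive fit, so it is deliberately conservative about spatial detail in
low-SNR parcels — that is the intended adaptivity.

## Kernel-smoothing comparators (`splash.gks`)

Weights are truncated (3h) renormalized Gaussians on Euclidean distances;
`FWHM = 2√(2 ln 2)·h` (so h = 2.55 ↔ FWHM 6). Two closed-form oracles
characterize smoothing the data rather than the coefficients: the
smoothed-GLM estimator has conditional mean `Σ_u w_vu β_u` (bias
`Wβ − β`, zero only for locally constant fields), and under iid noise the
naive residual variance estimator is attenuated by exactly `Σ_u w_vu²`.
Both are verified by 2000-replicate Monte-Carlo tests at 4-SE / 3%
tolerances.

The adaptive variant (AGKS) selects h per parcel by a Gaussian BIC with
effective parameter count `KB · tr(WWᵀ)` restricted to the parcel — the
smoother's effective number of independent locations, which decreases
with h. The likelihood is evaluated against the **unsmoothed** data
(residuals `y_v − X β̂_GKS,v`): scoring the smoothed series would always
favor the widest kernel, because smoothing itself deflates the apparent
residual variance. This definition is a design choice of this package.

## Group inference (`splash.inference`)

One (condition, basis) coefficient at a time; two-sided tests by default.
Stage 1: one-sample t-statistics of the subject parcel means, BH at
`α_parcel` (default 0.1). Stage 2: within each selected parcel, vertex
one-sample t-tests and BH at the selective level `q_p = α_voxel·|S|/P`
(default `α_voxel` 0.5), which bounds the expected average FDR over the
selected parcels; the average is defined as 0 when nothing is selected.
Degenerate zero-variance vertices get p = 0 (nonzero mean, flagged) or
p = 1 (zero mean). BH is implemented directly (step-up with deterministic
tie handling) and cross-checked against statsmodels. Comparator pipelines
(GLM, GKS, AGKS) use a single flat vertex-wise BH pass.

Because the subject random effect γ is spatially constant, null-vertex
t-statistics are strongly dependent within a replicate: a single large
draw of γ̄ can push a flat BH pass to reject everywhere. The parcel screen
absorbs exactly this failure mode; FDR control holds on average over
replicates, as the 500-replicate calibration test verifies.

## Synthetic data (`splash.simulate`)

The generator emulates a group study on a parcellated spherical cortical
surface:

- **Mesh** — Fibonacci lattice (deterministic), radius 100 (a
  cortex-like physical scale); parcels are Voronoi regions of seeded
  centers relaxed by 8 Lloyd iterations: compact, roughly equal-area,
  non-empty.
- **Truth fields** — per condition, `n_blobs = 3` activation regions:
  plateau spherical caps (interior 1, cosine roll-off over the outer 30%
  of the radius) anchored at the centroids of randomly chosen parcels,
  with angular radii spanning 0.5–1.5× the nominal parcel radius, heights
  U(0.75, 1). Interiors are modulated by a band-pass random texture
  (difference of mesh-kernel smoothings of white noise at 0.8 and 2.0
  mesh spacings, standardized, applied as `clip(0.85 + 0.45·z, 0, 1)`),
  then each condition is max-scaled to [0, 1]. The active mask is the
  support `μ > 0`. Design intent: activation co-aligns with functional
  parcels (so parcel screening has realistic targets: with between-subject
  SD 1 and N = 30, a parcel is only detectable when its mean activation
  approaches saturation), the interior is a graded field with structure
  finer than the smoothing kernel but resolvable on the mesh (the regime
  in which data smoothing is biased while coefficient-space splines are
  not), and every condition contains one focal and one diffuse region.
- **Subjects** — `β_i = μ + γ_i` with `γ_{i,k} ~ N(0, σ_g²)` constant
  over space; subject noise variances `σ_i² ~ U(1, 5)`; `Y_i = Xβ_iᵀ + ε`
  with iid temporal noise. Effective SNR levels: σ_g² = 1 (high),
  3 (moderate), 5 (low).
- **Design** — interleaved 15 s on / 15 s off blocks per condition,
  canonical HRF, T = 200 volumes at TR = 1 s (T is a package default
  chosen to leave ample temporal degrees of freedom).
- **Seeding** — one master seed feeds named substreams (geometry, truth,
  subjects); identical configs are bit-for-bit reproducible.

The desk-scale default (V = 2000, P = 20, N = 30, K = 2) keeps ~100
vertices per parcel; a full-resolution configuration (32,492 vertices,
100 parcels) is provided but slower. What desk scale does **not**
preserve: the full-resolution surface has ~325 vertices per parcel, so
the spline variance cost M/V_p is about 3× higher here. Consequently the
spline model's decisive advantage over *kernel smoothing* carries over
(bias dominates GKS in both regimes), while its margin over the
*unsmoothed GLM* is regime-dependent: with the efficient default block
design the per-vertex GLM variance is small and the two are close;
with shorter runs (noisier GLMs) the spline model wins consistently, as
the test suite shows at T = 100. Passing tests therefore demonstrate the
mechanism and the error control, not the exact full-resolution margins.

Real-data features deliberately not emulated: motion and physiological
artifacts, drift, spatially correlated noise, inter-subject
misregistration, and hemodynamic variability across regions.

## Metrics and the benchmark harness

`evaluate` reports MSE against the truth, FPR over truly inactive
vertices, FNR over truly active ones, and ROC AUC from |t| scores.
`run_study` reports two MSEs: `mse`, the mean over subjects of the error
of each subject's map against that subject's own field `μ + γ_i`; and
`group_mse`, the group-average map against μ. The latter is floored at
`σ_g²/N ≈ 0.033` by the shared random effect regardless of estimator, so
method comparisons and the headline benchmark use the subject-level
definition, which is floor-free and on the scale of the per-vertex
estimation error. The High-SNR benchmark (`high_snr_benchmark`) reports
medians over 5 replicate studies of Task-1 MSE ×100 per method and the
spline/kernel MSE ratio in percent.

The smoothing-parameter robustness sweep (`sweep_robustness`) refits GKS
over a bandwidth grid (0.8–4.5 mesh spacings) and the spline model over a
fixed-M grid (6–32), per seed, and compares the spread of FNR across each
grid. Detection in this sweep runs at a conventional FDR level of 0.05:
at the liberal 0.5 default the comparator FNRs saturate at 0 and the
comparison degenerates. GKS bandwidth defaults to 1.275× the mesh
nearest-neighbor spacing, preserving the kernel-to-mesh ratio of a 6 mm
FWHM kernel on a 2 mm full-resolution surface.

## Known limitations

- Smoothing is Euclidean/chordal, not geodesic; across-sulci leakage is
  not modeled (parcel boundaries mitigate it for the spline model).
- Σ is block-diagonal by location: no spatial noise correlation.
- FGLS is one-step and p is user-set (no order selection).
- The BIC forms (spline dimension, AGKS bandwidth) are documented choices;
  no claim of equivalence to any other implementation's selector.
- Multi-basis (B > 1) inference is exposed per (k, l); combining
  coefficients into one activation decision is left to the user.
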