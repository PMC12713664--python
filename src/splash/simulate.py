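"""Synthetic surface fMRI generator and the simulation/evaluation harness.

The generator emulates a group task-fMRI study on a parcellated spherical
cortical surface: quasi-uniform vertices (Fibonacci lattice) partitioned
into Voronoi-style parcels; per-condition ground-truth activation fields
built from compact smooth bumps and scaled to [0, 1]; subject coefficient
maps ``beta_i = mu + gamma_i`` with a spatially constant random effect
``gamma_{i,k} ~ N(0, sigma_g^2)``; and BOLD series ``Y_i = X beta_i' + eps``
with iid temporal noise whose subject variance is drawn uniformly from a
configured range.  Effective SNR is controlled through sigma_g^2
(1 = high, 3 = moderate, 5 = low SNR).

``run_study`` chains the generator through the four estimation pipelines
(vertex GLM, fixed-bandwidth GKS, BIC-adaptive GKS, and spline-based
parcel regression) and group inference, and computes MSE / FPR / FNR / AUC,
optionally sweeping the GKS bandwidth and the spline dimension.

All randomness flows from a single master seed through named substreams
(geometry, truth, subjects, noise), so identical configs reproduce
identical datasets bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

from .gks import KernelSpec, attenuation_profile, smooth_timeseries, smoothing_matrix
from .hrf import DesignMatrix, StimulusTrain, build_basis, build_design
from .inference import GroupData, flat_bh_inference, selective_fdr
from .model import fit_vertex_glm
from .tps import ParcelGeometry, SplineBasis, build_tprs

__all__ = [
    "SimulationConfig",
    "SphereGeometry",
    "SimulatedDataset",
    "make_sphere_mesh",
    "make_truth_field",
    "block_stimuli",
    "simulate_subjects",
    "simulate_dataset",
    "default_bandwidth",
    "evaluate",
    "run_study",
]

#: ratio of the default kernel bandwidth to the mesh nearest-neighbor
#: spacing; mirrors a 2.55 mm bandwidth (FWHM 6 mm) on a ~2 mm-spacing
#: full-resolution surface mesh
BANDWIDTH_SPACING_RATIO = 1.275


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic surface experiment.

    Defaults are the desk-scale configuration: a 2,000-vertex sphere with 20
    parcels, 30 subjects, two conditions under a canonical HRF, 200 volumes
    at TR = 1 s, high-SNR between-subject variance ``sigma_g2 = 1`` and
    subject noise variances drawn from [1, 5].  ``paper_scale`` below gives
    the full-resolution analogue (32,492 vertices, 100 parcels).
    """

    n_vertices: int = 2000
    n_parcels: int = 20
    N: int = 30
    K: int = 2
    T: int = 200
    TR: float = 1.0
    sigma_g2: float = 1.0
    sigma_i2_range: tuple[float, float] = (1.0, 5.0)
    n_blobs: int = 3
    blob_scale: float = 1.0
    sphere_radius: float = 100.0
    block_on: float = 15.0
    block_off: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_vertices, self.n_parcels, self.N, self.K, self.T) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_parcels > self.n_vertices:
            raise ValueError("cannot have more parcels than vertices")
        if self.sigma_g2 < 0:
            raise ValueError("sigma_g2 must be non-negative")
        lo, hi = self.sigma_i2_range
        if not (0 < lo <= hi):
            raise ValueError("sigma_i2_range must be a positive interval")


def paper_scale(seed: int = 0) -> SimulationConfig:
    """The full-resolution configuration (slower; desk-scale is the default)."""
    return SimulationConfig(n_vertices=32492, n_parcels=100, seed=seed)


@dataclass(frozen=True)
class SphereGeometry:
    """Vertices on a sphere with integer parcel labels."""

    coords: np.ndarray  # [V x 3]
    parcel_labels: np.ndarray  # [V] int
    radius: float

    @property
    def V(self) -> int:
        return self.coords.shape[0]

    @property
    def parcels(self) -> np.ndarray:
        return np.unique(self.parcel_labels)

    def nn_spacing(self) -> float:
        """Mean nearest-neighbor distance (the mesh resolution scale)."""
        tree = cKDTree(self.coords)
        d, _ = tree.query(self.coords, k=2)
        return float(d[:, 1].mean())

    def parcel_geometry(self, pid: int) -> ParcelGeometry:
        idx = np.nonzero(self.parcel_labels == pid)[0]
        return ParcelGeometry(
            parcel_id=str(pid), vertex_ids=idx, coords=self.coords[idx]
        )


@dataclass
class SimulatedDataset:
    """Everything one simulated study produces."""

    geometry: SphereGeometry
    truth_mu: np.ndarray  # [V x K] in [0, 1]
    active_mask: np.ndarray  # [V x K] bool
    subject_beta: np.ndarray  # [N x V x K]
    gamma: np.ndarray  # [N x K] random effects
    sigma_i2: np.ndarray  # [N]
    Y: np.ndarray  # [N x T x V]
    X: DesignMatrix
    stimuli: list[StimulusTrain]
    config: SimulationConfig


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform deterministic lattice on the sphere."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return radius * pts


def make_sphere_mesh(
    n_vertices: int,
    n_parcels: int,
    seed: int,
    radius: float = 100.0,
    lloyd_iters: int = 8,
) -> SphereGeometry:
    """Fibonacci-lattice sphere partitioned into Voronoi parcels.

    Parcel centers start at randomly chosen vertices (seeded) and are relaxed
    by a few Lloyd iterations (assign nearest center, recenter on the parcel
    mean reprojected to the sphere) to give compact, roughly equal-area
    parcels.  Deterministic given the seed.
    """
    if n_parcels > n_vertices:
        raise ValueError("cannot have more parcels than vertices")
    coords = _fibonacci_sphere(n_vertices, radius)
    rng = np.random.default_rng(seed)
    centers = coords[rng.choice(n_vertices, size=n_parcels, replace=False)]
    for _ in range(lloyd_iters):
        labels = np.argmin(
            ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1
        )
        for p in range(n_parcels):
            members = coords[labels == p]
            if members.shape[0]:
                m = members.mean(axis=0)
                nrm = np.linalg.norm(m)
                if nrm > 0:
                    centers[p] = radius * m / nrm
    labels = np.argmin(
        ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1
    )
    # guarantee non-empty parcels: reseed any empty parcel on its nearest
    # unclaimed vertex (rare after Lloyd relaxation)
    for p in range(n_parcels):
        if not np.any(labels == p):
            big = np.bincount(labels, minlength=n_parcels).argmax()
            steal = np.nonzero(labels == big)[0]
            labels[steal[: max(1, steal.size // 2)]] = p
    return SphereGeometry(coords=coords, parcel_labels=labels, radius=radius)


def _cap_bump(
    coords: np.ndarray,
    center: np.ndarray,
    ang_radius: float,
    plateau_frac: float = 0.7,
) -> np.ndarray:
    """Plateau spherical cap with a cosine roll-off edge: compact, max 1.

    The bump is 1 inside ``plateau_frac * ang_radius`` and rolls smoothly to
    0 at ``ang_radius``, mimicking an activation region with an interior of
    full strength and a sharp (but continuous) boundary.
    """
    unit = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    c = center / np.linalg.norm(center)
    ang = np.arccos(np.clip(unit @ c, -1.0, 1.0))
    out = np.zeros(coords.shape[0])
    r0 = plateau_frac * ang_radius
    out[ang <= r0] = 1.0
    edge = (ang > r0) & (ang < ang_radius)
    out[edge] = 0.5 * (1.0 + np.cos(np.pi * (ang[edge] - r0) / (ang_radius - r0)))
    return out


def make_truth_field(
    geometry: SphereGeometry,
    K: int,
    n_blobs: int,
    blob_scale: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-condition smooth truth fields, compactly supported, scaled to [0, 1].

    Each condition receives ``n_blobs`` plateau caps anchored at the
    centroids of randomly chosen parcels (activation regions co-align with
    functional parcels).  Blob angular radii interpolate between half and
    1.5x the nominal parcel radius, so every condition contains one focal
    activation (sub-parcel diameter, hard to screen) and one diffuse one
    spilling into neighboring parcels.  Inside its support the field is not
    flat: it is modulated by a band-pass random texture (structure between
    the mesh scale and the kernel/parcel scale) saturating at full strength,
    emulating a generic smooth activation field with graded fine interior
    structure.  The active mask is the support ``mu > 0``.
    """
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    P = np.unique(geometry.parcel_labels).size
    theta_parcel = np.arccos(1.0 - 2.0 / P)  # cap radius of an equal-area parcel
    if n_blobs == 1:
        radii = np.array([theta_parcel])
    else:
        radii = np.linspace(0.5, 1.5, n_blobs) * theta_parcel
    radii = radii * blob_scale
    V = geometry.V
    spacing = geometry.nn_spacing()
    # band-pass random texture: structure between the mesh scale and the
    # parcel scale, i.e. fine-grained but resolvable activation detail
    W_fine = smoothing_matrix(geometry.coords, KernelSpec(h=0.8 * spacing))
    W_coarse = smoothing_matrix(geometry.coords, KernelSpec(h=2.0 * spacing))
    parcel_ids = np.unique(geometry.parcel_labels)
    centroids = np.stack(
        [geometry.coords[geometry.parcel_labels == p].mean(axis=0) for p in parcel_ids]
    )
    truth = np.zeros((V, K))
    for k in range(K):
        anchors = rng.choice(parcel_ids.size, size=min(n_blobs, parcel_ids.size),
                             replace=False)
        for r, a in zip(radii[::-1], anchors):
            height = rng.uniform(0.75, 1.0)
            truth[:, k] += height * _cap_bump(geometry.coords, centroids[a], r)
        lowpass = W_fine @ rng.normal(size=V)
        texture = lowpass - W_coarse @ lowpass
        texture = (texture - texture.mean()) / texture.std()
        # graded interior saturating at full strength
        truth[:, k] *= np.clip(0.85 + 0.45 * texture, 0.0, 1.0)
        mx = truth[:, k].max()
        if mx > 0:
            truth[:, k] /= mx
    truth = np.clip(truth, 0.0, 1.0)
    return truth, truth > 0


def block_stimuli(config: SimulationConfig) -> list[StimulusTrain]:
    """Interleaved block design: each condition cycles 15 s on / 15 s off.

    Condition k's blocks start at ``k*(on+off)`` within a cycle of length
    ``K*(on+off)``, so conditions never overlap.
    """
    cycle = config.K * (config.block_on + config.block_off)
    run_len = config.T * config.TR
    stims = []
    for k in range(config.K):
        onsets = np.arange(k * (config.block_on + config.block_off), run_len, cycle)
        onsets = onsets[onsets < run_len]
        stims.append(
            StimulusTrain(
                condition_id=f"task{k + 1}",
                onsets=onsets,
                durations=np.full(onsets.size, config.block_on),
            )
        )
    return stims


def simulate_subjects(
    truth_mu: np.ndarray,
    config: SimulationConfig,
    geometry: SphereGeometry,
    X: DesignMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Draw subject coefficient maps and BOLD series around a truth field."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    stims = block_stimuli(config)
    if X is None:
        basis = build_basis("canonical", 1, config.TR)
        X = build_design(stims, basis, config.T, config.TR)
    V, K = truth_mu.shape
    gamma = rng.normal(0.0, np.sqrt(config.sigma_g2), size=(config.N, K))
    sigma_i2 = rng.uniform(*config.sigma_i2_range, size=config.N)
    subject_beta = truth_mu[None, :, :] + gamma[:, None, :]
    Y = np.empty((config.N, config.T, V))
    for i in range(config.N):
        signal = X.X @ subject_beta[i].T  # T x V
        Y[i] = signal + rng.normal(0.0, np.sqrt(sigma_i2[i]), size=(config.T, V))
    return SimulatedDataset(
        geometry=geometry,
        truth_mu=truth_mu,
        active_mask=truth_mu > 0,
        subject_beta=subject_beta,
        gamma=gamma,
        sigma_i2=sigma_i2,
        Y=Y,
        X=X,
        stimuli=stims,
        config=config,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full generator: mesh, truth field, subjects, noise — one master seed."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    geom_seed = int(ss[0].generate_state(1)[0] % (2**31))
    truth_seed = int(ss[1].generate_state(1)[0] % (2**31))
    geometry = make_sphere_mesh(
        config.n_vertices, config.n_parcels, geom_seed, radius=config.sphere_radius
    )
    truth_mu, _ = make_truth_field(
        geometry, config.K, config.n_blobs, config.blob_scale, truth_seed
    )
    rng = np.random.default_rng(ss[2])
    return simulate_subjects(truth_mu, config, geometry, rng=rng)


def default_bandwidth(geometry: SphereGeometry) -> float:
    """Mesh-relative default GKS bandwidth (same kernel-to-spacing ratio as a
    6 mm FWHM kernel on a 2 mm full-resolution surface mesh)."""
    return BANDWIDTH_SPACING_RATIO * geometry.nn_spacing()


def evaluate(
    estimates: np.ndarray,
    detections: np.ndarray,
    truth_mu: np.ndarray,
    active_mask: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> dict[str, float]:
    """MSE / FPR / FNR / AUC of an estimated map and its detections.

    ``detections`` is a boolean mask shaped like the truth; ``scores``
    (optional, e.g. |t|) rank vertices for the ROC AUC.  Metrics whose
    reference set is empty are returned as NaN.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth_mu = np.asarray(truth_mu, dtype=float)
    if estimates.shape != truth_mu.shape:
        raise ValueError("estimates and truth must have the same shape")
    if active_mask is None:
        active_mask = truth_mu > 0
    detections = np.asarray(detections, dtype=bool)
    mse = float(np.mean((estimates - truth_mu) ** 2))
    act = active_mask.ravel()
    det = detections.ravel()
    n_act, n_inact = int(act.sum()), int((~act).sum())
    fpr = float(det[~act].sum() / n_inact) if n_inact else np.nan
    fnr = float((~det[act]).sum() / n_act) if n_act else np.nan
    if scores is None or n_act == 0 or n_inact == 0:
        auc = np.nan
    else:
        auc = float(roc_auc_score(act, np.asarray(scores, dtype=float).ravel()))
    return {"mse": mse, "fpr": fpr, "fnr": fnr, "auc": auc}


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

def _subject_mse(beta_hat: np.ndarray, subject_beta: np.ndarray) -> float:
    """Mean over subjects of the MSE against each subject's own truth field.

    Each subject's estimand is mu + gamma_i, so comparing per subject keeps
    the between-subject random effect out of the error (a group-average
    comparison against mu alone would be floored at sigma_g^2 / N even for a
    perfect estimator).
    """
    return float(np.mean((beta_hat - subject_beta) ** 2))


def _fit_glm_all(Y: np.ndarray, X: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vertex GLM for every subject: betas [N x V x KB], per-vertex RSS [N x V]."""
    N = Y.shape[0]
    betas = np.empty((N, Y.shape[2], X.KB))
    rss = np.empty((N, Y.shape[2]))
    for i in range(N):
        b, resid, _ = fit_vertex_glm(Y[i], X)
        betas[i] = b
        rss[i] = np.einsum("tv,tv->v", resid, resid)
    return betas, rss


def _splash_maps(
    data: SimulatedDataset,
    beta_glm: np.ndarray,
    rss_glm: np.ndarray,
    M_grid: Sequence[int] | None = None,
    M_fixed: int | None = None,
) -> tuple[np.ndarray, dict[int, int]]:
    """Spline-smoothed subject maps with per-parcel BIC selection of M.

    Uses the OLS reduction: per parcel, the spline fit projects the
    vertex-GLM coefficients onto the basis, and candidate-M residual sums
    follow from the projection defect without refitting the time series
    (``RSS_M = RSS_glm + tr(dB' X'X dB)``).  Returns the [N x V x KB] maps
    and the selected M per parcel.
    """
    geometry = data.geometry
    X = data.X
    XtX = X.X.T @ X.X
    N, _, V = data.Y.shape
    KB = X.KB
    T = X.T
    n_sel: dict[int, int] = {}
    beta_sp = np.empty((N, V, KB))
    logn_cache: dict[int, float] = {}
    for pid in geometry.parcels:
        geom = geometry.parcel_geometry(int(pid))
        vidx = geom.vertex_ids
        Vp = vidx.size
        if Vp < geom.null_dim + 2:
            # parcel too small for a spline model: fall back to the GLM
            beta_sp[:, vidx, :] = beta_glm[:, vidx, :]
            n_sel[int(pid)] = Vp
            continue
        if M_fixed is not None:
            grid = [min(M_fixed, Vp)]
        elif M_grid is not None:
            grid = sorted({min(int(m), Vp) for m in M_grid if m >= geom.null_dim + 1})
        else:
            from .model import default_m_grid

            grid = default_m_grid(Vp, geom.null_dim)
        M_max = max(grid)
        basis_full = build_tprs(geom, M_max)
        B_p = beta_glm[:, vidx, :]  # N x Vp x KB
        rss_p = rss_glm[:, vidx].sum(axis=1)  # N
        n = T * Vp
        logn = logn_cache.setdefault(n, float(np.log(n)))
        best = None
        for M in grid:
            S = basis_full.S[:, :M]
            proj = np.einsum("vm,nvc->nmc", S, B_p)  # N x M x KB
            fitted = np.einsum("vm,nmc->nvc", S, proj)
            delta = B_p - fitted
            extra = np.einsum("nvc,cd,nvd->n", delta, XtX, delta)
            rss_M = np.maximum(rss_p + extra, np.finfo(float).tiny * n)
            bic_total = float(
                np.sum(n * (np.log(2 * np.pi * rss_M / n) + 1.0) + KB * M * logn)
            )
            if best is None or bic_total < best[0] - 1e-9:
                best = (bic_total, M, fitted)
        _, M_star, fitted = best
        beta_sp[:, vidx, :] = fitted
        n_sel[int(pid)] = M_star
    return beta_sp, n_sel


def _group_metrics(
    maps: np.ndarray,
    data: SimulatedDataset,
    method: str,
    alpha_parcel: float,
    alpha_voxel: float,
) -> list[dict[str, float]]:
    """Group inference + evaluation, one row per task condition."""
    rows = []
    K = data.truth_mu.shape[1]
    for k in range(K):
        group = GroupData(beta=maps[:, :, k], parcel_labels=data.geometry.parcel_labels)
        t_flat, _, flat_rej = flat_bh_inference(group, alpha_voxel=alpha_voxel)
        det = np.zeros(data.geometry.V, dtype=bool)
        if method == "splash":
            res = selective_fdr(
                group, alpha_parcel=alpha_parcel, alpha_voxel=alpha_voxel
            )
            det[res.discoveries] = True
        else:
            det[flat_rej] = True
        m = evaluate(
            maps.mean(axis=0)[:, k],
            det,
            data.truth_mu[:, k],
            active_mask=data.active_mask[:, k],
            scores=np.abs(t_flat),
        )
        # group_mse: group-average map against the population field mu
        # (floored at sigma_g^2/N by the shared random effect); mse: mean per
        # subject against that subject's own field mu + gamma_i
        m["group_mse"] = m["mse"]
        m["mse"] = _subject_mse(maps[:, :, k], data.subject_beta[:, :, k])
        m["task"] = k + 1
        rows.append(m)
    return rows


def run_study(
    config: SimulationConfig,
    methods: Iterable[str] = ("glm", "gks", "agks", "splash"),
    sweep: Mapping[str, Sequence[float]] | None = None,
    alpha_parcel: float = 0.1,
    alpha_voxel: float = 0.5,
    data: SimulatedDataset | None = None,
) -> pd.DataFrame:
    """Simulate one study and score the requested methods.

    Returns a tidy frame with one row per (method, parameter, task):
    columns ``method, param, snr, task, mse, fpr, fnr, auc, m_median``.
    ``sweep`` may map ``"gks_h"`` to a bandwidth grid and/or ``"splash_M"``
    to fixed spline dimensions; swept rows carry the parameter value while
    adaptive rows have ``param = NaN``.
    """
    methods = list(methods)
    unknown = set(methods) - {"glm", "gks", "agks", "splash"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if data is None:
        data = simulate_dataset(config)
    geometry = data.geometry
    beta_glm, rss_glm = _fit_glm_all(data.Y, data.X)
    rows: list[dict] = []

    def add(method: str, param: float, maps: np.ndarray, m_median: float = np.nan):
        for m in _group_metrics(maps, data, method, alpha_parcel, alpha_voxel):
            rows.append(
                {
                    "method": method,
                    "param": param,
                    "snr": config.sigma_g2,
                    "m_median": m_median,
                    **m,
                }
            )

    if "glm" in methods:
        add("glm", np.nan, beta_glm)

    def gks_maps(h: float) -> np.ndarray:
        spec = KernelSpec(h=h)
        W = smoothing_matrix(geometry.coords, spec)
        out = np.empty_like(beta_glm)
        for i in range(data.config.N):
            Ys = smooth_timeseries(data.Y[i], geometry.coords, spec, W=W)
            out[i], _, _ = fit_vertex_glm(Ys, data.X)
        return out

    if "gks" in methods:
        h0 = default_bandwidth(geometry)
        add("gks", h0, gks_maps(h0))
        for h in (sweep or {}).get("gks_h", []):
            add("gks", float(h), gks_maps(float(h)))

    if "agks" in methods:
        add("agks", np.nan, _agks_maps(data, alpha_voxel))

    if "splash" in methods:
        maps, n_sel = _splash_maps(data, beta_glm, rss_glm)
        add("splash", np.nan, maps, m_median=float(np.median(list(n_sel.values()))))
        for M in (sweep or {}).get("splash_M", []):
            maps_M, _ = _splash_maps(data, beta_glm, rss_glm, M_fixed=int(M))
            add("splash", float(M), maps_M, m_median=float(M))

    return pd.DataFrame(rows)


def _agks_maps(data: SimulatedDataset, alpha_voxel: float) -> np.ndarray:
    """Adaptive GKS: per-parcel BIC bandwidth selection over a spacing-relative
    grid, then GLM on data smoothed with each parcel's winner."""
    geometry = data.geometry
    spacing = geometry.nn_spacing()
    h_grid = spacing * np.array([0.8, 1.275, 2.0, 3.0, 4.5])
    N, _, V = data.Y.shape
    KB = data.X.KB
    T = data.X.T
    # precompute per-h smoothed GLM results once, then pick per parcel
    per_h_beta = {}
    per_h_rss = {}
    per_h_att = {}
    for h in h_grid:
        spec = KernelSpec(h=float(h))
        W = smoothing_matrix(geometry.coords, spec)
        betas = np.empty((N, V, KB))
        rss = np.empty((N, V))
        for i in range(N):
            Ys = smooth_timeseries(data.Y[i], geometry.coords, spec, W=W)
            b, _, _ = fit_vertex_glm(Ys, data.X)
            betas[i] = b
            # likelihood scored against the unsmoothed data; see
            # gks.select_bandwidth_bic
            resid = data.Y[i] - data.X.X @ b.T
            rss[i] = np.einsum("tv,tv->v", resid, resid)
        per_h_beta[h] = betas
        per_h_rss[h] = rss
        per_h_att[h] = attenuation_profile(W)
    out = np.empty((N, V, KB))
    for pid in geometry.parcels:
        vidx = np.nonzero(geometry.parcel_labels == pid)[0]
        n = T * vidx.size
        best = None
        for h in h_grid:
            v_eff = float(per_h_att[h][vidx].sum())
            rss_p = per_h_rss[h][:, vidx].sum(axis=1)
            rss_p = np.maximum(rss_p, np.finfo(float).tiny * n)
            total = float(
                np.sum(n * (np.log(2 * np.pi * rss_p / n) + 1.0) + KB * v_eff * np.log(n))
            )
            if best is None or total < best[0] - 1e-12:
                best = (total, h)
        out[:, vidx, :] = per_h_beta[best[1]][:, vidx, :]
    return out


def fdr_calibration_study(
    n_reps: int = 500,
    seed: int = 0,
    n_parcels: int = 20,
    vertices_per_parcel: int = 100,
    N: int = 30,
    n_active_parcels: int = 5,
    active_fraction: float = 0.3,
    effect: float = 0.5,
    subject_sd: float = 1.0,
    alpha_parcel: float = 0.1,
    alpha_voxel: float = 0.5,
) -> dict[str, float]:
    """Monte-Carlo calibration of the two-stage selective procedure.

    Replicates a mixed group setting at the activation-map level: P parcels
    of equal size, a subset containing active vertices (``active_fraction``
    of their vertices at mean ``effect``), subject maps perturbed by iid
    N(0, subject_sd^2) noise per vertex.  For each replicate the two-stage
    procedure runs and two error rates are recorded: the average false
    discovery proportion (FDP) across selected parcels (0 when none is
    selected) and the stage-1 parcel-level FDP (fraction of selected parcels
    that are truly null).  Their Monte-Carlo means estimate the selective
    FDR guarantee (bounded by alpha_voxel) and the screening FDR (bounded by
    alpha_parcel).
    """
    rng = np.random.default_rng(seed)
    V = n_parcels * vertices_per_parcel
    labels = np.repeat(np.arange(n_parcels), vertices_per_parcel)
    mu = np.zeros(V)
    active_parcels = np.arange(n_active_parcels)
    n_active_v = int(round(active_fraction * vertices_per_parcel))
    for p in active_parcels:
        mu[p * vertices_per_parcel : p * vertices_per_parcel + n_active_v] = effect
    truly_active = mu != 0
    null_parcels = set(range(n_active_parcels, n_parcels))
    avg_fdp = np.empty(n_reps)
    parcel_fdp = np.empty(n_reps)
    power = np.empty(n_reps)
    for r in range(n_reps):
        beta = mu[None, :] + rng.normal(0.0, subject_sd, size=(N, V))
        res = selective_fdr(
            GroupData(beta=beta, parcel_labels=labels),
            alpha_parcel=alpha_parcel,
            alpha_voxel=alpha_voxel,
        )
        if res.n_selected == 0:
            avg_fdp[r] = 0.0
            parcel_fdp[r] = 0.0
            power[r] = 0.0
            continue
        fdps = []
        for pid in res.selected:
            in_parcel = res.discoveries[labels[res.discoveries] == pid]
            n_disc = in_parcel.size
            n_false = int((~truly_active[in_parcel]).sum())
            fdps.append(n_false / n_disc if n_disc else 0.0)
        avg_fdp[r] = float(np.mean(fdps))
        parcel_fdp[r] = sum(p in null_parcels for p in res.selected) / res.n_selected
        power[r] = float(truly_active[res.discoveries].sum() / truly_active.sum())
    return {
        "selective_fdr": float(avg_fdp.mean()),
        "selective_fdr_se": float(avg_fdp.std(ddof=1) / np.sqrt(n_reps)),
        "parcel_fdr": float(parcel_fdp.mean()),
        "parcel_fdr_se": float(parcel_fdp.std(ddof=1) / np.sqrt(n_reps)),
        "mean_power": float(power.mean()),
        "n_reps": n_reps,
    }


def high_snr_benchmark(
    seed: int = 1,
    n_replicates: int = 5,
    config: SimulationConfig | None = None,
) -> dict[str, float]:
    """Estimation benchmark at the High-SNR study conditions.

    Runs ``n_replicates`` independent studies (seeds derived from ``seed``)
    at the desk-scale High-SNR configuration (sigma_g^2 = 1, N = 30), fits
    the vertex GLM, fixed-bandwidth kernel smoothing and the spline model
    with BIC-selected dimension, and reports the median over replicates of:
    Task-1 MSE x100 for each method (mean over subjects of the error against
    each subject's own activation field) and the spline/kernel MSE ratio in
    percent.
    """
    if config is None:
        config = SimulationConfig(sigma_g2=1.0, N=30)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    splash_mse, gks_mse, glm_mse = [], [], []
    for s in seeds:
        cfg = replace(config, seed=int(s))
        df = run_study(cfg, methods=("glm", "gks", "splash"))
        t1 = df[df["task"] == 1].set_index("method")
        splash_mse.append(100 * t1.loc["splash", "mse"])
        gks_mse.append(100 * t1.loc["gks", "mse"])
        glm_mse.append(100 * t1.loc["glm", "mse"])
    splash_mse = np.asarray(splash_mse)
    gks_mse = np.asarray(gks_mse)
    return {
        "splash_mse_x100": float(np.median(splash_mse)),
        "gks_mse_x100": float(np.median(gks_mse)),
        "glm_mse_x100": float(np.median(glm_mse)),
        "splash_gks_ratio_pct": float(np.median(100 * splash_mse / gks_mse)),
        "n_replicates": n_replicates,
    }


def sweep_robustness(
    config: SimulationConfig,
    seeds: Sequence[int],
    h_factors: Sequence[float] = (0.8, 1.275, 2.0, 3.0, 4.5),
    M_values: Sequence[int] = (6, 8, 12, 16, 24, 32),
    alpha_parcel: float = 0.1,
    alpha_voxel: float = 0.5,
) -> pd.DataFrame:
    """Smoothing-parameter robustness: sweep h (GKS) and M (splines) per seed.

    Returns the concatenated tidy results over seeds with a ``seed`` column;
    downstream summaries compare the spread (e.g. coefficient of variation of
    FNR) across each method's parameter grid.
    """
    frames = []
    for seed in seeds:
        cfg = replace(config, seed=int(seed))
        data = simulate_dataset(cfg)
        spacing = data.geometry.nn_spacing()
        sweep = {
            "gks_h": [f * spacing for f in h_factors],
            "splash_M": list(M_values),
        }
        df = run_study(
            cfg,
            methods=("gks", "splash"),
            sweep=sweep,
            alpha_parcel=alpha_parcel,
            alpha_voxel=alpha_voxel,
            data=data,
        )
        df = df[df["param"].notna()].copy()
        df["seed"] = int(seed)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
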