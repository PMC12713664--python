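"""Parcel-wise spline regression: structured OLS/FGLS with AR(p) noise and BIC.

Within a parcel the stacked model is ``Y = Z P Phi Gamma + eps`` with
``Z = I_V (x) X`` (one GLM design block per location), ``P`` the permutation
from location-major to basis-major coefficient ordering, and
``Phi = I_KB (x) S`` the spatial spline expansion.  The operator
``A = Z P Phi`` is never materialized: its normal equations decompose over
locations as ``A' Sigma^-1 A = sum_v (X' Sigma_v^-1 X) (x) (s_v s_v')`` where
``s_v`` is row v of S, which the fitter accumulates directly.

Noise is temporal AR(p), independent across locations, estimated per
location from vertex-GLM residuals by Yule-Walker; whitening uses the exact
banded Cholesky factor of the AR precision (Levinson-Durbin for the first p
rows), O(T p) per series.

Coefficient ordering conventions (realizing P):
  location-major index  = v*KB + c          (c = k*B + l)
  basis-major index     = c*V + v
  spline-coef index     = c*M + m
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import toeplitz
from scipy.signal import lfilter
from statsmodels.regression.linear_model import yule_walker as _sm_yule_walker

from .hrf import DesignMatrix
from .tps import SplineBasis

__all__ = [
    "NoiseModel",
    "ParcelDesign",
    "SubjectFit",
    "fit_vertex_glm",
    "yule_walker_ar",
    "ar_whiten",
    "estimate_noise",
    "fit_splash",
    "bic_score",
    "select_basis_dim",
]

#: relative condition threshold beyond which normal matrices count as singular
COND_TOL = 1e12


# ---------------------------------------------------------------------------
# vertex-wise GLM
# ---------------------------------------------------------------------------

def _clean_design(X: DesignMatrix, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Project nuisance columns out of both Y and the task regressors.

    Returns the cleaned task matrix, cleaned Y, and the residual dof lost to
    nuisance (J).  Task-column count KB never includes nuisance.
    """
    Xt = X.X
    J = X.n_nuisance
    if J:
        Q, _ = np.linalg.qr(X.nuisance)
        Xt = Xt - Q @ (Q.T @ Xt)
        Y = Y - Q @ (Q.T @ Y)
    return Xt, Y, J


def fit_vertex_glm(
    Y: np.ndarray, X: DesignMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordinary least squares per location.

    Returns ``(beta [V x KB], residuals [T x V], sigma2 [V])`` with
    ``sigma2 = ||residual||^2 / (T - KB - J)``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2 or Y.shape[0] != X.T:
        raise ValueError("Y must be [T x V]")
    Xt, Yc, J = _clean_design(X, Y)
    KB = Xt.shape[1]
    if X.T <= KB + J:
        raise ValueError("T must exceed the number of regressors")
    Q, R = np.linalg.qr(Xt)
    diag = np.abs(np.diag(R))
    bad = diag < diag.max() * 1e-10 if diag.max() > 0 else np.ones(KB, bool)
    if bad.any():
        names = [X.column_labels[j] for j in np.nonzero(bad)[0]]
        raise np.linalg.LinAlgError(f"design matrix is rank deficient; collinear columns: {names}")
    beta = np.linalg.solve(R, Q.T @ Yc).T  # V x KB
    resid = Yc - Xt @ beta.T
    sigma2 = np.einsum("tv,tv->v", resid, resid) / (X.T - KB - J)
    return beta, resid, sigma2


# ---------------------------------------------------------------------------
# AR(p) noise
# ---------------------------------------------------------------------------

def yule_walker_ar(residuals: np.ndarray, p: int) -> tuple[np.ndarray, float]:
    """Yule-Walker AR(p) fit of one residual series.

    Uses biased (positive-definite) sample autocovariances, which guarantees
    a stationary AR polynomial; a safeguard shrinks the coefficients toward 0
    with a warning if numerical round-off ever leaves roots on the circle.
    """
    x = np.asarray(residuals, dtype=float)
    if x.ndim != 1:
        raise ValueError("residuals must be a 1-D series")
    if p < 0:
        raise ValueError("p must be non-negative")
    if p == 0:
        return np.empty(0), float(np.mean(x**2))
    if x.size <= 10 * p:
        raise ValueError(f"need T > 10*p observations (T={x.size}, p={p})")
    if np.allclose(x, x[0]):
        # degenerate constant series
        return np.zeros(p), 0.0
    rho, sigma = _sm_yule_walker(x, order=p, method="mle", demean=False)
    if not _is_stationary(rho):
        import warnings

        warnings.warn("Yule-Walker produced non-stationary coefficients; shrinking", stacklevel=2)
        while not _is_stationary(rho):
            rho = rho * 0.99
    return rho, float(sigma**2)


def _is_stationary(ar_coeffs: np.ndarray) -> bool:
    if ar_coeffs.size == 0:
        return True
    roots = np.roots(np.concatenate([[1.0], -np.asarray(ar_coeffs)]))
    return bool(np.all(np.abs(roots) < 1.0 - 1e-10))


def _ar_autocov(ar_coeffs: np.ndarray, innovation_var: float, nlags: int) -> np.ndarray:
    """Theoretical autocovariances gamma_0..gamma_nlags of a stationary AR(p)."""
    p = ar_coeffs.size
    if p == 0:
        g = np.zeros(nlags + 1)
        g[0] = innovation_var
        return g
    # solve the Yule-Walker system for gamma_0..gamma_p
    n = p + 1
    Amat = np.zeros((n, n))
    bvec = np.zeros(n)
    Amat[0, 0] = 1.0
    for i, phi in enumerate(ar_coeffs, start=1):
        Amat[0, i] -= phi
    bvec[0] = innovation_var
    for k in range(1, n):
        Amat[k, k] += 1.0
        for i, phi in enumerate(ar_coeffs, start=1):
            Amat[k, abs(k - i)] -= phi
        bvec[k] = 0.0
    g = np.zeros(max(nlags + 1, n))
    g[:n] = np.linalg.solve(Amat, bvec)
    for k in range(n, nlags + 1):
        g[k] = ar_coeffs @ g[k - 1 : k - 1 - p : -1] if p else 0.0
    return g[: nlags + 1]


def _levinson_prefix(gamma: np.ndarray, p: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Order-j predictor coefficients and innovation variances, j = 0..p.

    Standard Levinson-Durbin recursion on the autocovariance sequence; the
    order-j coefficients whiten observation j given the j preceding ones.
    """
    coeffs: list[np.ndarray] = [np.empty(0)]
    v = np.empty(p + 1)
    v[0] = gamma[0]
    a = np.empty(0)
    for j in range(1, p + 1):
        acc = gamma[j] - (a @ gamma[j - 1 : 0 : -1] if j > 1 else 0.0)
        k = acc / v[j - 1]
        a_new = np.empty(j)
        a_new[:-1] = a - k * a[::-1]
        a_new[-1] = k
        v[j] = v[j - 1] * (1.0 - k * k)
        coeffs.append(a_new)
        a = a_new
    return coeffs, v


def ar_whiten(
    series_or_matrix: np.ndarray,
    ar_coeffs: np.ndarray,
    innovation_var: float,
) -> np.ndarray:
    """Apply the banded Cholesky whitening factor L (L' L = Sigma^-1).

    Rows >= p are the scaled AR innovations ``(x_t - sum phi_i x_{t-i}) /
    sigma``; the first p rows use the exact order-t predictors from the
    Levinson-Durbin recursion, so ``L Sigma L' = I`` exactly in finite
    samples.  O(T p) per column.
    """
    x = np.asarray(series_or_matrix, dtype=float)
    ar_coeffs = np.asarray(ar_coeffs, dtype=float)
    p = ar_coeffs.size
    if innovation_var < 0:
        raise ValueError("innovation variance must be non-negative")
    if not _is_stationary(ar_coeffs):
        raise ValueError("AR coefficients are not stationary")
    sd = np.sqrt(innovation_var)
    if p == 0:
        return x / sd
    vec = x.ndim == 1
    X = x[:, None] if vec else x
    T = X.shape[0]
    out = lfilter(np.concatenate([[1.0], -ar_coeffs]), [1.0], X, axis=0) / sd
    gamma = _ar_autocov(ar_coeffs, innovation_var, p)
    coeffs, v = _levinson_prefix(gamma, p)
    for t in range(min(p, T)):
        pred = coeffs[t] @ X[t - 1 :: -1][:t] if t else 0.0
        out[t] = (X[t] - pred) / np.sqrt(v[t])
    return out[:, 0] if vec else out


@dataclass
class NoiseModel:
    """Per-location AR(p) noise: coefficients [V x p], innovation variances [V]."""

    p: int
    ar_coeffs: np.ndarray
    innovation_var: np.ndarray
    T: int
    degenerate: np.ndarray = field(default=None)  # flags, set in __post_init__

    def __post_init__(self) -> None:
        self.ar_coeffs = np.atleast_2d(np.asarray(self.ar_coeffs, dtype=float))
        self.innovation_var = np.asarray(self.innovation_var, dtype=float)
        if self.degenerate is None:
            self.degenerate = self.innovation_var <= 0
        for v in range(self.ar_coeffs.shape[0]):
            if not _is_stationary(self.ar_coeffs[v]):
                raise ValueError(f"non-stationary AR polynomial at location {v}")

    @property
    def V(self) -> int:
        return self.innovation_var.shape[0]

    def whiten(self, Y: np.ndarray) -> np.ndarray:
        """Whiten columns of a [T x V] matrix, each with its own AR model."""
        Y = np.asarray(Y, dtype=float)
        out = np.empty_like(Y)
        for v in range(Y.shape[1]):
            out[:, v] = ar_whiten(Y[:, v], self.ar_coeffs[v], self.innovation_var[v])
        return out

    def whiten_design(self, X: np.ndarray, v: int) -> np.ndarray:
        return ar_whiten(X, self.ar_coeffs[v], self.innovation_var[v])

    def covariance(self, v: int) -> np.ndarray:
        """Dense T x T Toeplitz covariance at location v (for small-T checks)."""
        g = _ar_autocov(self.ar_coeffs[v], self.innovation_var[v], self.T - 1)
        return toeplitz(g)

    def logdet(self, v: int) -> float:
        """log |Sigma_v| from the Levinson innovation variances."""
        p = self.ar_coeffs.shape[1]
        if p == 0:
            return self.T * np.log(self.innovation_var[v])
        g = _ar_autocov(self.ar_coeffs[v], self.innovation_var[v], p)
        _, vj = _levinson_prefix(g, p)
        return float(np.sum(np.log(vj[:p])) + (self.T - p) * np.log(self.innovation_var[v]))


def estimate_noise(residuals: np.ndarray, p: int) -> NoiseModel:
    """Fit an AR(p) model to each column of a [T x V] residual matrix.

    Zero-variance (constant) residual series are flagged degenerate and get
    unit-weight whitening (zero AR coefficients, unit variance) so that
    downstream GLS stays well defined.
    """
    residuals = np.asarray(residuals, dtype=float)
    T, V = residuals.shape
    coeffs = np.zeros((V, p))
    ivar = np.empty(V)
    for v in range(V):
        c, s2 = yule_walker_ar(residuals[:, v], p)
        coeffs[v, :] = c
        ivar[v] = s2
    degenerate = ivar <= 0
    coeffs[degenerate] = 0.0
    ivar[degenerate] = 1.0
    return NoiseModel(
        p=p, ar_coeffs=coeffs, innovation_var=ivar, T=T, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# structured SPLASH fit
# ---------------------------------------------------------------------------

@dataclass
class ParcelDesign:
    """Pairing of a GLM design X with a parcel spline basis S.

    Provides the documented index maps realizing the permutation P, and a
    dense materialization of A = Z P Phi for small-instance verification.
    """

    X: DesignMatrix
    S: SplineBasis

    @property
    def KB(self) -> int:
        return self.X.KB

    @property
    def V(self) -> int:
        return self.S.V

    @property
    def M(self) -> int:
        return self.S.M

    @staticmethod
    def loc_major_index(v: int, c: int, KB: int) -> int:
        return v * KB + c

    @staticmethod
    def basis_major_index(c: int, v: int, V: int) -> int:
        return c * V + v

    def permutation(self) -> np.ndarray:
        """P as an index array: loc_major[i] = basis_major[perm[i]]."""
        KB, V = self.KB, self.V
        perm = np.empty(KB * V, dtype=int)
        for v in range(V):
            for c in range(KB):
                perm[self.loc_major_index(v, c, KB)] = self.basis_major_index(c, v, V)
        return perm

    def materialize_A(self) -> np.ndarray:
        """Dense [T*V x KB*M] operator A = Z P Phi (small parcels only)."""
        X, S = self.X.X, self.S.S
        T, KB = X.shape
        V, M = S.shape
        A = np.empty((T * V, KB * M))
        for v in range(V):
            A[v * T : (v + 1) * T, :] = np.kron(X, S[v][None, :])
        return A


@dataclass
class SubjectFit:
    """Per-subject, per-parcel SPLASH fit."""

    parcel_id: str
    M: int
    gamma_hat: np.ndarray  # [KB*M], (k,l)-major then spline index
    beta_sp: np.ndarray  # [V x KB]
    vertex_beta: np.ndarray  # [V x KB] unsmoothed GLM estimates
    var_gamma: np.ndarray  # [KB*M x KB*M]
    var_beta_sp: np.ndarray  # [V x KB]
    noise: NoiseModel | None
    estimator: str
    rss: float
    sigma2: float | None = None  # pooled variance (OLS)
    bic: float = np.nan
    fallback_glm: bool = False


def fit_splash(
    Y: np.ndarray,
    design: ParcelDesign,
    estimator: str = "ols",
    noise: NoiseModel | None = None,
    ar_order: int = 1,
    vertex_fit: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    parcel_id: str = "",
) -> SubjectFit:
    """Fit the parcel spline model for one subject.

    ``estimator='ols'`` assumes a common iid noise variance, under which the
    structured estimator reduces exactly to projecting the vertex-GLM
    coefficients onto the spline basis (``Gamma_c = S' beta_hat_c`` for
    orthonormal S).  ``estimator='fgls'`` whitens each location by its AR(p)
    model (estimated from vertex-GLM residuals when ``noise`` is None) and
    accumulates the Kronecker-structured normal equations without ever
    materializing A = Z P Phi.
    """
    Y = np.asarray(Y, dtype=float)
    X = design.X
    S = design.S.S
    V, M = S.shape
    KB = X.KB
    T = X.T
    if Y.shape != (T, V):
        raise ValueError(f"Y must be [T x V] = [{T} x {V}]")
    if KB * M >= T * V:
        raise ValueError("KB*M must be smaller than T*V")

    if vertex_fit is None:
        vertex_fit = fit_vertex_glm(Y, X)
    beta_glm, resid_glm, _ = vertex_fit
    Xt, Yc, _ = _clean_design(X, Y)

    if estimator == "ols":
        G = beta_glm.T @ S  # KB x M
        beta_sp = S @ G.T  # V x KB
        XtX = Xt.T @ Xt
        delta = beta_glm - beta_sp
        rss = float(np.sum(resid_glm**2) + np.einsum("vc,cd,vd->", delta, XtX, delta))
        dof = T * V - KB * M
        sigma2 = rss / dof
        XtX_inv = np.linalg.inv(XtX)
        var_gamma = sigma2 * np.kron(XtX_inv, np.eye(M))
        row_norm2 = np.sum(S * S, axis=1)
        var_beta_sp = sigma2 * np.outer(row_norm2, np.diag(XtX_inv))
        gamma_hat = G.reshape(-1)
        noise_out = noise
    elif estimator == "fgls":
        if noise is None:
            noise = estimate_noise(resid_glm, ar_order)
        KBM = KB * M
        H = np.zeros((KBM, KBM))
        b = np.zeros(KBM)
        for v in range(V):
            Xw = noise.whiten_design(Xt, v)
            yw = ar_whiten(Yc[:, v], noise.ar_coeffs[v], noise.innovation_var[v])
            Cv = Xw.T @ Xw
            dv = Xw.T @ yw
            sv = S[v]
            H += np.kron(Cv, np.outer(sv, sv))
            b += np.kron(dv, sv)
        # guard against singular accumulated normal equations
        w = np.linalg.eigvalsh(H)
        if w[0] <= 0 or w[-1] / max(w[0], np.finfo(float).tiny) > COND_TOL:
            raise np.linalg.LinAlgError(
                f"singular structured normal matrix in parcel {parcel_id!r}"
            )
        var_gamma = np.linalg.inv(H)
        gamma_hat = var_gamma @ b
        G = gamma_hat.reshape(KB, M)
        beta_sp = S @ G.T
        var_beta_sp = np.empty((V, KB))
        for c in range(KB):
            block = var_gamma[c * M : (c + 1) * M, c * M : (c + 1) * M]
            var_beta_sp[:, c] = np.einsum("vm,mn,vn->v", S, block, S)
        rss = float(np.sum((Yc - Xt @ beta_sp.T) ** 2))
        sigma2 = None
        noise_out = noise
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    return SubjectFit(
        parcel_id=parcel_id,
        M=M,
        gamma_hat=gamma_hat,
        beta_sp=beta_sp,
        vertex_beta=beta_glm,
        var_gamma=var_gamma,
        var_beta_sp=var_beta_sp,
        noise=noise_out,
        estimator=estimator,
        rss=rss,
        sigma2=sigma2,
    )


def bic_score(Y: np.ndarray, design: ParcelDesign, fit: SubjectFit) -> float:
    """BIC = -2 loglik + k log n with n = T*V and k = KB*M.

    For OLS the Gaussian likelihood is concentrated over the common variance;
    for FGLS it is evaluated under the fitted AR(p) noise model.
    """
    Y = np.asarray(Y, dtype=float)
    T, V = Y.shape
    n = T * V
    k = design.KB * design.S.M
    if fit.estimator == "ols":
        rss = max(fit.rss, np.finfo(float).tiny * n)
        neg2ll = n * (np.log(2 * np.pi * rss / n) + 1.0)
    else:
        noise = fit.noise
        Xt, Yc, _ = _clean_design(design.X, Y)
        R = Yc - Xt @ fit.beta_sp.T
        quad = 0.0
        logdet = 0.0
        for v in range(V):
            rw = ar_whiten(R[:, v], noise.ar_coeffs[v], noise.innovation_var[v])
            quad += float(rw @ rw)
            logdet += noise.logdet(v)
        neg2ll = n * np.log(2 * np.pi) + logdet + quad
    return float(neg2ll + k * np.log(n))


def select_basis_dim(
    Y_subjects: Sequence[np.ndarray],
    design_factory: Callable[[int], ParcelDesign],
    M_grid: Sequence[int],
    estimator: str = "ols",
    ar_order: int = 1,
) -> tuple[int, list[SubjectFit]]:
    """Select one shared spline dimension per parcel by summed BIC.

    For each candidate M the per-subject BICs are summed; the minimizer is
    returned (ties break to the smaller M) together with the per-subject fits
    at the selected dimension.
    """
    M_grid = sorted(set(int(m) for m in M_grid))
    if not M_grid:
        raise ValueError("M_grid must be non-empty")
    best = None
    for M in M_grid:
        design = design_factory(M)
        fits = []
        total = 0.0
        for Y in Y_subjects:
            f = fit_splash(Y, design, estimator=estimator, ar_order=ar_order)
            f.bic = bic_score(Y, design, f)
            total += f.bic
            fits.append(f)
        if best is None or total < best[0] - 1e-12:
            best = (total, M, fits)
    return best[1], best[2]


def default_m_grid(V: int, null_dim: int, n_points: int = 8, cap: int = 100) -> list[int]:
    """Geometric grid of candidate spline dimensions in [null_dim+1, min(V, cap)]."""
    lo, hi = null_dim + 1, min(V, cap)
    if hi <= lo:
        return [hi] if hi >= null_dim else []
    grid = np.unique(
        np.round(np.geomspace(lo, hi, num=min(n_points, hi - lo + 1))).astype(int)
    )
    return [int(g) for g in grid]
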