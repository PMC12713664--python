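"""Low-rank thin-plate regression spline (TPRS) bases on arbitrary coordinates.

Within each parcel the activation field over the V member locations is
modeled as ``beta = S gamma`` with S a V x M spline design matrix.  S is the
low-rank eigen-truncation of the thin-plate radial-kernel matrix: keep the
leading M - (d+1) eigenvectors of E_ij = eta(||x_i - x_j||), append the
polynomial null space [1, x_1, ..., x_d], and orthonormalize.  M itself acts
as the smoothing control (selected elsewhere by BIC); the basis is used
unpenalized.

Distances are Euclidean in the coordinate embedding, so spherical surfaces
are handled through their 3-D embedding (chordal distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ParcelGeometry", "SplineBasis", "tps_kernel", "build_tprs", "project_field"]


@dataclass(frozen=True)
class ParcelGeometry:
    """Coordinates of the locations making up one parcel.

    Duplicate coordinate rows are collapsed (with a warning) since coincident
    points make the spline kernel degenerate.
    """

    parcel_id: str
    vertex_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        vids = np.asarray(self.vertex_ids)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError("coords must be [V x d] with d in {2, 3}")
        if coords.shape[0] < 1:
            raise ValueError("parcel must contain at least one location")
        if vids.shape[0] != coords.shape[0]:
            raise ValueError("vertex_ids must match coords in length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        _, keep = np.unique(coords, axis=0, return_index=True)
        if keep.size < coords.shape[0]:
            warnings.warn(
                f"parcel {self.parcel_id!r}: collapsed "
                f"{coords.shape[0] - keep.size} duplicated coordinate rows",
                stacklevel=2,
            )
            keep = np.sort(keep)
            coords = coords[keep]
            vids = vids[keep]
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "vertex_ids", vids)

    @property
    def V(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def null_dim(self) -> int:
        """Dimension of the polynomial (constant + linear) null space."""
        return self.d + 1


@dataclass(frozen=True)
class SplineBasis:
    """Orthonormal V x M TPRS design matrix with construction metadata."""

    S: np.ndarray
    M: int
    null_dim: int
    eigen_spectrum: np.ndarray
    geometry: ParcelGeometry

    @property
    def V(self) -> int:
        return self.S.shape[0]


def tps_kernel(r: np.ndarray | float, d: int) -> np.ndarray | float:
    """Second-order thin-plate radial kernel.

    ``d=2``: eta(r) = r^2 log r (0 at r = 0); ``d=3``: eta(r) = -r.  The
    proportionality constants are fixed to 1 (resp. -1); they only rescale the
    eigen-spectrum and never change the retained span.
    """
    if d not in (2, 3):
        raise ValueError(f"unsupported dimension d={d}; expected 2 or 3")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    if d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
    else:
        out = -r
    return out if out.ndim else float(out)


def _orthonormal_greedy(columns: np.ndarray, M: int, tol: float = 1e-10) -> np.ndarray:
    """First M independent columns, orthonormalized in priority order.

    Modified Gram-Schmidt that skips near-dependent columns, so the result
    always has rank M when the input span allows it.
    """
    V = columns.shape[0]
    Q = np.empty((V, M))
    got = 0
    scale = np.linalg.norm(columns, axis=0).max()
    for j in range(columns.shape[1]):
        if got == M:
            break
        v = columns[:, j].copy()
        for _ in range(2):  # re-orthogonalize for stability
            v -= Q[:, :got] @ (Q[:, :got].T @ v)
        nrm = np.linalg.norm(v)
        if nrm <= tol * max(scale, 1.0):
            continue
        Q[:, got] = v / nrm
        got += 1
    if got < M:
        raise ValueError(f"could not build {M} independent basis columns (got {got})")
    return Q


def build_tprs(geom: ParcelGeometry, M: int) -> SplineBasis:
    """Build the rank-M TPRS design matrix for one parcel.

    Deterministic given coordinates and M: the kernel eigenvectors are sorted
    by decreasing |eigenvalue| with the sign fixed so each vector's
    largest-magnitude entry is positive, and the polynomial columns are
    orthonormalized first so the null space is always inside the span.
    """
    V, d = geom.V, geom.d
    null_dim = geom.null_dim
    if M < null_dim:
        raise ValueError(f"M={M} below the polynomial null-space dimension {null_dim}")
    if M > V:
        raise ValueError(f"M={M} exceeds the parcel size V={V}")
    diff = geom.coords[:, None, :] - geom.coords[None, :, :]
    E = tps_kernel(np.linalg.norm(diff, axis=-1), d)
    eigval, eigvec = np.linalg.eigh(E)
    order = np.argsort(-np.abs(eigval), kind="stable")
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: largest-magnitude entry positive
    piv = np.argmax(np.abs(eigvec), axis=0)
    signs = np.sign(eigvec[piv, np.arange(V)])
    signs[signs == 0] = 1.0
    eigvec = eigvec * signs
    poly = np.column_stack([np.ones(V), geom.coords])
    # polynomial terms first (guaranteeing their span), then leading
    # eigenvectors; greedy orthonormalization skips dependent directions so
    # M = V always spans R^V.
    stacked = np.column_stack([poly, eigvec])
    S = _orthonormal_greedy(stacked, M)
    return SplineBasis(
        S=S,
        M=M,
        null_dim=null_dim,
        eigen_spectrum=eigval[: M - null_dim],
        geometry=geom,
    )


def project_field(basis: SplineBasis, field: np.ndarray) -> np.ndarray:
    """Least-squares spline coefficients of a field (or stack of fields).

    Since S has orthonormal columns the minimizer of ||field - S gamma|| is
    simply ``S.T @ field``.  Accepts a [V] vector or [V x m] matrix.
    """
    field = np.asarray(field, dtype=float)
    if field.shape[0] != basis.V:
        raise ValueError("field length must equal the parcel size V")
    if not np.all(np.isfinite(field)):
        raise ValueError("field must be finite")
    return basis.S.T @ field
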