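"""Hemodynamic response bases and GLM design construction.

The BOLD response at a location is modeled as the sum over task conditions of
the stimulus function convolved with a hemodynamic response function (HRF),
each HRF expressed in a temporal basis of B functions.  Fitting then reduces
to a linear model ``y = X beta + eps`` whose design matrix holds one column
per (condition k, basis l) pair, ordered k-major.

All timing is in seconds; volumes are indexed from 0 at acquisition times
``0, TR, ..., (T-1)*TR``.  Stimuli are convolved on an internal grid
oversampled at TR/16 and decimated to volume times, which keeps off-grid
onsets alias-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import gamma as _gamma

__all__ = [
    "StimulusTrain",
    "HRFBasisSet",
    "DesignMatrix",
    "canonical_hrf",
    "build_basis",
    "convolve_regressor",
    "build_design",
    "read_stimulus_tsv",
]

#: internal oversampling factor relative to TR
OVERSAMPLE = 16

#: default support of the HRF in seconds
HRF_WINDOW = 32.0


@dataclass(frozen=True)
class StimulusTrain:
    """Event timing for one task condition.

    Parameters
    ----------
    condition_id : str
        Label of the condition.
    onsets : array of float
        Event onsets in seconds, sorted ascending, non-negative.
    durations : array of float
        Event durations in seconds (0 means an impulse), same length as onsets.
    amplitudes : array of float or None
        Per-event modulation heights; defaults to 1 for every event.
    """

    condition_id: str
    onsets: np.ndarray
    durations: np.ndarray
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if onsets.ndim != 1 or durations.shape != onsets.shape:
            raise ValueError("onsets and durations must be 1-D of equal length")
        if onsets.size and (np.any(onsets < 0) or np.any(durations < 0)):
            raise ValueError("onsets and durations must be non-negative")
        if np.any(np.diff(onsets) < 0):
            raise ValueError("onsets must be sorted ascending")
        amplitudes = self.amplitudes
        if amplitudes is None:
            amplitudes = np.ones_like(onsets)
        else:
            amplitudes = np.asarray(amplitudes, dtype=float)
            if amplitudes.shape != onsets.shape:
                raise ValueError("amplitudes must match onsets in length")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "amplitudes", amplitudes)

    def scaled(self, factor: float) -> "StimulusTrain":
        return StimulusTrain(
            self.condition_id, self.onsets, self.durations, self.amplitudes * factor
        )


@dataclass(frozen=True)
class HRFBasisSet:
    """A temporal HRF basis sampled on a fine grid.

    ``values`` has one column per basis function, sampled at ``sample_grid``
    (spacing TR/16).  ``kind`` is one of ``canonical`` (single double-gamma
    function), ``fir`` (indicator bins tiling the window) or ``bspline``
    (cubic B-splines forming a partition of unity on the interior).
    """

    kind: str
    B: int
    window: float
    sample_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("basis values must be finite")
        if self.values.shape != (self.sample_grid.size, self.B):
            raise ValueError("values must be [grid x B]")


@dataclass
class DesignMatrix:
    """GLM design: T x (K*B) task regressors plus optional nuisance columns.

    ``column_labels`` lists (condition, basis index) pairs in k-major order.
    Nuisance columns are kept separate and are never counted in KB.
    """

    X: np.ndarray
    column_labels: list[tuple[str, int]]
    TR: float
    T: int
    nuisance: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    rank_deficient: bool = False

    @property
    def KB(self) -> int:
        return self.X.shape[1]

    @property
    def n_nuisance(self) -> int:
        return 0 if self.nuisance.size == 0 else self.nuisance.shape[1]

    def full_matrix(self) -> np.ndarray:
        """Task columns followed by nuisance columns."""
        if self.n_nuisance == 0:
            return self.X
        return np.column_stack([self.X, self.nuisance])

    def to_frame(self) -> pd.DataFrame:
        cols = {f"{k}_b{l}": self.X[:, j] for j, (k, l) in enumerate(self.column_labels)}
        for j in range(self.n_nuisance):
            cols[f"nuisance{j}"] = self.nuisance[:, j]
        return pd.DataFrame(cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def canonical_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
    normalize: bool = True,
) -> np.ndarray:
    """Double-gamma canonical HRF sampled at times ``t`` (seconds).

    The response is the difference of two gamma densities, one for the main
    peak (mode near 5 s with the defaults) and one for the post-stimulus
    undershoot, mixed with weight ``ratio``.  With ``normalize`` the curve is
    scaled so its maximum equals 1.
    """
    t = np.asarray(t, dtype=float)
    if t.size and np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be ascending")
    for name, v in [
        ("peak_delay", peak_delay),
        ("undershoot_delay", undershoot_delay),
        ("peak_disp", peak_disp),
        ("undershoot_disp", undershoot_disp),
        ("ratio", ratio),
    ]:
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"HRF parameter {name} must be finite and non-negative")
    peak = _gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = _gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - ratio * under
    if normalize and h.size:
        m = np.max(np.abs(h))
        if m > 0:
            h = h / np.max(h)
    return h


def build_basis(
    kind: str,
    B: int,
    TR: float,
    window: float = HRF_WINDOW,
    **hrf_params,
) -> HRFBasisSet:
    """Construct an HRF basis set sampled at spacing TR/16 on [0, window]."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if window <= 0:
        raise ValueError("window must be positive")
    dt = TR / OVERSAMPLE
    grid = np.arange(0.0, window + dt / 2, dt)
    if kind == "canonical":
        if B != 1:
            raise ValueError(
                "canonical basis has a single function; request kind='fir' or "
                "'bspline' for B > 1"
            )
        values = canonical_hrf(grid, **hrf_params)[:, None]
    elif kind == "fir":
        # B indicator bins tiling [0, window) disjointly
        edges = np.linspace(0.0, window, B + 1)
        idx = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, B - 1)
        values = np.zeros((grid.size, B))
        inside = grid < window
        values[np.nonzero(inside)[0], idx[inside]] = 1.0
    elif kind == "bspline":
        degree = 3
        n_inner = max(B - degree - 1, 0)
        inner = np.linspace(0.0, window, n_inner + 2)[1:-1]
        knots = np.concatenate(
            [np.repeat(0.0, degree + 1), inner, np.repeat(window, degree + 1)]
        )
        if knots.size - degree - 1 != B:
            raise ValueError(f"bspline basis needs B >= {degree + 1}")
        values = BSpline.design_matrix(
            np.clip(grid, 0, window * (1 - 1e-12)), knots, degree
        ).toarray()
    else:
        raise ValueError(f"unknown basis kind {kind!r}")
    return HRFBasisSet(kind=kind, B=B, window=window, sample_grid=grid, values=values)


def _fine_stimulus(stim: StimulusTrain, dt: float, n_fine: int) -> np.ndarray:
    """Boxcar stimulus on the fine grid; impulses become sticks of mass `amp`."""
    u = np.zeros(n_fine)
    for onset, dur, amp in zip(stim.onsets, stim.durations, stim.amplitudes):
        i0 = int(round(onset / dt))
        if i0 >= n_fine:
            continue
        if dur == 0:
            # unit-mass stick so that (u * b) dt = amp * b(t - onset)
            u[i0] += amp / dt
        else:
            i1 = min(int(round((onset + dur) / dt)), n_fine)
            u[i0:i1] += amp
    return u


def convolve_regressor(
    stim: StimulusTrain,
    basis_column: np.ndarray,
    TR: float,
    T: int,
) -> np.ndarray:
    """Convolve one stimulus train with one HRF basis column.

    The stimulus boxcar and the basis are both represented on the TR/16 grid;
    their discrete convolution (Riemann approximation of the convolution
    integral) is decimated to the T volume acquisition times.
    """
    dt = TR / OVERSAMPLE
    n_fine = T * OVERSAMPLE
    if stim.onsets.size == 0:
        return np.zeros(T)
    u = _fine_stimulus(stim, dt, n_fine)
    conv = np.convolve(u, np.asarray(basis_column, dtype=float))[:n_fine] * dt
    return conv[:: OVERSAMPLE][:T]


def build_design(
    stims: Sequence[StimulusTrain],
    basis: HRFBasisSet,
    T: int,
    TR: float,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the T x KB design matrix, k-major then l-minor column order."""
    if len(stims) < 1:
        raise ValueError("need at least one condition")
    run_len = T * TR
    for s in stims:
        if s.onsets.size and np.any(s.onsets >= run_len):
            raise ValueError(
                f"condition {s.condition_id!r} has onsets beyond the run length"
            )
    K, B = len(stims), basis.B
    if T <= K * B:
        raise ValueError(f"T={T} must exceed the number of task regressors {K * B}")
    cols, labels = [], []
    for s in stims:
        for l in range(B):
            cols.append(convolve_regressor(s, basis.values[:, l], TR, T))
            labels.append((s.condition_id, l))
    X = np.column_stack(cols)
    nuis = np.empty((0, 0)) if nuisance is None else np.asarray(nuisance, dtype=float)
    if nuis.size and nuis.shape[0] != T:
        raise ValueError("nuisance matrix must have T rows")
    rank = np.linalg.matrix_rank(X)
    deficient = rank < X.shape[1]
    if deficient:
        warnings.warn(
            "design matrix is rank deficient (duplicated or degenerate conditions)",
            stacklevel=2,
        )
    return DesignMatrix(
        X=X, column_labels=labels, TR=TR, T=T, nuisance=nuis, rank_deficient=deficient
    )


def read_stimulus_tsv(path: str | Path, condition_id: str | None = None) -> StimulusTrain:
    """Read an FSL-style 3-column timing file (onset, duration, amplitude)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least onset and duration columns")
    onsets = df.iloc[:, 0].to_numpy(float)
    order = np.argsort(onsets, kind="stable")
    amplitudes = (
        df.iloc[:, 2].to_numpy(float)[order] if df.shape[1] >= 3 else None
    )
    return StimulusTrain(
        condition_id=condition_id or Path(path).stem,
        onsets=onsets[order],
        durations=df.iloc[:, 1].to_numpy(float)[order],
        amplitudes=amplitudes,
    )
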