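"""Two-stage hierarchical group inference with selective FDR control.

Stage 1 screens parcels: each parcel's subject-level spatial means enter a
one-sample t-test, and Benjamini-Hochberg (BH) at level ``alpha_parcel``
selects the parcel set S.  Stage 2 runs vertex-level one-sample t-tests
inside each selected parcel, with BH applied per parcel at the adjusted level
``q_p = alpha_voxel * |S| / P``.  The adjustment (Benjamini-Bogomolov)
guarantees that the expected average false discovery rate across the
selected parcels stays below ``alpha_voxel`` (defined as 0 when S is empty).

Tests are two-sided by default.  Inference runs on one (task, basis)
coefficient at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GroupData",
    "InferenceResult",
    "parcel_tstats",
    "bh_select",
    "selective_fdr",
    "flat_bh_inference",
]

ALPHA_PARCEL_DEFAULT = 0.1
ALPHA_VOXEL_DEFAULT = 0.5


@dataclass
class GroupData:
    """Per-subject activation maps for one (task, basis) coefficient.

    ``beta`` is [N subjects x V vertices]; ``parcel_labels`` assigns every
    vertex to exactly one parcel.
    """

    beta: np.ndarray
    parcel_labels: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.parcel_labels = np.asarray(self.parcel_labels)
        if self.beta.ndim != 2:
            raise ValueError("beta must be [N x V]")
        if self.beta.shape[0] < 2:
            raise ValueError("group inference needs N >= 2 subjects")
        if self.parcel_labels.shape[0] != self.beta.shape[1]:
            raise ValueError("parcel_labels must have one entry per vertex")

    @property
    def N(self) -> int:
        return self.beta.shape[0]

    @property
    def V(self) -> int:
        return self.beta.shape[1]

    @property
    def parcels(self) -> np.ndarray:
        return np.unique(self.parcel_labels)

    @property
    def P(self) -> int:
        return self.parcels.size


@dataclass
class InferenceResult:
    """Output of the two-stage selective procedure."""

    parcel_ids: np.ndarray
    parcel_T: np.ndarray
    parcel_p: np.ndarray
    selected: np.ndarray  # parcel ids in S
    q_p: float
    voxel_T: np.ndarray  # [V], NaN outside selected parcels
    voxel_p: np.ndarray  # [V], NaN outside selected parcels
    discoveries: np.ndarray  # vertex indices
    alpha_parcel: float
    alpha_voxel: float
    degenerate_parcels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_selected(self) -> int:
        return self.selected.size


def _one_sample_t(values: np.ndarray, two_sided: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t-statistics and p-values along axis 0 with degenerate guards.

    Zero between-subject SD gives p = 0 if the mean is nonzero (infinite
    evidence) and p = 1 if the mean is zero too.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    N = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_sd, np.sign(mean) * np.inf, mean / (sd / np.sqrt(N)))
    t = np.where(zero_sd & (mean == 0), 0.0, t)
    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df=N - 1)
    else:
        p = stats.t.sf(t, df=N - 1)
    p = np.where(zero_sd, np.where(mean == 0, 1.0, 0.0), p)
    return t, p


def parcel_tstats(
    group: GroupData, two_sided: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parcel-level one-sample t-tests of the subject spatial means.

    Returns ``(parcel_ids, T, p)``; the statistic for parcel p is the
    t-statistic of the N subject averages over the parcel's vertices.
    """
    ids = group.parcels
    means = np.column_stack(
        [group.beta[:, group.parcel_labels == pid].mean(axis=1) for pid in ids]
    )
    T, p = _one_sample_t(means, two_sided=two_sided)
    return ids, T, p


def bh_select(pvals: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: reject the hypotheses with p <= p_(i*).

    i* is the largest i with p_(i) <= i * alpha / m; returns the rejected
    index set (original order) and the rejection threshold p_(i*) (0.0 when
    nothing is rejected).  Ties are handled by the sorted order, so equal
    p-values are rejected together.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.empty(0, dtype=int), 0.0
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    sorted_p = pvals[order]
    crit = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(sorted_p <= crit)[0]
    if passing.size == 0:
        return np.empty(0, dtype=int), 0.0
    thresh = sorted_p[passing[-1]]
    return np.nonzero(pvals <= thresh)[0], float(thresh)


def selective_fdr(
    group: GroupData,
    alpha_parcel: float = ALPHA_PARCEL_DEFAULT,
    alpha_voxel: float = ALPHA_VOXEL_DEFAULT,
    two_sided: bool = True,
) -> InferenceResult:
    """Run the full two-stage procedure on one coefficient's group maps."""
    ids, T_parcel, p_parcel = parcel_tstats(group, two_sided=two_sided)
    sel_idx, _ = bh_select(p_parcel, alpha_parcel)
    selected = ids[sel_idx]
    P = ids.size
    q_p = alpha_voxel * selected.size / P
    voxel_T = np.full(group.V, np.nan)
    voxel_p = np.full(group.V, np.nan)
    discoveries: list[np.ndarray] = []
    for pid in selected:
        vmask = group.parcel_labels == pid
        vidx = np.nonzero(vmask)[0]
        t, p = _one_sample_t(group.beta[:, vidx], two_sided=two_sided)
        voxel_T[vidx] = t
        voxel_p[vidx] = p
        rej, _ = bh_select(p, q_p)
        if rej.size:
            discoveries.append(vidx[rej])
    disc = (
        np.sort(np.concatenate(discoveries)) if discoveries else np.empty(0, dtype=int)
    )
    return InferenceResult(
        parcel_ids=ids,
        parcel_T=T_parcel,
        parcel_p=p_parcel,
        selected=selected,
        q_p=float(q_p),
        voxel_T=voxel_T,
        voxel_p=voxel_p,
        discoveries=disc,
        alpha_parcel=alpha_parcel,
        alpha_voxel=alpha_voxel,
    )


def flat_bh_inference(
    group: GroupData, alpha_voxel: float = ALPHA_VOXEL_DEFAULT, two_sided: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertex-wise one-sample t-tests with a single BH pass over all vertices.

    The comparator inference used for the unsmoothed GLM and GKS pipelines.
    Returns ``(voxel_T, voxel_p, discovered vertex indices)``.
    """
    t, p = _one_sample_t(group.beta, two_sided=two_sided)
    rej, _ = bh_select(p, alpha_voxel)
    return t, p, rej
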