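"""Dataset and results I/O.

Native formats are plain text and NPY so an analysis round-trips without any
neuroimaging toolchain: coordinates as TSV ``(vertex_id, x, y[, z])``, parcel
labels as TSV ``(vertex_id, parcel_id)``, per-subject time series as NPY or
TSV ``[T x V]`` arrays, stimulus timing as FSL-style 3-column files.  GIFTI
surface geometry/labels and NIfTI series are accepted through optional
nibabel adapters and converted to the native in-memory model.

Vertex indexing is 0-based everywhere; parcel ids are opaque strings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .hrf import StimulusTrain, read_stimulus_tsv
from .inference import InferenceResult

__all__ = [
    "Dataset",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "write_results",
    "load_config",
    "gifti_coords",
    "gifti_labels",
    "nifti_series",
]


@dataclass
class Dataset:
    """Validated multi-subject dataset bound to one spatial domain."""

    coords: np.ndarray  # [V x d]
    parcel_labels: np.ndarray  # [V] str
    subjects: list[tuple[str, np.ndarray]]  # (id, [T x V])
    stimuli: list[StimulusTrain] = field(default_factory=list)
    TR: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be [V x d], d in {2, 3}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.parcel_labels = np.asarray(self.parcel_labels).astype(str)
        V = self.coords.shape[0]
        if self.parcel_labels.shape[0] != V:
            raise ValueError("parcel labels must have one entry per vertex")
        T = None
        for sid, series in self.subjects:
            series = np.asarray(series, dtype=float)
            if series.ndim != 2 or series.shape[1] != V:
                raise ValueError(f"subject {sid!r}: series must be [T x {V}]")
            if T is None:
                T = series.shape[0]
            elif series.shape[0] != T:
                raise ValueError(
                    f"subject {sid!r}: T={series.shape[0]} differs from the "
                    f"dataset's T={T}"
                )

    @property
    def V(self) -> int:
        return self.coords.shape[0]

    @property
    def T(self) -> int:
        return self.subjects[0][1].shape[0] if self.subjects else 0


class RunConfig(BaseModel):
    """Schema-validated analysis configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    method: str = "splash"
    estimator: str = "ols"
    ar_order: int = 1
    M_grid: list[int] | None = None
    fwhm: float | None = None
    bandwidth: float | None = None
    alpha_parcel: float = 0.1
    alpha_voxel: float = 0.5
    seed: int = 0
    paths: dict[str, str] = {}

    @field_validator("method")
    @classmethod
    def _method_known(cls, v: str) -> str:
        if v not in {"glm", "gks", "agks", "splash"}:
            raise ValueError(f"unknown method {v!r}")
        return v

    @field_validator("estimator")
    @classmethod
    def _estimator_known(cls, v: str) -> str:
        if v not in {"ols", "fgls"}:
            raise ValueError(f"unknown estimator {v!r}")
        return v

    @field_validator("bandwidth")
    @classmethod
    def _exclusive_smoothing(cls, v, info):
        if v is not None and info.data.get("fwhm") is not None:
            raise ValueError("fwhm and bandwidth are mutually exclusive")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# native TSV / NPY round trip
# ---------------------------------------------------------------------------

def _read_series(path: Path) -> np.ndarray:
    if path.suffix == ".npy":
        return np.load(path)
    return pd.read_csv(path, sep="\t", header=None).to_numpy(float)


def read_dataset(
    coords_path: str | Path,
    labels_path: str | Path,
    subject_paths: dict[str, str | Path],
    stimulus_paths: dict[str, str | Path] | None = None,
    TR: float = 1.0,
) -> Dataset:
    """Load and validate a dataset from native files.

    Raises descriptive errors for shape mismatches, unknown vertex ids in
    the label table, or subjects with a different T.
    """
    cdf = pd.read_csv(coords_path, sep="\t")
    dims = [c for c in ("x", "y", "z") if c in cdf.columns]
    if "vertex_id" not in cdf.columns or len(dims) < 2:
        raise ValueError(f"{coords_path}: expected columns vertex_id, x, y[, z]")
    cdf = cdf.sort_values("vertex_id")
    if not np.array_equal(cdf["vertex_id"].to_numpy(), np.arange(len(cdf))):
        raise ValueError(f"{coords_path}: vertex ids must be 0..V-1")
    coords = cdf[dims].to_numpy(float)
    ldf = pd.read_csv(labels_path, sep="\t", dtype={"parcel_id": str})
    if set(ldf.columns) < {"vertex_id", "parcel_id"}:
        raise ValueError(f"{labels_path}: expected columns vertex_id, parcel_id")
    unknown = set(ldf["vertex_id"]) - set(range(len(cdf)))
    if unknown:
        raise ValueError(f"{labels_path}: unknown vertex ids {sorted(unknown)[:5]}")
    labels = ldf.sort_values("vertex_id")["parcel_id"].to_numpy()
    subjects = [(sid, _read_series(Path(p))) for sid, p in subject_paths.items()]
    stimuli = [
        read_stimulus_tsv(p, condition_id=cid)
        for cid, p in (stimulus_paths or {}).items()
    ]
    return Dataset(
        coords=coords, parcel_labels=labels, subjects=subjects, stimuli=stimuli, TR=TR
    )


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset in the native layout; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    V = dataset.V
    d = dataset.coords.shape[1]
    cols = ["x", "y", "z"][:d]
    cdf = pd.DataFrame(dataset.coords, columns=cols)
    cdf.insert(0, "vertex_id", np.arange(V))
    files = {"coords": out / "coords.tsv", "labels": out / "parcels.tsv"}
    cdf.to_csv(files["coords"], sep="\t", index=False)
    pd.DataFrame(
        {"vertex_id": np.arange(V), "parcel_id": dataset.parcel_labels}
    ).to_csv(files["labels"], sep="\t", index=False)
    for sid, series in dataset.subjects:
        p = out / f"sub-{sid}_bold.npy"
        np.save(p, series)
        files[f"subject:{sid}"] = p
    for stim in dataset.stimuli:
        p = out / f"cond-{stim.condition_id}.tsv"
        np.savetxt(
            p,
            np.column_stack([stim.onsets, stim.durations, stim.amplitudes]),
            fmt="%.6g",
            delimiter="\t",
        )
        files[f"stimulus:{stim.condition_id}"] = p
    return files


# ---------------------------------------------------------------------------
# results export
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    result: InferenceResult,
    parcel_labels: np.ndarray,
    out_dir: str | Path,
) -> dict:
    """Write the discovery table, JSON summary and checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    V = parcel_labels.shape[0]
    discovered = np.zeros(V, dtype=bool)
    discovered[result.discoveries] = True
    table = pd.DataFrame(
        {
            "vertex_id": np.arange(V),
            "parcel_id": np.asarray(parcel_labels).astype(str),
            "T": result.voxel_T,
            "p": result.voxel_p,
            "q_threshold": result.q_p,
            "discovered": discovered.astype(int),
        }
    )
    table_path = out / "discoveries.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.10g")
    summary = {
        "n_parcels": int(result.parcel_ids.size),
        "n_selected": int(result.n_selected),
        "selected": [str(s) for s in result.selected],
        "q_p": result.q_p,
        "n_discoveries": int(result.discoveries.size),
        "alpha_parcel": result.alpha_parcel,
        "alpha_voxel": result.alpha_voxel,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "files": {
            p.name: _sha256(p) for p in (table_path, summary_path)
        }
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# neuroimaging adapters (optional nibabel dependency)
# ---------------------------------------------------------------------------

def _nib():
    try:
        import nibabel
    except ImportError as exc:  # pragma: no cover
        raise ImportError("GIFTI/NIfTI support requires nibabel") from exc
    return nibabel


def gifti_coords(path: str | Path) -> np.ndarray:
    """Vertex coordinates [V x 3] from a GIFTI surface geometry file."""
    img = _nib().load(str(path))
    for arr in img.darrays:
        if arr.data.ndim == 2 and arr.data.shape[1] == 3 and arr.data.dtype.kind == "f":
            return np.asarray(arr.data, dtype=float)
    raise ValueError(f"{path}: no coordinate array found")


def gifti_labels(path: str | Path) -> np.ndarray:
    """Per-vertex labels from a GIFTI label file, as strings."""
    img = _nib().load(str(path))
    data = np.asarray(img.darrays[0].data).ravel()
    return data.astype(str)


def nifti_series(path: str | Path, mask: np.ndarray | None = None) -> np.ndarray:
    """Flatten a 4-D NIfTI volume to a [T x V] matrix (optionally masked)."""
    img = _nib().load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume")
    flat = data.reshape(-1, data.shape[3]).T  # T x voxels
    if mask is not None:
        flat = flat[:, np.asarray(mask, dtype=bool).ravel()]
    return flat
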