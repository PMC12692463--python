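"""Reading, batching and normalization of multi-site two-modality cohorts.

A cohort is described by a manifest table (one row per subject: ids, site,
diagnosis, file paths) plus per-subject region×time series (delimited text)
and gray-matter-volume images (NIfTI or a packed little-endian binary with a
JSON sidecar).  The canonical in-memory layout for a time series is
timepoints × regions; the on-disk orientation is declared when loading.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord", "TimeSeriesMatrix", "Volume3D", "TimeSeriesBatch",
    "ManifestError", "read_manifest", "load_timeseries", "save_timeseries",
    "load_gmv", "save_gmv_packed", "save_gmv_nifti", "pad_and_mask", "unpad",
    "normalize", "normalize_timeseries", "normalize_gmv",
]

REQUIRED_COLUMNS = ("subject_id", "site_id", "label")


class ManifestError(ValueError):
    """Malformed manifest: missing columns or invalid values."""


@dataclass
class SubjectRecord:
    """One subject: identifiers, diagnosis, site, and modality payloads.

    ``ts`` / ``gmv`` hold inline arrays when the cohort lives in memory
    (synthetic cohorts); otherwise ``ts_path`` / ``gmv_path`` point at files.
    """

    subject_id: str
    site_id: int
    label: int  # 0 = healthy control, 1 = MDD
    ts_path: str | None = None
    gmv_path: str | None = None
    ts: np.ndarray | None = field(default=None, repr=False)
    gmv: np.ndarray | None = field(default=None, repr=False)
    age: float | None = None
    sex: str | None = None
    education: float | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ManifestError(
                f"label must be 0 (HC) or 1 (MDD), got {self.label!r}")


@dataclass
class TimeSeriesMatrix:
    """ROI time series in canonical T × d layout (timepoints × regions)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class Volume3D:
    """A 3-D gray-matter-volume image."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"volume must be 3-D, got rank {self.values.ndim}")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


@dataclass
class TimeSeriesBatch:
    """Zero-padded batch B × T_max × d with a per-timestep validity mask."""

    X: np.ndarray       # B, T_max, d
    mask: np.ndarray    # B, T_max — 1.0 at valid timesteps
    lengths: np.ndarray  # B

    def validate(self) -> None:
        B, T_max, _ = self.X.shape
        for i in range(B):
            L = int(self.lengths[i])
            expected = np.zeros(T_max)
            expected[:L] = 1.0
            if not np.array_equal(self.mask[i], expected):
                raise AssertionError("mask inconsistent with lengths")
        if np.abs(self.X * (1.0 - self.mask)[:, :, None]).max(initial=0) != 0:
            raise AssertionError("padded positions must be exactly zero")


def _detect_delimiter(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_manifest(path: str | Path) -> tuple[list[SubjectRecord], dict]:
    """Read a cohort manifest, densely re-indexing site ids to 0..S−1.

    Returns the records in file order plus the original→dense site mapping
    (insertion order of first appearance).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_delimiter(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing required columns: {missing}")
    if not any(c in df.columns for c in ("ts_path", "gmv_path")):
        raise ManifestError(
            "manifest needs at least one modality path column "
            "(ts_path or gmv_path)")
    site_map: dict = {}
    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        raw_site = row["site_id"]
        if raw_site not in site_map:
            site_map[raw_site] = len(site_map)
        label = int(row["label"])
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            site_id=site_map[raw_site],
            label=label,
            ts_path=str(row["ts_path"]) if "ts_path" in df.columns else None,
            gmv_path=(str(row["gmv_path"])
                      if "gmv_path" in df.columns else None),
            age=float(row["age"]) if "age" in df.columns else None,
            sex=str(row["sex"]) if "sex" in df.columns else None,
            education=(float(row["education"])
                       if "education" in df.columns else None),
        ))
    return records, site_map


def load_timeseries(path: str | Path,
                    orientation: str = "regions_by_time",
                    t_bounds: tuple[int, int] = (90, 240)) -> TimeSeriesMatrix:
    """Load a delimited numeric matrix into canonical T × d layout.

    ``orientation`` declares the on-disk layout; consortium-style files are
    regions × time (e.g. 116 × T).  A scan length outside ``t_bounds`` only
    warns — site protocols vary.
    """
    path = Path(path)
    if orientation not in ("regions_by_time", "time_by_regions"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        values = np.loadtxt(path, delimiter=_detect_delimiter(path),
                            dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "regions_by_time":
        values = values.T
    mat = TimeSeriesMatrix(values)
    if not (t_bounds[0] <= mat.T <= t_bounds[1]):
        warnings.warn(
            f"{path.name}: T={mat.T} outside expected range {t_bounds}",
            stacklevel=2)
    return mat


def save_timeseries(mat: TimeSeriesMatrix | np.ndarray, path: str | Path,
                    orientation: str = "regions_by_time") -> None:
    values = mat.values if isinstance(mat, TimeSeriesMatrix) else np.asarray(mat)
    if orientation == "regions_by_time":
        values = values.T
    np.savetxt(path, values, delimiter=",", fmt="%.10g")


def load_gmv(path: str | Path) -> Volume3D:
    """Load a gray-matter-volume image from NIfTI or packed binary."""
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several types
            raise IOError(f"cannot read NIfTI {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        return Volume3D(np.squeeze(data))
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise IOError(f"packed volume {path} has no JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    dtype = np.dtype(meta["dtype"]).newbyteorder("<")
    data = np.fromfile(path, dtype=dtype).astype(np.float64)
    return Volume3D(data.reshape(meta["dims"]))


def save_gmv_packed(vol: Volume3D | np.ndarray, path: str | Path) -> None:
    """Write a volume as little-endian float64 raw bytes + JSON sidecar."""
    values = vol.values if isinstance(vol, Volume3D) else np.asarray(vol)
    path = Path(path)
    values.astype("<f8").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"dims": list(values.shape), "dtype": "f8", "byteorder": "little"}))


def save_gmv_nifti(vol: Volume3D | np.ndarray, path: str | Path) -> None:
    values = vol.values if isinstance(vol, Volume3D) else np.asarray(vol)
    nib.save(nib.Nifti1Image(values.astype(np.float32), np.eye(4)), str(path))


def pad_and_mask(matrices: Sequence[TimeSeriesMatrix | np.ndarray]
                 ) -> TimeSeriesBatch:
    """Zero-pad variable-length series to a common T_max with validity mask."""
    if len(matrices) == 0:
        raise ValueError("cannot batch an empty list of time series")
    arrays = [m.values if isinstance(m, TimeSeriesMatrix) else np.asarray(m)
              for m in matrices]
    dims = {a.shape[1] for a in arrays}
    if len(dims) > 1:
        raise ValueError(f"inconsistent region counts across batch: {dims}")
    d = dims.pop()
    lengths = np.array([a.shape[0] for a in arrays], dtype=np.int64)
    T_max = int(lengths.max())
    B = len(arrays)
    X = np.zeros((B, T_max, d))
    mask = np.zeros((B, T_max))
    for i, a in enumerate(arrays):
        X[i, :a.shape[0]] = a
        mask[i, :a.shape[0]] = 1.0
    return TimeSeriesBatch(X=X, mask=mask, lengths=lengths)


def unpad(batch: TimeSeriesBatch) -> list[np.ndarray]:
    """Invert :func:`pad_and_mask`, recovering each input matrix exactly."""
    return [batch.X[i, :int(L)].copy() for i, L in enumerate(batch.lengths)]


def normalize(dataset, mode: str, train_idx: Sequence[int] | None = None):
    """Normalization front-end.

    ``mode="ts_zscore_per_region"`` expects a sequence of T_i × d arrays;
    ``mode="gmv_global_zscore"`` expects a stacked (N, D, H, W) array.
    Statistics come from ``train_idx`` only when a split is supplied.
    """
    if mode == "ts_zscore_per_region":
        return normalize_timeseries(dataset, train_idx=train_idx)
    if mode == "gmv_global_zscore":
        return normalize_gmv(dataset, train_idx=train_idx)
    raise ValueError(f"unknown normalization mode: {mode!r}")


def normalize_timeseries(series: Sequence[np.ndarray],
                         train_idx: Sequence[int] | None = None
                         ) -> tuple[list[np.ndarray], dict]:
    """Per-region z-scoring using statistics from the training subjects only.

    Statistics pool all (valid) timesteps of the training subjects; regions
    with zero variance are left at zero with a warning.
    """
    idx = range(len(series)) if train_idx is None else train_idx
    pooled = np.concatenate([np.asarray(series[i]) for i in idx], axis=0)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance regions left at "
                      "zero after centering", stacklevel=2)
    sd_safe = np.where(zero_var, 1.0, sd)
    out = [(np.asarray(s) - mean) / sd_safe for s in series]
    return out, {"mean": mean, "sd": sd}


def normalize_gmv(volumes: np.ndarray,
                  train_idx: Sequence[int] | None = None
                  ) -> tuple[np.ndarray, dict]:
    """Global z-scoring of a stack of volumes (N, D, H, W) with one
    cohort-level mean/SD computed on the training subjects."""
    volumes = np.asarray(volumes, dtype=np.float64)
    idx = slice(None) if train_idx is None else list(train_idx)
    mean = float(volumes[idx].mean())
    sd = float(volumes[idx].std())
    if sd == 0:
        warnings.warn("zero-variance volume stack left at zero after "
                      "centering", stacklevel=2)
        return volumes - mean, {"mean": mean, "sd": sd}
    return (volumes - mean) / sd, {"mean": mean, "sd": sd}
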