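"""Readers, writers and the core data containers.

Three kinds of external data flow through the pipeline:

* landmark trajectories exported by a pose tracker (flat CSV, one row per
  frame, two columns per landmark; or an HDF5 container with one dataset
  per landmark),
* stimulus/eye motion traces (CSV with ``time, stimulus, eye_left
  [, eye_right]`` columns and ``# key: value`` metadata header lines),
* dye-filled canal image stacks (multi-page grayscale TIFF).

All loaders validate shape invariants on entry; all reader/writer pairs
round-trip exactly on the canonical formats.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

LANDMARK_NAMES = (
    "left_eye",
    "right_eye",
    "skull_center",
    "body_com",
    "tail1",
    "tail2",
)


class SchemaError(ValueError):
    """A file is readable but does not contain the expected fields."""


class FormatError(ValueError):
    """A file's contents violate a structural invariant."""


@dataclasses.dataclass
class LandmarkTrajectory:
    """Per-frame 2D pixel coordinates of named body landmarks.

    Coordinates follow the image convention (origin top-left, x rightward,
    y downward) and stay in pixel units; conversion to millimetres happens
    only inside the kinematics stage via ``pixel_scale`` (mm/pixel).
    Missing (dropped-tracker) frames are stored as NaN, never silently
    removed.
    """

    frame_rate: float
    pixel_scale: float
    landmarks: dict[str, np.ndarray]  # name -> (n_frames, 2) float array

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        unknown = set(self.landmarks) - set(LANDMARK_NAMES)
        if unknown:
            raise SchemaError(f"unknown landmark names: {sorted(unknown)}")
        lengths = {name: len(np.asarray(xy)) for name, xy in self.landmarks.items()}
        if len(set(lengths.values())) > 1:
            raise FormatError(f"ragged landmark lengths: {lengths}")
        self.landmarks = {
            name: np.asarray(xy, dtype=float).reshape(-1, 2)
            for name, xy in self.landmarks.items()
        }

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.landmarks.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of frames where any landmark is missing."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for xy in self.landmarks.values():
            mask |= ~np.isfinite(xy).all(axis=1)
        return mask


@dataclasses.dataclass
class MotionTrace:
    """Paired stimulus/eye position time series in degrees.

    ``stimulus_kind`` tags the experimental condition: ``vestibular_dark``
    (turntable rotation in darkness), ``vestibular_light`` (rotation in
    front of a stationary visual pattern) or ``visual`` (optokinetic
    pattern motion with the head stationary). ``stimulus_amplitude`` is the
    positional half-excursion in degrees.
    """

    sample_rate: float
    stimulus: np.ndarray
    eyes: list[np.ndarray]
    stimulus_kind: str = "vestibular_dark"
    stimulus_freq: float = 0.5
    stimulus_amplitude: float = 10.0

    VALID_KINDS = ("vestibular_dark", "vestibular_light", "visual")

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.stimulus_freq <= 0:
            raise ValueError("stimulus_freq must be positive")
        if self.stimulus_kind not in self.VALID_KINDS:
            raise ValueError(f"stimulus_kind must be one of {self.VALID_KINDS}")
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        self.eyes = [np.asarray(e, dtype=float) for e in self.eyes]
        if not self.eyes:
            raise FormatError("at least one eye trace required")
        for e in self.eyes:
            if len(e) != len(self.stimulus):
                raise FormatError("stimulus and eye traces differ in length")

    @property
    def n_samples(self) -> int:
        return len(self.stimulus)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def is_vestibular(self) -> bool:
        return self.stimulus_kind.startswith("vestibular")

    def conjugate_eye(self) -> np.ndarray:
        """Average of left/right conjugated eye positions."""
        return np.mean(self.eyes, axis=0)


@dataclasses.dataclass
class CanalVolume:
    """3D voxel grid of a dye-filled canal, axes ordered (z, y, x).

    ``voxel_size`` is (dz, dy, dx) in micrometres; all morphometry converts
    to micrometres immediately so the core works in a single unit.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise FormatError("voxels must be a non-empty 3D grid")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive values (dz, dy, dx)")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


# ---------------------------------------------------------------------------
# landmark tables


def _landmark_columns() -> list[str]:
    cols = []
    for name in LANDMARK_NAMES:
        cols += [f"{name}_x", f"{name}_y"]
    return cols


def read_landmarks(
    path: str | Path, frame_rate: float, pixel_scale: float
) -> LandmarkTrajectory:
    """Read a landmark table (CSV or HDF5) into a validated trajectory.

    The flat CSV layout has one row per frame and columns
    ``<landmark>_x, <landmark>_y`` for each of the six landmarks. HDF5
    files carry one ``(n_frames, 2)`` dataset per landmark under the
    ``landmarks/`` group.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "landmarks" not in f:
                raise SchemaError("missing 'landmarks' group")
            grp = f["landmarks"]
            missing = [n for n in LANDMARK_NAMES if n not in grp]
            if missing:
                raise SchemaError(f"missing landmark datasets: {missing}")
            landmarks = {n: np.asarray(grp[n], dtype=float) for n in LANDMARK_NAMES}
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _landmark_columns() if c not in df.columns]
        if missing:
            raise SchemaError(f"missing landmark columns: {missing}")
        landmarks = {
            n: df[[f"{n}_x", f"{n}_y"]].to_numpy(dtype=float) for n in LANDMARK_NAMES
        }
    return LandmarkTrajectory(frame_rate, pixel_scale, landmarks)


def write_landmarks(traj: LandmarkTrajectory, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            grp = f.create_group("landmarks")
            for name, xy in traj.landmarks.items():
                grp.create_dataset(name, data=xy)
            f.attrs["frame_rate"] = traj.frame_rate
            f.attrs["pixel_scale"] = traj.pixel_scale
    else:
        data = {}
        for name in LANDMARK_NAMES:
            xy = traj.landmarks[name]
            data[f"{name}_x"] = xy[:, 0]
            data[f"{name}_y"] = xy[:, 1]
        # 17 significant digits: lossless text round trip for float64
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def interpolate_gaps(
    traj: LandmarkTrajectory, max_gap: int = 5
) -> tuple[LandmarkTrajectory, np.ndarray]:
    """Linearly interpolate missing landmark frames up to ``max_gap``.

    Runs of missing frames longer than ``max_gap`` are left as NaN and
    returned in a boolean flag mask so that downstream bout detection can
    invalidate the events that contain them.
    """
    flagged = np.zeros(traj.n_frames, dtype=bool)
    filled: dict[str, np.ndarray] = {}
    for name, xy in traj.landmarks.items():
        xy = xy.copy()
        bad = ~np.isfinite(xy).all(axis=1)
        if bad.any():
            # locate runs of consecutive missing frames
            idx = np.flatnonzero(bad)
            splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            good = np.flatnonzero(~bad)
            for run in splits:
                if len(run) <= max_gap and good.size >= 2:
                    for k in (0, 1):
                        xy[run, k] = np.interp(run, good, xy[good, k])
                else:
                    flagged[run] = True
        filled[name] = xy
    return LandmarkTrajectory(traj.frame_rate, traj.pixel_scale, filled), flagged


# ---------------------------------------------------------------------------
# motion traces


def read_trace(path: str | Path) -> MotionTrace:
    """Read a stimulus/eye trace CSV.

    Metadata (stimulus kind, frequency, amplitude) live in leading
    ``# key: value`` comment lines; the sample rate is inferred from the
    ``time`` column.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("time", "stimulus", "eye_left"):
        if col not in df.columns:
            raise SchemaError(f"missing trace column: {col}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("trace needs at least two samples")
    sample_rate = 1.0 / np.median(np.diff(t))
    eyes = [df["eye_left"].to_numpy(dtype=float)]
    if "eye_right" in df.columns:
        eyes.append(df["eye_right"].to_numpy(dtype=float))
    return MotionTrace(
        sample_rate=sample_rate,
        stimulus=df["stimulus"].to_numpy(dtype=float),
        eyes=eyes,
        stimulus_kind=meta.get("stimulus_kind", "vestibular_dark"),
        stimulus_freq=float(meta.get("stimulus_freq", 0.5)),
        stimulus_amplitude=float(meta.get("stimulus_amplitude", 10.0)),
    )


def write_trace(trace: MotionTrace, path: str | Path) -> None:
    path = Path(path)
    data = {"time": trace.time, "stimulus": trace.stimulus, "eye_left": trace.eyes[0]}
    if len(trace.eyes) > 1:
        data["eye_right"] = trace.eyes[1]
    with open(path, "w") as fh:
        fh.write(f"# stimulus_kind: {trace.stimulus_kind}\n")
        fh.write(f"# stimulus_freq: {trace.stimulus_freq}\n")
        fh.write(f"# stimulus_amplitude: {trace.stimulus_amplitude}\n")
        pd.DataFrame(data).to_csv(fh, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# volumes


def read_volume(path: str | Path, voxel_size: Sequence[float]) -> CanalVolume:
    """Read a multi-page grayscale TIFF stack with a stated voxel size."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected a grayscale stack, got shape {arr.shape}")
    is_binary = bool(np.isin(np.unique(arr), (0, 1)).all())
    return CanalVolume(arr, tuple(voxel_size), is_binary=is_binary)


def write_volume(vol: CanalVolume, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(vol.voxels))


# ---------------------------------------------------------------------------
# result tables


def write_results(records: Sequence[Mapping | object], path: str | Path) -> None:
    """Write named records (dicts or dataclasses) as delimited text.

    The column order is the field order of the first record, so repeated
    runs produce byte-identical files.
    """
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rec = dataclasses.asdict(rec)
        rows.append(dict(rec))
    if rows:
        columns = list(rows[0].keys())
        for row in rows[1:]:
            if list(row.keys()) != columns:
                raise SchemaError("records do not share a schema")
        df = pd.DataFrame(rows, columns=columns)
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_summary(summary: Mapping, path: str | Path) -> None:
    """JSON summary sidecar for a run; numpy scalars are coerced."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(dict(summary), fh, indent=2, default=default)
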