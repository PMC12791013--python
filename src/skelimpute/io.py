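"""Reading, writing and windowing of keypoint trajectories.

A :class:`Recording` is the raw unit of data: per-frame coordinates of K named
keypoints in 2 or 3 dimensions, together with a boolean missingness mask.
Missing coordinates are stored as NaN internally; zero-filling only happens at
model-input assembly, because zero is an in-range coordinate value.

The CSV dialect is ``frame,<kp>_x,<kp>_y[,<kp>_z]`` with an optional
``<kp>_conf`` column per keypoint for pose-estimator exports.  Optional
metadata (fps, individual labels) travels in a ``# skelimpute {json}`` comment
line.  The npz bundle stores ``coords``, ``missing`` and a JSON ``meta`` blob.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, FormatError, ShapeError

_AXES = ("x", "y", "z")


@dataclass
class Recording:
    """Full keypoint trajectory of one session.

    Attributes
    ----------
    id : str
        Session identifier.
    fps : float
        Frames per second, > 0.
    keypoint_names : list of str
        K names, one per keypoint.
    coords : ndarray, shape (T, K, D)
        Coordinates in original units; NaN wherever missing.
    missing : ndarray of bool, shape (T, K)
        True where the keypoint is unobserved at that frame.
    individual_of : ndarray of int, optional
        Individual label per keypoint for multi-animal data.
    """

    id: str
    fps: float
    keypoint_names: list[str]
    coords: np.ndarray
    missing: np.ndarray | None = None
    individual_of: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3:
            raise ShapeError(f"coords must be (T, K, D), got {self.coords.shape}")
        T, K, D = self.coords.shape
        if T < 1:
            raise EmptyInputError("recording has zero frames")
        if K < 2:
            raise ShapeError(f"need at least 2 keypoints, got {K}")
        if D not in (2, 3):
            raise ShapeError(f"D must be 2 or 3, got {D}")
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if len(self.keypoint_names) != K:
            raise ShapeError("keypoint_names length does not match coords")
        # A keypoint-frame with any NaN axis is wholly untrustworthy
        # (coordinates are triangulated jointly): mark the full cell missing.
        nan_cell = np.isnan(self.coords).any(axis=2)
        if self.missing is None:
            self.missing = nan_cell
        else:
            self.missing = np.asarray(self.missing, dtype=bool) | nan_cell
        self.coords[self.missing] = np.nan
        if self.individual_of is not None:
            self.individual_of = np.asarray(self.individual_of, dtype=np.int64)
            if self.individual_of.shape != (K,):
                raise ShapeError("individual_of must have one entry per keypoint")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.coords.shape[1]

    @property
    def dims(self) -> int:
        return self.coords.shape[2]


@dataclass
class Sample:
    """Fixed-length window of a recording (default 60 frames)."""

    recording_id: str
    start_frame: int
    coords: np.ndarray  # (L, K, D)
    missing: np.ndarray  # (L, K)
    transform: "object | None" = None  # TransformMeta once normalized

    @property
    def length(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return not bool(self.missing.any())

    def copy(self) -> "Sample":
        return Sample(self.recording_id, self.start_frame, self.coords.copy(),
                      self.missing.copy(), self.transform)


@dataclass
class Segment:
    """A contiguous frame range [start, stop) of one recording."""

    recording: Recording
    start: int
    stop: int


@dataclass
class SplitAssignment:
    """Frame-level assignment of recordings to train/val/test."""

    train: list[Segment]
    val: list[Segment]
    test: list[Segment]
    mode: str


@dataclass
class DatasetSplit:
    """Extracted samples per split."""

    train: list[Sample] = field(default_factory=list)
    val: list[Sample] = field(default_factory=list)
    test: list[Sample] = field(default_factory=list)
    split_mode: str = "by_recording"


# ---------------------------------------------------------------------------
# loading / writing


def _parse_header(columns: Sequence[str]) -> tuple[list[str], int, bool]:
    """Return (keypoint names, D, has_confidence) from CSV column names."""
    cols = list(columns)
    if not cols or cols[0] != "frame":
        raise FormatError("first CSV column must be 'frame'")
    cols = cols[1:]
    if not cols:
        raise FormatError("no coordinate columns found")
    names: list[str] = []
    for c in cols:
        if "_" not in c:
            raise FormatError(f"column {c!r} lacks '_<axis>' suffix")
        base, suffix = c.rsplit("_", 1)
        if suffix not in _AXES + ("conf",):
            raise FormatError(f"unknown axis suffix in column {c!r}")
        if base not in names:
            names.append(base)
    has_conf = any(c == f"{names[0]}_conf" for c in cols)
    dims = 3 if f"{names[0]}_z" in cols else 2
    expected = []
    for n in names:
        expected.extend(f"{n}_{a}" for a in _AXES[:dims])
        if has_conf:
            expected.append(f"{n}_conf")
    if expected != cols:
        raise ShapeError(
            "inconsistent column layout: expected "
            f"{len(expected)} columns ({dims}D"
            f"{' + conf' if has_conf else ''} per keypoint), got {cols}")
    return names, dims, has_conf


def load_recording(path: str | Path,
                   format: str = "csv",
                   missing_sentinel: float | None = None,
                   confidence_threshold: float | None = None,
                   fps: float | None = None,
                   id: str | None = None) -> Recording:
    """Load a keypoint trajectory file.

    ``format`` is one of ``csv``, ``npz`` or ``pose_csv`` (CSV with a
    ``<kp>_conf`` column per keypoint; coordinates whose confidence falls
    below ``confidence_threshold`` are marked missing).  Coordinates equal to
    ``missing_sentinel`` (or NaN) are marked missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rec_id = id if id is not None else path.stem

    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            coords = z["coords"]
            missing = z["missing"]
            meta = json.loads(str(z["meta"]))
        return Recording(id=meta.get("id", rec_id), fps=meta["fps"],
                         keypoint_names=meta["keypoint_names"],
                         coords=coords, missing=missing,
                         individual_of=(np.asarray(meta["individual_of"])
                                        if meta.get("individual_of") is not None
                                        else None))

    if format not in ("csv", "pose_csv"):
        raise ConfigError(f"unknown format {format!r}")

    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# skelimpute"):
            meta = json.loads(first[len("# skelimpute"):])
    df = pd.read_csv(path, comment="#")
    if len(df) == 0:
        raise EmptyInputError(f"{path} contains zero frames")
    names, dims, has_conf = _parse_header(df.columns)
    if format == "pose_csv" and not has_conf:
        raise FormatError("pose_csv requires a _conf column per keypoint")

    T, K = len(df), len(names)
    coords = np.empty((T, K, dims))
    for k, n in enumerate(names):
        for d in range(dims):
            coords[:, k, d] = df[f"{n}_{_AXES[d]}"].to_numpy(dtype=np.float64)
    if missing_sentinel is not None and not math.isnan(missing_sentinel):
        coords[coords == missing_sentinel] = np.nan
    missing = np.isnan(coords).any(axis=2)
    if has_conf and confidence_threshold is not None:
        conf = np.stack([df[f"{n}_conf"].to_numpy(dtype=np.float64)
                         for n in names], axis=1)
        missing |= conf < confidence_threshold
    return Recording(id=meta.get("id", rec_id),
                     fps=float(fps if fps is not None else meta.get("fps", 60.0)),
                     keypoint_names=names, coords=coords, missing=missing,
                     individual_of=(np.asarray(meta["individual_of"])
                                    if meta.get("individual_of") is not None
                                    else None))


def write_recording(recording: Recording, path: str | Path,
                    format: str = "csv") -> Path:
    """Write a recording; ``load_recording(write_recording(r))`` round-trips
    coords (NaN-preserving) and the missing mask exactly (npz) or to text
    precision (csv)."""
    path = Path(path)
    meta = {"id": recording.id, "fps": recording.fps,
            "keypoint_names": recording.keypoint_names,
            "individual_of": (recording.individual_of.tolist()
                              if recording.individual_of is not None else None)}
    if format == "npz":
        np.savez(path, coords=recording.coords, missing=recording.missing,
                 meta=np.asarray(json.dumps(meta)))
        return path
    if format != "csv":
        raise ConfigError(f"unknown format {format!r}")
    T, K, D = recording.coords.shape
    cols = {"frame": np.arange(T)}
    for k, n in enumerate(recording.keypoint_names):
        for d in range(D):
            cols[f"{n}_{_AXES[d]}"] = recording.coords[:, k, d]
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# skelimpute " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# splitting / windowing


def split_dataset(recordings: list[Recording],
                  fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  mode: str = "by_recording",
                  seed: int = 0) -> SplitAssignment:
    """Assign frames to train/val/test.

    ``by_recording`` shuffles whole recordings (seeded) and assigns them
    entirely to one set.  ``by_time`` partitions each recording contiguously:
    the starting ``fractions[0]`` of frames go to train, the next block to
    validation and the remainder to test, so the train set only contains
    information prior to validation and test.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ConfigError(f"fractions must be >= 0 and sum to 1, got {fractions}")
    if mode == "by_recording":
        if len(recordings) < 3:
            raise ConfigError("by_recording split needs at least 3 recordings")
        order = np.random.default_rng(seed).permutation(len(recordings))
        n = len(recordings)
        n_train = int(np.floor(fractions[0] * n))
        n_val = int(np.floor(fractions[1] * n))
        n_train, n_val = max(n_train, 1), max(n_val, 1)
        if n_train + n_val >= n:  # keep test non-empty
            n_train = max(n - n_val - 1, 1)
        sets: list[list[Segment]] = [[], [], []]
        for i, idx in enumerate(order):
            r = recordings[idx]
            which = 0 if i < n_train else (1 if i < n_train + n_val else 2)
            sets[which].append(Segment(r, 0, r.n_frames))
        return SplitAssignment(*sets, mode=mode)
    if mode == "by_time":
        # boundary rounding: floor for the train end and for the cumulative
        # val end; remainder to test — reproducible across runs.
        sets = [[], [], []]
        for r in recordings:
            T = r.n_frames
            t1 = int(np.floor(fractions[0] * T))
            t2 = int(np.floor((fractions[0] + fractions[1]) * T))
            sets[0].append(Segment(r, 0, t1))
            sets[1].append(Segment(r, t1, t2))
            sets[2].append(Segment(r, t2, T))
        return SplitAssignment(*sets, mode=mode)
    raise ConfigError(f"unknown split mode {mode!r}")


def extract_samples(recording: Recording,
                    length: int = 60,
                    stride: int = 30,
                    complete_only: bool = False,
                    start: int = 0,
                    stop: int | None = None) -> list[Sample]:
    """Cut windows [start + i*stride, ... + length) from a recording.

    Windows are half-open and 0-based.  With ``complete_only``, windows that
    contain any missing keypoint-frame are dropped.  ``start``/``stop``
    restrict extraction to a frame range (used for by-time splits).  A range
    shorter than ``length`` yields an empty list.
    """
    if length < 2:
        raise ConfigError(f"sample length must be >= 2, got {length}")
    if stride < 1:
        raise ConfigError(f"stride must be >= 1, got {stride}")
    stop = recording.n_frames if stop is None else stop
    out: list[Sample] = []
    for s in range(start, stop - length + 1, stride):
        missing = recording.missing[s:s + length]
        if complete_only and missing.any():
            continue
        out.append(Sample(recording.id, s,
                          recording.coords[s:s + length].copy(),
                          missing.copy()))
    return out


def build_dataset_split(assignment: SplitAssignment,
                        length: int = 60,
                        stride: int = 30,
                        complete_only: bool = True) -> DatasetSplit:
    """Extract samples from a split assignment into a DatasetSplit."""
    split = DatasetSplit(split_mode=assignment.mode)
    for name in ("train", "val", "test"):
        samples = getattr(split, name)
        for seg in getattr(assignment, name):
            samples.extend(extract_samples(seg.recording, length, stride,
                                           complete_only, seg.start, seg.stop))
    return split
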