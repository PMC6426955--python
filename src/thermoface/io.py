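"""Readers and writers for every artifact the pipeline touches.

Thermal frame stacks travel either as a directory of per-frame CSV matrices
(inspectable, 2-decimal precision) or as a single ``TSTACK v1`` binary file
(one ASCII header line followed by frame-major float32 data). Landmark
records, scalar signals and beat lists are plain CSV. All geometry is
0-based with x = column increasing rightward and y = row increasing
downward.

Readers validate and never silently reorder, drop or impute samples; all
repairs happen downstream and are flagged there.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ThermalFrame",
    "ThermalVideo",
    "SignalTrace",
    "EventDesign",
    "LandmarkRecord",
    "read_thermal_stack",
    "write_thermal_stack",
    "read_landmarks",
    "write_landmarks",
    "read_signal_csv",
    "write_signal_csv",
    "read_beats_csv",
    "write_beats_csv",
]

LANDMARK_SOURCES = ("model1", "model2", "fused", "truth")


class FormatError(ValueError):
    """Malformed or inconsistent on-disk artifact."""


@dataclass(frozen=True)
class ThermalFrame:
    """One radiometric frame: a (height, width) matrix of temperatures in deg C."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise FormatError(f"frame must be a 2-D matrix, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise FormatError("frame contains non-finite temperatures")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class ThermalVideo:
    """Time-ordered stack of thermal frames with a uniform sampling rate.

    ``data`` has shape (n_frames, height, width); temperatures in deg C.
    """

    data: np.ndarray
    fs_hz: float = 5.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[0] < 1:
            raise FormatError(f"video data must be (n, h, w) with n >= 1, got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise FormatError("video contains non-finite temperatures")
        if not self.fs_hz > 0:
            raise FormatError("fs_hz must be positive")
        self.data = d

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.fs_hz

    def frame(self, i: int) -> ThermalFrame:
        return ThermalFrame(self.data[i])


@dataclass
class SignalTrace:
    """Uniformly sampled scalar series (GSR, ECG, temperature, z, ...)."""

    values: np.ndarray
    fs_hz: float
    units: str = ""
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not self.fs_hz > 0:
            raise FormatError("fs_hz must be positive")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.fs_hz


@dataclass(frozen=True)
class EventDesign:
    """Single-event design: stimulus onset with baseline and response windows.

    Defaults mirror a 60 s recording with the stimulus at 40 s, a 5 s
    pre-stimulus baseline and a 10 s post-stimulus window.
    """

    onset_s: float = 40.0
    pre_window_s: float = 5.0
    post_window_s: float = 10.0
    total_s: float = 60.0

    def __post_init__(self) -> None:
        if self.onset_s - self.pre_window_s < 0:
            raise ValueError("baseline window starts before the recording")
        if self.onset_s + self.post_window_s > self.total_s:
            raise ValueError("response window extends past the recording")


class LandmarkRecord(NamedTuple):
    frame_index: int
    point_id: int
    x: float
    y: float
    confidence: float
    source: str


# ---------------------------------------------------------------------------
# thermal stacks

_TSTACK_MAGIC = "TSTACK v1"
_CSV_FRAME_RE = re.compile(r"frame_(\d{6})\.csv$")
_META_NAME = "stack_meta.yaml"


def write_thermal_stack(video: ThermalVideo, path: str | Path, dialect: str = "binary") -> None:
    """Write a frame stack; ``dialect`` is ``binary`` (TSTACK v1) or ``csv_dir``.

    CSV frames are rounded to 2 decimals (the stated radiometric precision);
    the binary dialect stores float32 and round-trips to < 0.005 deg C.
    """
    path = Path(path)
    if video.n_frames < 1:
        raise FormatError("cannot write an empty video")
    if dialect == "binary":
        header = f"{_TSTACK_MAGIC} {video.width} {video.height} {video.n_frames} {video.fs_hz:g}\n"
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(np.ascontiguousarray(video.data, dtype="<f4").tobytes())
    elif dialect == "csv_dir":
        path.mkdir(parents=True, exist_ok=True)
        for k in range(video.n_frames):
            np.savetxt(path / f"frame_{k:06d}.csv", video.data[k], fmt="%.2f", delimiter=",")
        meta = {"fs_hz": float(video.fs_hz), "t0_s": float(video.t0_s), "n_frames": int(video.n_frames)}
        (path / _META_NAME).write_text(yaml.safe_dump(meta))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_thermal_stack(path: str | Path) -> ThermalVideo:
    """Read a ``TSTACK v1`` binary file or a ``frame_%06d.csv`` directory."""
    path = Path(path)
    if path.is_dir():
        return _read_csv_dir(path)
    with open(path, "rb") as fh:
        header = fh.readline().decode("ascii", errors="replace").strip()
        parts = header.split()
        if len(parts) != 6 or " ".join(parts[:2]) != _TSTACK_MAGIC:
            raise FormatError(f"not a {_TSTACK_MAGIC} stack: header {header!r}")
        width, height, n_frames = (int(p) for p in parts[2:5])
        fs_hz = float(parts[5])
        raw = np.frombuffer(fh.read(), dtype="<f4")
    expected = n_frames * height * width
    if raw.size != expected:
        raise FormatError(f"stack payload has {raw.size} values, header promises {expected}")
    data = raw.astype(float).reshape(n_frames, height, width)
    if not np.all(np.isfinite(data)):
        raise FormatError("stack contains non-finite temperatures")
    return ThermalVideo(data, fs_hz=fs_hz)


def _read_csv_dir(path: Path) -> ThermalVideo:
    files = sorted(p for p in path.iterdir() if _CSV_FRAME_RE.search(p.name))
    if not files:
        raise FormatError(f"no frame_XXXXXX.csv files in {path}")
    meta_path = path / _META_NAME
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {_META_NAME} in {path}")
    meta = yaml.safe_load(meta_path.read_text())
    frames = []
    shape = None
    for p in files:
        try:
            m = np.atleast_2d(np.loadtxt(p, delimiter=",", dtype=float))
        except ValueError as exc:
            raise FormatError(f"frame {p.name} is malformed: {exc}") from exc
        if shape is None:
            shape = m.shape
        elif m.shape != shape:
            raise FormatError(f"frame {p.name} has shape {m.shape}, expected {shape}")
        if not np.all(np.isfinite(m)):
            raise FormatError(f"frame {p.name} contains non-finite values")
        frames.append(m)
    return ThermalVideo(np.stack(frames), fs_hz=float(meta["fs_hz"]), t0_s=float(meta.get("t0_s", 0.0)))


# ---------------------------------------------------------------------------
# landmarks

_LANDMARK_COLS = ["frame_index", "point_id", "x", "y", "confidence", "source"]


def write_landmarks(records: Iterable[LandmarkRecord], path: str | Path) -> None:
    df = pd.DataFrame(list(records), columns=_LANDMARK_COLS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_landmarks(path: str | Path) -> list[LandmarkRecord]:
    """Read landmark records, sorted by (frame_index, point_id).

    Rejects duplicate (frame, point, source) triples and confidences
    outside [0, 1].
    """
    df = pd.read_csv(path)
    missing = set(_LANDMARK_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"landmark file missing columns {sorted(missing)}")
    if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
        bad = df.loc[(df["confidence"] < 0) | (df["confidence"] > 1)].index[0]
        raise FormatError(f"confidence outside [0, 1] at row {bad}")
    if df.duplicated(subset=["frame_index", "point_id", "source"]).any():
        raise FormatError("duplicate (frame_index, point_id, source) records")
    df = df.sort_values(["frame_index", "point_id"], kind="stable")
    return [
        LandmarkRecord(int(r.frame_index), int(r.point_id), float(r.x), float(r.y),
                       float(r.confidence), str(r.source))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# scalar signals

def write_signal_csv(trace: SignalTrace, path: str | Path,
                     flags: Sequence[str] | None = None) -> None:
    """Write a two-column time_s,value CSV; optional per-sample flags column."""
    cols = {"time_s": trace.t_s, "value": trace.values}
    if flags is not None:
        if len(flags) != len(trace):
            raise ValueError("flags length does not match trace")
        cols["flag"] = list(flags)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_signal_csv(path: str | Path, units: str = "") -> SignalTrace:
    """Read a time_s,value CSV, inferring fs from the median sample spacing.

    Sampling must be uniform to within 1e-6 s jitter; a single-row file has
    no inferable rate and is rejected.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "value" not in df.columns:
        raise FormatError("signal CSV must have columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("cannot infer sampling rate from fewer than 2 samples")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0 or np.any(np.abs(dt - dt_med) > 1e-6):
        raise FormatError("non-uniform sampling (jitter beyond 1e-6 s)")
    return SignalTrace(df["value"].to_numpy(dtype=float), fs_hz=1.0 / dt_med,
                       units=units, t0_s=float(t[0]))


def write_beats_csv(beats_s: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"beat_s": np.asarray(beats_s, dtype=float)}).to_csv(
        path, index=False, float_format="%.10g")


def read_beats_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if "beat_s" not in df.columns:
        raise FormatError("beat list CSV must have column beat_s")
    return df["beat_s"].to_numpy(dtype=float)
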