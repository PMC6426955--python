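"""ROI thermometry: circular regions anchored to the eyebrow-midpoint
reference, per-frame mean temperature extraction with carry-forward for
frames where landmarks were lost, 5-SD spline outlier repair, and per-series
z-scoring.

The four standard regions are the nose tip, the two cheeks and the
forehead, each a 10-pixel-radius circle placed at a fixed pixel offset from
the midpoint of the two medial (inner) eyebrow landmarks. The offsets are
configurable per subject — they stand in for the one-time manual ROI
placement on a subject's first frame — and by default assume 640x480
framing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .io import SignalTrace
from .landmarks import MEDIAL_BROW_IDS, LandmarkFrame

__all__ = [
    "ROISpec",
    "ROIMask",
    "CleaningConfig",
    "LabeledSeries",
    "DEFAULT_ROI_SPECS",
    "reference_point",
    "rasterize_roi",
    "extract_series",
    "repair_outliers",
    "zscore",
    "MaskError",
]

ROI_NAMES = ("nose_tip", "right_cheek", "left_cheek", "forehead")


class MaskError(ValueError):
    """ROI mask could not be built (e.g. fully off-frame)."""


@dataclass(frozen=True)
class ROISpec:
    """A named circle: ``offset_px`` = (dx, dy) from the reference point."""

    name: str
    offset_px: tuple[float, float]
    radius_px: float = 10.0

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise ValueError("radius_px must be positive")


def default_roi_specs(scale: float = 1.0) -> dict[str, ROISpec]:
    """Standard four-region layout for 640x480 framing, optionally scaled.

    Offsets scale with frame size; the 10-px radius does not (it is the
    stated measurement aperture, not a geometric feature of the face).
    """
    s = scale
    return {
        "forehead": ROISpec("forehead", (0.0, -60.0 * s)),
        "nose_tip": ROISpec("nose_tip", (0.0, 90.0 * s)),
        "right_cheek": ROISpec("right_cheek", (-70.0 * s, 70.0 * s)),
        "left_cheek": ROISpec("left_cheek", (70.0 * s, 70.0 * s)),
    }


DEFAULT_ROI_SPECS: dict[str, ROISpec] = default_roi_specs()


@dataclass(frozen=True)
class ROIMask:
    """Integer pixel membership of one rasterized circle on one frame."""

    pixels: np.ndarray  # (n, 2) int, columns (x, y)
    dims: tuple[int, int]  # (width, height)
    n_clipped: int = 0

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class CleaningConfig:
    """Outlier threshold in SDs of the full series (single pass, sample SD)."""

    outlier_sd: float = 5.0
    boundary_policy: str = "nearest"

    def __post_init__(self) -> None:
        if not self.outlier_sd > 0:
            raise ValueError("outlier_sd must be positive")


@dataclass
class LabeledSeries:
    """A per-ROI scalar series plus provenance of repaired/carried samples."""

    trace: SignalTrace
    roi_name: str = ""
    repaired_indices: frozenset[int] = frozenset()
    carried_indices: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        n = len(self.trace)
        for idx in (self.repaired_indices, self.carried_indices):
            if any(i < 0 or i >= n for i in idx):
                raise ValueError("flag index out of range")

    @property
    def values(self) -> np.ndarray:
        return self.trace.values

    def flags(self) -> list[str]:
        """Per-sample status column for CSV export."""
        out = []
        for i in range(len(self.trace)):
            if i in self.repaired_indices:
                out.append("repaired")
            elif i in self.carried_indices:
                out.append("carried")
            else:
                out.append("ok")
        return out


def reference_point(frame_landmarks: LandmarkFrame,
                    brow_ids: tuple[int, int] = MEDIAL_BROW_IDS) -> tuple[float, float]:
    """Midpoint of the two medial eyebrow landmarks, real-valued."""
    a, b = brow_ids
    n = frame_landmarks.xy.shape[0]
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError(f"brow ids {brow_ids} outside point range")
    p = 0.5 * (frame_landmarks.xy[a] + frame_landmarks.xy[b])
    if not np.all(np.isfinite(p)):
        raise ValueError("medial brow landmarks are not finite")
    return (float(p[0]), float(p[1]))


def rasterize_roi(spec: ROISpec, reference: tuple[float, float],
                  dims: tuple[int, int]) -> ROIMask:
    """Pixels whose integer centre lies within ``radius_px`` of the circle
    centre (reference + offset), Euclidean, boundary inclusive. Pixels
    falling outside the frame are dropped and counted in ``n_clipped``; a
    fully off-frame circle raises :class:`MaskError` so the caller can fall
    back to carry-forward."""
    w, h = dims
    cx = reference[0] + spec.offset_px[0]
    cy = reference[1] + spec.offset_px[1]
    if not (np.isfinite(cx) and np.isfinite(cy)):
        raise MaskError("non-finite ROI centre")
    r = spec.radius_px
    xs = np.arange(int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1)
    ys = np.arange(int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1)
    gx, gy = np.meshgrid(xs, ys)
    inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
    px = np.column_stack([gx[inside], gy[inside]])
    in_frame = (px[:, 0] >= 0) & (px[:, 0] < w) & (px[:, 1] >= 0) & (px[:, 1] < h)
    clipped = int(px.shape[0] - in_frame.sum())
    px = px[in_frame]
    if px.shape[0] == 0:
        raise MaskError(f"ROI {spec.name!r} lies fully outside the frame")
    return ROIMask(px.astype(int), dims=(w, h), n_clipped=clipped)


def extract_series(video, masks: Sequence[ROIMask | None], roi_name: str = "",
                   carry_policy: str = "value") -> LabeledSeries:
    """Mean ROI temperature per frame, in deg C.

    ``masks[k]`` is the rasterized mask for frame k, or None when landmarks
    were not detected; then the previous frame's temperature VALUE is
    carried forward (``carry_policy="value"``, the default) or the last
    valid mask is applied to the current frame (``"previous_mask"``), and
    the sample index is recorded in ``carried_indices``. The first frame
    must have a valid mask.
    """
    if carry_policy not in ("value", "previous_mask"):
        raise ValueError(f"unknown carry_policy {carry_policy!r}")
    if len(masks) != video.n_frames:
        raise ValueError("one mask (or None) required per frame")
    if masks[0] is None:
        raise ValueError("no valid mask on frame 0: nothing to carry forward")
    values = np.empty(video.n_frames)
    carried = []
    last_mask = masks[0]
    for k, m in enumerate(masks):
        if m is None:
            if carry_policy == "value":
                values[k] = values[k - 1]
            else:
                values[k] = float(video.data[k][last_mask.pixels[:, 1],
                                                last_mask.pixels[:, 0]].mean())
            carried.append(k)
        else:
            last_mask = m
            values[k] = float(video.data[k][m.pixels[:, 1], m.pixels[:, 0]].mean())
    trace = SignalTrace(values, fs_hz=video.fs_hz, units="degC", t0_s=video.t0_s)
    return LabeledSeries(trace, roi_name=roi_name, carried_indices=frozenset(carried))


def repair_outliers(series: LabeledSeries,
                    cfg: CleaningConfig = CleaningConfig()) -> LabeledSeries:
    """Replace samples more than ``outlier_sd`` sample-SDs from the series
    mean by cubic-spline interpolation through the non-flagged samples.

    The mean and SD are those of the full input series, computed once
    (outliers included). Flagged samples outside the span of the non-flagged
    ones are filled with the nearest non-flagged value (spline extrapolation
    is unstable). Non-flagged samples pass through bit-unchanged. A
    zero-variance series is returned as-is; a series where everything would
    be flagged is an error.
    """
    v = series.trace.values
    if len(v) < 4:
        raise ValueError("need at least 4 samples for cubic spline repair")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return replace(series, trace=replace(series.trace, values=v.copy()))
    bad = np.abs(v - v.mean()) > cfg.outlier_sd * sd
    if not bad.any():
        return replace(series, trace=replace(series.trace, values=v.copy()))
    if bad.all():
        raise ValueError("every sample flagged as outlier; nothing to interpolate from")
    good_idx = np.flatnonzero(~bad)
    out = v.copy()
    bad_idx = np.flatnonzero(bad)
    lo, hi = good_idx[0], good_idx[-1]
    interior = bad_idx[(bad_idx > lo) & (bad_idx < hi)]
    if interior.size:
        if good_idx.size >= 4:
            spline = CubicSpline(good_idx, v[good_idx])
            out[interior] = spline(interior)
        else:
            out[interior] = np.interp(interior, good_idx, v[good_idx])
    edges = bad_idx[(bad_idx <= lo) | (bad_idx >= hi)]
    for i in edges:
        out[i] = v[lo] if i < lo else v[hi]
    return replace(series,
                   trace=replace(series.trace, values=out),
                   repaired_indices=series.repaired_indices | frozenset(bad_idx.tolist()))


def zscore(series: LabeledSeries) -> LabeledSeries:
    """Standardize the series to mean 0, sample SD 1 (units become z)."""
    v = series.trace.values
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    if sd == 0.0:
        raise ValueError("cannot z-score a constant series")
    z = (v - v.mean()) / sd
    return replace(series, trace=replace(series.trace, values=z, units="z"))
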