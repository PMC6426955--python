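"""Landmark detection support: frame enhancement, cascade fusion of two
detectors, temporal stabilization, and accuracy scoring.

The 70 points follow the Multi-PIE 68-point mark-up plus two pupil
centres (ids 68, 69). A detector is anything that supplies 70
(x, y, confidence) triples per frame on the enhanced intensity image; this
package ships a mock detector (jitter/dropout/outliers around a known
truth) so the fusion and tracking stages are testable without any trained
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io import ThermalFrame

__all__ = [
    "N_LANDMARKS",
    "MEDIAL_BROW_IDS",
    "EnhancementConfig",
    "FusionConfig",
    "TrackingConfig",
    "LandmarkFrame",
    "enhance_frame",
    "fuse_landmarks",
    "stabilize_sequence",
    "evaluate_accuracy",
    "mock_detector",
    "frames_from_records",
    "records_from_frames",
]

N_LANDMARKS = 70
#: inner eyebrow ends in the 68-point convention (0-based); pupils are 68, 69
MEDIAL_BROW_IDS = (21, 22)


@dataclass(frozen=True)
class EnhancementConfig:
    """Percentile-clip linear stretch to [0, 1] with optional gamma."""

    saturation_fraction: float = 0.01
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.saturation_fraction < 0.5:
            raise ValueError("saturation_fraction must be in [0, 0.5)")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class FusionConfig:
    """Minimum confidence for a detection to count as valid in the cascade."""

    confidence_threshold: float = 0.65

    def __post_init__(self) -> None:
        if not 0 <= self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in [0, 1]")


@dataclass(frozen=True)
class TrackingConfig:
    """Maximum plausible inter-frame displacement of a landmark, in pixels."""

    validity_radius_px: float = 5.0

    def __post_init__(self) -> None:
        if not self.validity_radius_px > 0:
            raise ValueError("validity_radius_px must be positive")


@dataclass
class LandmarkFrame:
    """All 70 landmarks of one frame from one source.

    ``xy`` has shape (70, 2) in pixel coordinates; ``confidence`` shape (70,).
    """

    frame_index: int
    xy: np.ndarray
    confidence: np.ndarray
    source: str = "truth"

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        c = np.asarray(self.confidence, dtype=float)
        if xy.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected ({N_LANDMARKS}, 2) points, got {xy.shape}")
        if c.shape != (N_LANDMARKS,):
            raise ValueError(f"expected {N_LANDMARKS} confidences, got {c.shape}")
        if np.any((c < 0) | (c > 1)):
            raise ValueError("confidences must lie in [0, 1]")
        self.xy = xy
        self.confidence = c


def enhance_frame(frame: ThermalFrame | np.ndarray,
                  cfg: EnhancementConfig = EnhancementConfig()) -> np.ndarray:
    """Map a raw temperature frame to a [0, 1] intensity image for detection.

    Values at or below the ``saturation_fraction`` quantile map to 0, at or
    above the (1 - saturation_fraction) quantile to 1, linearly in between,
    then raised to ``gamma``. A constant frame maps to all zeros. The raw
    temperatures are never modified; thermometry always reads the original
    frame.
    """
    v = frame.values if isinstance(frame, ThermalFrame) else np.asarray(frame, dtype=float)
    lo = float(np.quantile(v, cfg.saturation_fraction))
    hi = float(np.quantile(v, 1.0 - cfg.saturation_fraction))
    if hi <= lo:
        return np.zeros_like(v)
    out = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    if cfg.gamma != 1.0:
        out = out ** cfg.gamma
    return out


def fuse_landmarks(det1: LandmarkFrame, det2: LandmarkFrame,
                   cfg: FusionConfig = FusionConfig()) -> LandmarkFrame:
    """Cascade-fuse two detectors' landmarks for one frame.

    Per point: if both detections clear the confidence threshold, the fused
    location is their coordinate-wise mean; if exactly one clears it, that
    detection is used; if neither does, the higher-scoring detection wins
    (ties go to detector 1, mirroring the cascade order). The fused
    confidence is the maximum of the contributing scores, so every point is
    always emitted.
    """
    if det1.frame_index != det2.frame_index:
        raise ValueError(
            f"frame index mismatch: {det1.frame_index} vs {det2.frame_index}")
    thr = cfg.confidence_threshold
    v1 = det1.confidence >= thr
    v2 = det2.confidence >= thr
    both = v1 & v2
    only1 = v1 & ~v2
    only2 = v2 & ~v1
    neither_take2 = ~v1 & ~v2 & (det2.confidence > det1.confidence)

    xy = det1.xy.copy()
    xy[both] = 0.5 * (det1.xy[both] + det2.xy[both])
    xy[only2 | neither_take2] = det2.xy[only2 | neither_take2]
    conf = np.maximum(det1.confidence, det2.confidence)
    return LandmarkFrame(det1.frame_index, xy, conf, source="fused")


def stabilize_sequence(frames: Sequence[LandmarkFrame],
                       cfg: TrackingConfig = TrackingConfig()) -> list[LandmarkFrame]:
    """Temporally stabilize a landmark sequence.

    A point is valid if it moved at most ``validity_radius_px`` from its
    stabilized location in the previous frame (boundary inclusive). A
    rejected point is replaced by the nearest point of the validity disc
    centred at the previous location, i.e. the candidate is radially
    projected back onto the disc boundary. Consequently every consecutive
    displacement is bounded by the radius.
    """
    if len(frames) == 0:
        raise ValueError("cannot stabilize an empty sequence")
    r = cfg.validity_radius_px
    out = [replace(frames[0], xy=frames[0].xy.copy(),
                   confidence=frames[0].confidence.copy())]
    for f in frames[1:]:
        prev = out[-1].xy
        delta = f.xy - prev
        dist = np.hypot(delta[:, 0], delta[:, 1])
        xy = f.xy.copy()
        bad = dist > r
        if np.any(bad):
            xy[bad] = prev[bad] + delta[bad] * (r / dist[bad])[:, None]
        out.append(replace(f, xy=xy, confidence=f.confidence.copy()))
    return out


def evaluate_accuracy(pred: Sequence[LandmarkFrame], truth: Sequence[LandmarkFrame],
                      tol_px: float = 5.0,
                      exclude_ids: Iterable[int] | None = None) -> float:
    """Fraction of point instances within ``tol_px`` (Euclidean, inclusive)
    of ground truth, optionally excluding point ids (e.g. the eyes, nose and
    outer-mouth subset)."""
    if len(pred) != len(truth):
        raise ValueError(f"sequence lengths differ: {len(pred)} vs {len(truth)}")
    keep = np.ones(N_LANDMARKS, dtype=bool)
    if exclude_ids is not None:
        keep[np.asarray(sorted(exclude_ids), dtype=int)] = False
    if not keep.any():
        raise ValueError("all point ids excluded")
    hits = total = 0
    for p, t in zip(pred, truth):
        err = np.hypot(*(p.xy[keep] - t.xy[keep]).T)
        # inclusive boundary with an allowance for coordinate round-off
        hits += int(np.sum(err <= tol_px + 1e-9))
        total += int(keep.sum())
    return hits / total


def mock_detector(truth: Sequence[LandmarkFrame], jitter_sd_px: float = 1.0,
                  dropout_prob: float = 0.0, outlier_prob: float = 0.0,
                  outlier_shift_px: float = 30.0, seed: int | None = None,
                  source: str = "model1",
                  rng: np.random.Generator | None = None) -> list[LandmarkFrame]:
    """Simulate a landmark detector around known ground truth.

    Adds isotropic Gaussian jitter to every point; with ``dropout_prob`` a
    point keeps its location but draws a confidence below the fusion
    threshold (a low-confidence miss); with ``outlier_prob`` a point is
    displaced by ``outlier_shift_px`` in a random direction at full
    confidence (a confident mistake). Deterministic for a fixed seed.
    """
    for p in (dropout_prob, outlier_prob):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for f in truth:
        xy = f.xy + rng.normal(0.0, jitter_sd_px, size=(N_LANDMARKS, 2))
        conf = np.ones(N_LANDMARKS)
        drop = rng.random(N_LANDMARKS) < dropout_prob
        conf[drop] = rng.uniform(0.0, 0.649, size=int(drop.sum()))
        outl = rng.random(N_LANDMARKS) < outlier_prob
        if outl.any():
            theta = rng.uniform(0.0, 2 * np.pi, size=int(outl.sum()))
            xy[outl] += outlier_shift_px * np.column_stack([np.cos(theta), np.sin(theta)])
        out.append(LandmarkFrame(f.frame_index, xy, conf, source=source))
    return out


# -- conversion between per-frame objects and flat record lists -------------

def frames_from_records(records, source: str | None = None) -> list[LandmarkFrame]:
    """Group flat LandmarkRecord rows into per-frame LandmarkFrame objects."""
    from collections import defaultdict

    by_frame: dict[int, list] = defaultdict(list)
    for r in records:
        if source is None or r.source == source:
            by_frame[r.frame_index].append(r)
    frames = []
    for idx in sorted(by_frame):
        rows = sorted(by_frame[idx], key=lambda r: r.point_id)
        if len(rows) != N_LANDMARKS or [r.point_id for r in rows] != list(range(N_LANDMARKS)):
            raise ValueError(f"frame {idx} does not have point ids 0..{N_LANDMARKS - 1}")
        xy = np.array([[r.x, r.y] for r in rows])
        conf = np.array([r.confidence for r in rows])
        frames.append(LandmarkFrame(idx, xy, conf, source=rows[0].source))
    if not frames:
        raise ValueError("no records matched")
    return frames


def records_from_frames(frames: Sequence[LandmarkFrame]):
    from .io import LandmarkRecord

    recs = []
    for f in frames:
        for pid in range(N_LANDMARKS):
            recs.append(LandmarkRecord(f.frame_index, pid, float(f.xy[pid, 0]),
                                       float(f.xy[pid, 1]), float(f.confidence[pid]),
                                       f.source))
    return recs
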