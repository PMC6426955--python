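"""Ground-truthed synthetic inputs for the whole pipeline.

The face phantom is a smooth 2-D Gaussian temperature field (a warm
face-shaped blob on a cooler background) carrying 70 canonical landmarks
that translate rigidly with the simulated head motion (random-walk plus
slow sinusoidal sway). After the stimulus onset each region of interest
cools exponentially toward its programmed amplitude with a programmed
latency and time constant; per-pixel sensor noise mirrors the 0.05 deg C
noise floor of a radiometric camera. GSR is a baseline plus a smooth
rise-decay response; heartbeats come from integrate-to-threshold sampling
of an instantaneous rate with post-stimulus slowing and sinusoidal LF/HF
modulation. Every generator is deterministic given its seed, and a cohort
derives per-subject seeds from one master seed.

This is a phantom, not a rendered face: it provides the statistical
structure the pipeline assumes (smooth fields, rigid motion, localized
responses, known latencies), nothing about real thermal physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import EventDesign, SignalTrace, ThermalVideo
from .landmarks import N_LANDMARKS, MEDIAL_BROW_IDS, LandmarkFrame
from .roi import LabeledSeries, ROISpec, default_roi_specs, rasterize_roi

__all__ = [
    "FacePhantomConfig",
    "ResponseConfig",
    "GroundTruth",
    "SubjectData",
    "canonical_landmarks",
    "generate_thermal_video",
    "generate_gsr",
    "generate_ecg_beats",
    "generate_cohort",
]

_BASE_DIMS = (640, 480)


@dataclass(frozen=True)
class FacePhantomConfig:
    """Geometry, motion and noise of the synthetic thermal recording."""

    dims: tuple[int, int] = _BASE_DIMS  # (width, height)
    fs_hz: float = 5.0
    duration_s: float = 60.0
    background_C: float = 26.0
    face_peak_C: float = 34.5
    face_sigma_frac: tuple[float, float] = (0.15, 0.27)  # of width/height
    motion_walk_sd_px: float = 0.3
    motion_drift_amp_px: float = 3.0
    motion_drift_period_s: float = 20.0
    sensor_noise_sd_C: float = 0.05  # camera noise floor (NEDT-like)

    def __post_init__(self) -> None:
        if self.motion_walk_sd_px < 0 or self.sensor_noise_sd_C < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def scale(self) -> float:
        return self.dims[0] / _BASE_DIMS[0]


@dataclass(frozen=True)
class ResponseConfig:
    """Programmed stimulus-locked responses (the ground truth).

    Thermal amplitudes are deg C changes reached asymptotically with an
    exponential time constant after a per-region latency; the forehead
    default is 0 (the null channel). GSR is a rise-decay bump whose peak
    sits at onset + latency + rise. IBI lengthens after onset and carries
    sinusoidal LF (0.1 Hz) and HF (0.25 Hz) modulation.
    """

    amplitudes_C: tuple = (("nose_tip", -0.3), ("right_cheek", -0.15),
                           ("left_cheek", -0.15), ("forehead", 0.0))
    latencies_s: tuple = (("nose_tip", 2.5), ("right_cheek", 3.5),
                          ("left_cheek", 3.5), ("forehead", 3.5))
    time_constant_s: float = 8.0
    response_disc_radius_px: float = 20.0
    gsr_amplitude: float = 1.0
    gsr_latency_s: float = 1.5
    gsr_rise_s: float = 4.0
    gsr_decay_s: float = 6.0
    gsr_baseline: float = 2.0
    rr_base_s: float = 0.8
    ibi_lengthen_s: float = 0.08
    ibi_tau_s: float = 5.0
    lf_amp_s: float = 0.02
    lf_freq_hz: float = 0.10
    hf_amp_s: float = 0.02
    hf_freq_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.gsr_latency_s < 0 or any(v < 0 for _, v in self.latencies_s):
            raise ValueError("latencies must be non-negative")

    @property
    def amplitude_map(self) -> dict[str, float]:
        return dict(self.amplitudes_C)

    @property
    def latency_map(self) -> dict[str, float]:
        return dict(self.latencies_s)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    landmark_frames: list  # LandmarkFrame, source="truth"
    roi_curves: dict  # name -> programmed mean-ROI temperature (n_frames,)
    response: ResponseConfig
    shifts_px: np.ndarray  # (n_frames, 2) rigid translation of the face
    seed: int | None


def canonical_landmarks(dims: tuple[int, int] = _BASE_DIMS) -> np.ndarray:
    """The 70-point template (68-point face mark-up + 2 pupils), scaled to
    the frame. Inner-brow points land so that the eyebrow midpoint is the
    standard ROI reference."""
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw 0-16: lower face ellipse, left ear to right ear through the chin
    ang = np.pi * (1 - np.arange(17) / 16)
    pts[0:17, 0] = 320 + 110 * np.cos(ang)
    pts[0:17, 1] = 240 + 150 * np.sin(ang)
    # brows 17-26, inner ends at ids 21 and 22
    pts[17:22, 0] = np.linspace(250, 301, 5)
    pts[17:22, 1] = np.linspace(186, 180, 5)
    pts[22:27, 0] = np.linspace(339, 390, 5)
    pts[22:27, 1] = np.linspace(180, 186, 5)
    # nose bridge 27-30 and base 31-35
    pts[27:31, 0] = 320
    pts[27:31, 1] = np.linspace(195, 255, 4)
    pts[31:36, 0] = np.linspace(300, 340, 5)
    pts[31:36, 1] = 265
    # eyes 36-41 / 42-47: hexagons
    hexa = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    for base, (ex, ey) in ((36, (285, 205)), (42, (355, 205))):
        pts[base:base + 6, 0] = ex + 15 * np.cos(hexa)
        pts[base:base + 6, 1] = ey + 8 * np.sin(hexa)
    # mouth 48-67: outer ring of 12, inner ring of 8
    outer = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    pts[48:60, 0] = 320 + 45 * np.cos(outer)
    pts[48:60, 1] = 330 + 20 * np.sin(outer)
    inner = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pts[60:68, 0] = 320 + 30 * np.cos(inner)
    pts[60:68, 1] = 330 + 10 * np.sin(inner)
    # pupils
    pts[68] = (285, 205)
    pts[69] = (355, 205)
    pts[:, 0] *= dims[0] / _BASE_DIMS[0]
    pts[:, 1] *= dims[1] / _BASE_DIMS[1]
    return pts


def _motion_path(phantom: FacePhantomConfig, n: int, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    w = 2 * np.pi / phantom.motion_drift_period_s
    drift = phantom.motion_drift_amp_px * np.column_stack(
        [np.sin(w * t), 0.6 * np.sin(w * t + 1.1)])
    walk = np.cumsum(rng.normal(0.0, phantom.motion_walk_sd_px, size=(n, 2)), axis=0)
    return drift + walk


def _face_field(phantom: FacePhantomConfig, shift: np.ndarray) -> np.ndarray:
    w, h = phantom.dims
    cx = w / 2 + shift[0]
    cy = h / 2 + shift[1]
    sx = phantom.face_sigma_frac[0] * w
    sy = phantom.face_sigma_frac[1] * h
    gx = np.exp(-((np.arange(w) - cx) ** 2) / (2 * sx * sx))
    gy = np.exp(-((np.arange(h) - cy) ** 2) / (2 * sy * sy))
    amp = phantom.face_peak_C - phantom.background_C
    return phantom.background_C + amp * np.outer(gy, gx)


def _response_delta(t: np.ndarray, onset: float, latency: float,
                    amplitude: float, tau: float) -> np.ndarray:
    u = t - onset - latency
    out = np.zeros_like(t)
    m = u > 0
    out[m] = amplitude * (1.0 - np.exp(-u[m] / tau))
    return out


def _roi_centres(phantom: FacePhantomConfig,
                 roi_specs: Mapping[str, ROISpec]) -> dict[str, np.ndarray]:
    tpl = canonical_landmarks(phantom.dims)
    ref = 0.5 * (tpl[MEDIAL_BROW_IDS[0]] + tpl[MEDIAL_BROW_IDS[1]])
    return {name: ref + np.asarray(spec.offset_px, dtype=float)
            for name, spec in roi_specs.items()}


def generate_thermal_video(phantom: FacePhantomConfig = FacePhantomConfig(),
                           resp: ResponseConfig = ResponseConfig(),
                           design: EventDesign = EventDesign(),
                           seed: int | None = 0,
                           roi_specs: Mapping[str, ROISpec] | None = None,
                           ) -> tuple[ThermalVideo, GroundTruth]:
    """Render the moving face phantom with stimulus-locked ROI cooling.

    Returns the video plus ground truth: true landmark trajectories, the
    programmed per-ROI mean-temperature curves (what a perfect extractor
    anchored to true landmarks would measure on the noiseless video), the
    response parameters and the rigid-motion path.
    """
    rng = np.random.default_rng(seed)
    fs = phantom.fs_hz
    n = int(round(design.total_s * fs))
    w, h = phantom.dims
    if roi_specs is None:
        roi_specs = default_roi_specs(phantom.scale)
    shifts = _motion_path(phantom, n, fs, rng)
    tpl = canonical_landmarks(phantom.dims)
    centres0 = _roi_centres(phantom, roi_specs)
    t = np.arange(n) / fs
    amps, lats = resp.amplitude_map, resp.latency_map
    deltas = {name: _response_delta(t, design.onset_s, lats.get(name, 0.0),
                                    amps.get(name, 0.0), resp.time_constant_s)
              for name in roi_specs}

    # programmed curves: noiseless mean over the measurement aperture in
    # frame-0 geometry (rigid motion moves field and aperture together)
    field0 = _face_field(phantom, np.zeros(2))
    roi_curves = {}
    for name, spec in roi_specs.items():
        mask = rasterize_roi(spec, tuple(centres0[name] - spec.offset_px), (w, h))
        base = float(field0[mask.pixels[:, 1], mask.pixels[:, 0]].mean())
        roi_curves[name] = base + deltas[name]

    # disc radius scales with the phantom so regional responses stay disjoint
    rd = resp.response_disc_radius_px * phantom.scale
    data = np.empty((n, h, w))
    lm_frames = []
    yy = np.arange(h)
    xx = np.arange(w)
    for k in range(n):
        frame = _face_field(phantom, shifts[k])
        for name in roi_specs:
            dk = deltas[name][k]
            if dk != 0.0:
                cx, cy = centres0[name] + shifts[k]
                x0, x1 = max(0, int(cx - rd) - 1), min(w, int(cx + rd) + 2)
                y0, y1 = max(0, int(cy - rd) - 1), min(h, int(cy + rd) + 2)
                sub_x = xx[x0:x1] - cx
                sub_y = yy[y0:y1] - cy
                disc = (sub_y[:, None] ** 2 + sub_x[None, :] ** 2) <= rd * rd
                frame[y0:y1, x0:x1][disc] += dk
        if phantom.sensor_noise_sd_C > 0:
            frame = frame + rng.normal(0.0, phantom.sensor_noise_sd_C, size=(h, w))
        data[k] = frame
        lm_frames.append(LandmarkFrame(k, tpl + shifts[k], np.ones(N_LANDMARKS),
                                       source="truth"))
    video = ThermalVideo(data, fs_hz=fs)
    truth = GroundTruth(lm_frames, roi_curves, resp, shifts, seed)
    return video, truth


def generate_gsr(resp: ResponseConfig = ResponseConfig(),
                 design: EventDesign = EventDesign(), fs_hz: float = 2000.0,
                 noise_sd: float = 0.01, seed: int | None = 0) -> SignalTrace:
    """Baseline skin conductance plus a smooth rise-decay response.

    The response kernel (u/rise)^(rise/decay) * exp((rise-u)/decay) peaks
    exactly at u = rise with value 1, so the noiseless peak time is
    onset + latency + rise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(design.total_s * fs_hz))
    t = np.arange(n) / fs_hz
    u = t - design.onset_s - resp.gsr_latency_s
    v = np.full(n, resp.gsr_baseline)
    m = u > 0
    a = resp.gsr_rise_s / resp.gsr_decay_s
    v[m] += resp.gsr_amplitude * (u[m] / resp.gsr_rise_s) ** a * np.exp(
        (resp.gsr_rise_s - u[m]) / resp.gsr_decay_s)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return SignalTrace(v, fs_hz=fs_hz, units="microsiemens")


def generate_ecg_beats(resp: ResponseConfig = ResponseConfig(),
                       design: EventDesign = EventDesign(),
                       duration_s: float | None = None,
                       seed: int | None = 0,
                       beat_jitter_s: float = 0.0) -> np.ndarray:
    """Beat times from integrate-to-threshold sampling of 1/RR(t).

    RR(t) = base + post-onset lengthening (exponential approach) + LF and
    HF sinusoidal modulation; a beat fires whenever the integrated rate
    crosses the next integer.
    """
    rng = np.random.default_rng(seed)
    dur = design.total_s if duration_s is None else duration_s
    fs = 200.0
    t = np.arange(int(round(dur * fs))) / fs
    rr = (resp.rr_base_s
          + _response_delta(t, design.onset_s, 0.0, resp.ibi_lengthen_s, resp.ibi_tau_s)
          + resp.lf_amp_s * np.sin(2 * np.pi * resp.lf_freq_hz * t)
          + resp.hf_amp_s * np.sin(2 * np.pi * resp.hf_freq_hz * t))
    if np.any(rr <= 0):
        raise ValueError("instantaneous RR must stay positive")
    phase = np.concatenate([[0.0], np.cumsum((1.0 / rr[1:] + 1.0 / rr[:-1]) / 2) / fs])
    n_beats = int(np.floor(phase[-1]))
    beats = np.interp(np.arange(1, n_beats + 1), phase, t)
    if beat_jitter_s > 0:
        beats = np.sort(beats + rng.normal(0.0, beat_jitter_s, size=beats.size))
    return beats


@dataclass
class SubjectData:
    """One simulated participant's recordings plus their ground truth."""

    subject_id: str
    roi_series: dict  # name -> LabeledSeries (deg C)
    gsr: SignalTrace | None
    beats_s: np.ndarray | None
    response: ResponseConfig  # this subject's true parameters
    seed: int
    video: ThermalVideo | None = None
    truth: GroundTruth | None = None


def _series_only_subject(phantom: FacePhantomConfig, resp: ResponseConfig,
                         design: EventDesign, rng: np.random.Generator,
                         roi_specs: Mapping[str, ROISpec]) -> dict[str, LabeledSeries]:
    """Programmed ROI curves plus mask-averaged sensor noise, skipping
    rasterization; emulates what extraction recovers from the video."""
    fs = phantom.fs_hz
    n = int(round(design.total_s * fs))
    t = np.arange(n) / fs
    field0 = _face_field(phantom, np.zeros(2))
    centres = _roi_centres(phantom, roi_specs)
    out = {}
    for name, spec in roi_specs.items():
        mask = rasterize_roi(spec, tuple(centres[name] - spec.offset_px), phantom.dims)
        base = float(field0[mask.pixels[:, 1], mask.pixels[:, 0]].mean())
        delta = _response_delta(t, design.onset_s, resp.latency_map.get(name, 0.0),
                                resp.amplitude_map.get(name, 0.0), resp.time_constant_s)
        noise_sd = phantom.sensor_noise_sd_C / np.sqrt(mask.n_pixels)
        v = base + delta + rng.normal(0.0, noise_sd, size=n)
        out[name] = LabeledSeries(SignalTrace(v, fs_hz=fs, units="degC"), roi_name=name)
    return out


def _vary_response(resp: ResponseConfig, rng: np.random.Generator,
                   amp_frac_sd: float, latency_sd_s: float) -> ResponseConfig:
    amps = tuple((name, a * float(np.clip(1 + rng.normal(0, amp_frac_sd), 0.2, 2.0)))
                 for name, a in resp.amplitudes_C)
    lats = tuple((name, float(np.clip(l + rng.normal(0, latency_sd_s), 0.5, 8.0)))
                 for name, l in resp.latencies_s)
    gsr_lat = float(np.clip(resp.gsr_latency_s + rng.normal(0, latency_sd_s / 2),
                            0.5, 3.0))
    return replace(resp, amplitudes_C=amps, latencies_s=lats, gsr_latency_s=gsr_lat)


def generate_cohort(n_subjects: int = 15,
                    phantom: FacePhantomConfig = FacePhantomConfig(),
                    resp: ResponseConfig = ResponseConfig(),
                    design: EventDesign = EventDesign(),
                    seed: int | None = 0,
                    mode: str = "series",
                    amp_frac_sd: float = 0.25,
                    latency_sd_s: float = 0.5,
                    include_gsr: bool = True,
                    include_ecg: bool = False,
                    gsr_fs_hz: float = 2000.0,
                    gsr_noise_sd: float = 0.01) -> list[SubjectData]:
    """Simulate a cohort; per-subject seeds spawn from the master seed.

    ``mode="series"`` emits the per-ROI temperature series directly (fast);
    ``mode="video"`` rasterizes full thermal videos per subject. Between-
    subject variation multiplies amplitudes by clipped 1 + N(0, amp_frac_sd)
    and shifts latencies by N(0, latency_sd_s).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if mode not in ("series", "video"):
        raise ValueError(f"unknown mode {mode!r}")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    roi_specs = default_roi_specs(phantom.scale)
    subjects = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(child)
        resp_i = _vary_response(resp, rng, amp_frac_sd, latency_sd_s)
        video = truth = None
        if mode == "video":
            video, truth = generate_thermal_video(phantom, resp_i, design,
                                                  seed=sub_seed, roi_specs=roi_specs)
            roi_series = {
                name: LabeledSeries(SignalTrace(curve.copy(), fs_hz=phantom.fs_hz,
                                                units="degC"), roi_name=name)
                for name, curve in truth.roi_curves.items()}
        else:
            roi_series = _series_only_subject(phantom, resp_i, design, rng, roi_specs)
        gsr = (generate_gsr(resp_i, design, fs_hz=gsr_fs_hz, noise_sd=gsr_noise_sd,
                            seed=sub_seed + 1) if include_gsr else None)
        beats = (generate_ecg_beats(resp_i, design, seed=sub_seed + 2)
                 if include_ecg else None)
        subjects.append(SubjectData(subject_id=f"sub{i + 1:02d}", roi_series=roi_series,
                                    gsr=gsr, beats_s=beats, response=resp_i,
                                    seed=sub_seed, video=video, truth=truth))
    return subjects
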