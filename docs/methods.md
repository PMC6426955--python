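# Methods

This note documents the models, defaults and numerical choices behind
`thermoface`, what the synthetic generator does and does not emulate, and
the known limitations of the procedures.

## Landmark fusion and temporal stabilization

A detector is any component that, given an enhanced intensity image,
returns 70 `(x, y, confidence)` triples per frame (68-point face mark-up
plus the two pupil centres, ids 68–69). Pixel coordinates are 0-based,
x = column rightward, y = row downward; all geometry in the package uses
this convention.

**Enhancement.** Detection operates on a percentile-clipped linear stretch
of the raw temperature frame to [0, 1]: values at or below the
`saturation_fraction` quantile (default 0.01) map to 0, at or above the
complementary quantile to 1, linearly in between, optionally followed by a
gamma exponent (default 1.0). A constant frame maps to all zeros.
Thermometry always reads the untouched raw frame; enhancement exists only
to make typical detectors work on thermal imagery.

**Cascade fusion.** Per point, with threshold *c* = 0.65: both detections
valid → coordinate-wise mean; exactly one valid → that detection; neither
valid → the higher-scoring detection, with an exact tie resolved toward
detector 1 (mirroring the cascade order in which the detectors are
consulted). The fused confidence is the maximum of the inputs, which
preserves "sufficient confidence" semantics for downstream validity
checks, and every point is always emitted — fusion never drops a point.
Fusion is symmetric in its two inputs except on exact ties.

**Stabilization.** A point within 5 px (inclusive) of its stabilized
location in the previous frame is kept. A rejected point is replaced by
the nearest point of the closed 5-px disc centred on the previous
location, i.e. radially projected onto the disc boundary along the segment
toward the candidate. This is parameter-free, preserves the candidate's
direction, and bounds every consecutive displacement by the radius. The
first frame is taken as-is. Tracking literature sometimes re-estimates a
rejected point from multiple initialization hypotheses; no such
re-detection is attempted here — only the validity/replacement rule is
applied.

**Accuracy.** Fraction of point instances within 5 px (Euclidean,
inclusive, with a 1e-9 round-off allowance) of ground truth, optionally
excluding a point-id subset (e.g. eyes/nose/outer mouth). On the synthetic
trajectories used in the acceptance script (1 px jitter, 20% dropout, 5%
outliers at 30 px), the fused+stabilized cascade scores slightly above
either single detector, which is the property that matters; absolute
percentages on synthetic jitter say nothing about real thermal footage.

## ROI thermometry

The reference point is the midpoint of the two medial (inner) eyebrow
landmarks, ids 21 and 22 in the 68-point convention (configurable — the
ids are a package default, chosen because the inner brow ends are the
most stably detected points in thermal imagery). ROIs are circles of
10-px radius at fixed pixel offsets from the reference; defaults for
640×480 framing are forehead (0, −60), nose tip (0, +90), right cheek
(−70, +70), left cheek (+70, +70), all configurable per subject exactly as
a one-time manual placement would be. Offsets scale with frame width; the
10-px radius is a measurement aperture and does not scale. The reference
is re-derived every frame from the tracked landmarks, so the ROIs follow
head motion.

Rasterization includes every integer pixel whose centre lies within the
radius of the (real-valued) circle centre; off-frame pixels are dropped
and counted, and a fully off-frame circle is a mask failure handled by the
caller's carry-forward. A radius-10 circle at an integer-valued centre
contains 317 lattice pixels.

Extraction takes the mean temperature over the mask per frame. A frame
with no usable landmarks repeats the previous frame's temperature value
(the default, matching the carry-forward rule as literally stated); the
alternative of applying the last valid mask to the current frame is
available via `carry_policy="previous_mask"`. Carried samples are flagged.

Outlier repair is a single pass: mean and sample SD (ddof = 1) of the full
series, outliers included; samples beyond 5 SDs are replaced by a cubic
spline fitted through the non-flagged samples. Flagged samples outside the
non-flagged span are filled with the nearest non-flagged value because
cubic extrapolation is unstable. Non-flagged samples pass through
bit-unchanged. Two consequences worth knowing: a constant series is a
no-op, and in a series of fewer than ~27 samples a single spike can never
be flagged, because the largest attainable z with sample SD is
(n−1)/√n < 5 for n ≤ 26. Z-scoring uses the full-series mean and sample
SD.

## Autonomic channels

**GSR.** Linear detrend, then a 501-tap Hamming windowed-sinc FIR low-pass
at 5 Hz applied forward–backward (`filtfilt`), then z-scoring. The
forward–backward pass squares the magnitude response and cancels the group
delay, so the latency of the slow electrodermal response is untouched —
essential because the lag analysis compares event latencies across
channels. The trace must be at least 3× the filter length.

**R peaks.** Deliberately simple: a ~30 ms moving average of the squared
derivative, an adaptive median + 8·MAD threshold, a 0.3 s refractory
period, and refinement to the local ECG maximum. Clinical-grade detection
(and manual correction) is out of scope; externally detected beat lists
pass through verbatim via `precomputed=`.

**HRV.** The IBI series (ms, attributed to the second beat of each pair)
is cubic-spline resampled to 2 Hz, then analysed in sliding windows of
16 s (32 samples) with 15-sample overlap, hence a 17-sample hop — the
overlap count is interpreted at the resampled rate, which the convention
leaves ambiguous. Per window the mean is removed, AR coefficients of order
16 (a common HRV default; configurable) are estimated by the Burg method
(via statsmodels), and the one-sided spectral density
S(f) = σ²/fs / |1 − Σ aₖ e^(−2πifk/fs)|² is evaluated on an nfft = 1024
grid and integrated (trapezoid) over vLF [0.003, 0.04), LF [0.04, 0.15)
and HF [0.15, 0.4] Hz. Percent power uses the within-band total
(vLF+LF+HF) as denominator, so the three percents sum to 100 by
construction. Windows with numerically zero variance — the floor is
relative, std < 1e-8·(1+|mean|), because beat times built from cumulative
sums carry ~1e-10 ms float noise — are flagged invalid and carry NaN
percents. Burg's residual variance is clamped to a tiny positive value so
that a noiseless sinusoid still yields a valid (sharply peaked) density.
A 16 s window resolves the 0.25 Hz HF tone cleanly; at 0.10 Hz it spans
only 1.6 cycles, so LF peak locations carry a few-bin bias even though
band attribution remains unambiguous.

## Event-locked statistics

Windows are half-open around the onset: pre = [onset − 5 s, onset),
post = (onset, onset + 10 s], so the onset sample belongs to neither. Per
channel, per-subject window means enter a paired two-sided t-test
(df = n − 1); the effect size is paired Cohen's d = d̄/s_d (the
convention had to be chosen; published tables rarely state it).
Benjamini–Hochberg (independence variant) at q = 0.05 is applied across
the four thermal channels only; GSR/IBI/HRV channels are reported
uncorrected, mirroring how such tables are usually presented.

**Lag estimation.** Both series are taken on the thermal sampling grid
(5 Hz; the 2 kHz GSR is linearly interpolated down), restricted to the
10 s post-stimulus window. r(τ) is the Pearson correlation of the
overlapping segments at each non-negative integer-sample lag τ; for the
anti-correlated thermal/GSR pair the lags of the 10 smallest r are
averaged (for positively correlated pairs, the 10 largest). Positive lag
means the response trails the reference. The default search range is 5 s —
half the window — because beyond that the overlapping segment becomes too
short for a stable correlation (at least 3 overlapping samples are
required, else an error), and physiological thermal lags are expected
under 2 s.

Known behaviour of this estimator, quantified by the acceptance script:
for shift-matched waveforms the single correlation extremum recovers the
programmed lag exactly at 5 Hz when noiseless, and averaged over noise
seeds stays within two samples at SNR 5. For waveforms that are *not*
shifted copies of each other — e.g. a monotone exponential cooling against
a rise–decay GSR bump — cross-correlation has no interior extremum at the
latency difference: the correlation valley is broad and its extremum can
sit at the search boundary. The mean-of-10-extrema variant reports the
valley centroid, which is robust to noise but biased upward for flat
valleys (visible in the worked example, where programmed latency
differences of ~1–2 s appear as ~4 s centroids). Latency differences
between dissimilar waveforms are fundamentally shape-confounded; the
package reports the full r(τ) curve so users can see the valley.

An `EventStudy` model holds per-subject, per-channel series and the
design; `.fit()` returns `EventStudyResults` with the per-channel table,
per-subject window means, per-subject lag curves and a `summary()`. The
forehead is excluded from lag analysis by default (it is the
minimal-change channel); this is configurable.

## Synthetic generator

The phantom is a 2-D Gaussian temperature field (background 26 °C, face
peak 34.5 °C, σ = 0.15/0.27 of frame width/height) — enough spatial
structure for masks, motion and extraction, with no pretence of rendering
a face. Seventy canonical landmarks ride rigidly on the field; motion is a
per-frame random walk (SD 0.3 px) plus slow sinusoidal sway (3 px
amplitude, 20 s period). Per-pixel Gaussian sensor noise defaults to
0.05 °C, the noise floor of a research-grade radiometric camera. Frames
default to 640×480 at 5 Hz for 60 s with the stimulus at 40 s; tests and
the acceptance script use half- or quarter-scale frames (offsets and
motion scale with width, the ROI aperture does not), which changes
rendering cost only.

Programmed responses: each ROI cools exponentially toward its amplitude
(nose −0.3 °C, cheeks −0.15 °C, forehead 0 — the built-in null channel)
after a latency (2.5 s nose, 3.5 s cheeks) with an 8 s time constant,
applied inside a response disc that scales with the frame (20 px at full
scale) so that the measurement aperture sits strictly inside it. GSR is a
baseline plus the kernel (u/r)^(r/d)·e^((r−u)/d), which peaks exactly at
u = r (latency 1.5 s, rise 4 s, decay 6 s → peak 5.5 s post-stimulus,
inside the 5–10 s range typical of startle responses). Beats come from
integrating an instantaneous rate with baseline RR 0.8 s, post-onset RR
lengthening (0.08 s, τ = 5 s) and sinusoidal LF (0.1 Hz) and HF (0.25 Hz)
modulation of 0.02 s each, firing a beat at every integer crossing of the
integrated rate.

Cohorts derive per-subject seeds from one master `SeedSequence`;
between-subject variation multiplies amplitudes by a clipped
1 + N(0, 0.25) and shifts latencies by N(0, 0.5 s) (GSR latency clipped to
the physiological 0.5–3 s). The default cohort size is 15. Series-only
mode emits the programmed ROI curves plus mask-averaged sensor noise
(σ/√317) directly, skipping rasterization; it is what makes 50-replicate
cohort studies run in seconds.

What the generator does **not** emulate: real thermal texture and
emissivity variation, non-rigid facial motion and expression, breathing
airflow artefacts on the nose tip, the transient spike sometimes seen
immediately post-stimulus, drift of the camera, or ECG waveform morphology
(beats are generated directly). Passing tests therefore demonstrate the
pipeline's correctness and its robustness to jitter, dropout, outliers and
sensor noise — not detector performance or physiological validity on real
recordings.

## Numerical and interface choices

- Window membership and lag windows use a 1e-9 time tolerance so that
  binary-float sample times at 5 Hz land on the intended side of window
  edges.
- Thermal stacks travel as `TSTACK v1` (one ASCII header line
  `TSTACK v1 width height n_frames fs_hz`, then frame-major, row-major
  float32) or as a directory of per-frame CSVs rounded to 2 decimals (the
  radiometric precision of the source data), with a YAML sidecar for the
  sampling rate. Readers validate shape, finiteness and header/payload
  consistency and never reorder or impute; all repairs happen downstream
  and are flagged.
- The CLI (`simulate`, `extract`, `analyze`, `report`) communicates only
  through files, writes a manifest of SHA-256 content hashes with the seed,
  contains no timestamps, and is byte-deterministic for a fixed config and
  seed. Exit codes: 0 ok, 1 user/config error, 2 data error.
- In `extract`, a frame's landmarks count as "not detected" for ROI
  purposes when either medial-brow confidence falls below the fusion
  threshold, or the ROI circle lies fully off-frame; the first frame must
  be usable, else the subject is rejected with a diagnostic.

## Limitations

- The detector contract is exercised only by mock detectors; no trained
  landmark network ships with the package.
- Lag estimates between dissimilar waveforms are shape-confounded (see
  above); treat per-subject mean lags as a relative, not absolute,
  latency measure.
- The 5-SD outlier rule is insensitive in short series (n ≤ 26) by
  arithmetic, and the single-pass convention means a gross artefact
  inflates the SD it is tested against.
- HRV percent power depends on the within-band-total denominator
  convention; absolute band powers are also reported for users who need a
  different normalization.
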