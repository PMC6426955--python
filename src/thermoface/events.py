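"""Event-locked statistics: baseline/response window means, paired t-tests
with BH-FDR over the thermal channels and paired Cohen's d, and the
cross-correlation estimate of the lag between thermal ROI responses and
GSR.

The modelling surface follows the statsmodels idiom: :class:`EventStudy`
is built from per-subject, per-channel series and an event design;
``.fit()`` returns an :class:`EventStudyResults` carrying the per-channel
statistics table, the per-subject lag curves, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

from .io import EventDesign, SignalTrace
from .roi import LabeledSeries

__all__ = [
    "StatsConfig",
    "LagConfig",
    "LagResult",
    "window_means",
    "paired_ttest",
    "cohens_d_paired",
    "fdr_correct",
    "crosscorr_lag",
    "EventStudy",
    "EventStudyResults",
]

THERMAL_CHANNELS = ("nose_tip", "right_cheek", "left_cheek", "forehead")
#: forehead excluded: its thermal response is the null/minimal-change channel
DEFAULT_LAG_CHANNELS = ("nose_tip", "right_cheek", "left_cheek")

_EPS = 1e-9


@dataclass(frozen=True)
class StatsConfig:
    fdr_q: float = 0.05
    alpha_tiers: tuple[float, ...] = (0.05, 0.01, 0.001)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")


@dataclass(frozen=True)
class LagConfig:
    """Cross-correlation lag search settings.

    ``max_lag_s`` defaults to half the 10 s analysis window: beyond that the
    overlapping segment becomes too short for a stable correlation (and the
    physiological lags of interest are 0-2 s).
    """

    max_lag_s: float = 5.0
    n_extrema: int = 10
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.n_extrema < 1:
            raise ValueError("n_extrema must be >= 1")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")


@dataclass
class LagResult:
    """Correlation-vs-lag curve and its extremal-lag summary."""

    lags_s: np.ndarray
    r: np.ndarray
    extremal_lags_s: np.ndarray
    mean_lag_s: float
    polarity: str


def _series_values(series) -> tuple[np.ndarray, np.ndarray]:
    trace = series.trace if isinstance(series, LabeledSeries) else series
    return trace.t_s, trace.values


def window_means(series, design: EventDesign) -> tuple[float, float]:
    """Baseline and response means: pre over [onset - pre_window, onset),
    post over (onset, onset + post_window]. Half-open so the onset sample
    belongs to neither window."""
    t, v = _series_values(series)
    pre = (t >= design.onset_s - design.pre_window_s - _EPS) & (t < design.onset_s - _EPS)
    post = (t > design.onset_s + _EPS) & (t <= design.onset_s + design.post_window_s + _EPS)
    if not pre.any() or not post.any():
        raise ValueError("empty pre- or post-stimulus window")
    return float(v[pre].mean()), float(v[post].mean())


def paired_ttest(pre: Sequence[float], post: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t-test on post - pre; returns (t, df, p)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 3:
        raise ValueError("pre and post must be equal-length vectors, n >= 3")
    d = post - pre
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences")
    res = ss.ttest_rel(post, pre)
    return float(res.statistic), len(d) - 1, float(res.pvalue)


def cohens_d_paired(pre: Sequence[float], post: Sequence[float]) -> float:
    """Paired Cohen's d: mean(post - pre) / SD(post - pre), sample SD."""
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    return float(d.mean() / sd)


def fdr_correct(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def _resample_to(trace: SignalTrace, fs: float) -> SignalTrace:
    if abs(trace.fs_hz - fs) < 1e-12:
        return trace
    t = trace.t_s
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n) / fs
    return SignalTrace(np.interp(grid, t, trace.values), fs_hz=fs,
                       units=trace.units, t0_s=float(t[0]))


def crosscorr_lag(reference, response, design: EventDesign,
                  cfg: LagConfig = LagConfig()) -> LagResult:
    """Lag of ``response`` behind ``reference`` in the post-stimulus window.

    Both series are taken on the response's sampling grid (the reference —
    typically GSR — is linearly interpolated down to it). r(tau) is the
    Pearson correlation between reference[0:N-k] and response[k:N] within
    the post-stimulus window, for non-negative lags tau = k/fs up to
    ``max_lag_s``. For negative polarity (thermal vs GSR) the ``n_extrema``
    lags with the smallest r are taken, for positive the largest; the
    reported lag is their mean. Positive lag = response lags the reference.
    """
    t_ref = reference.trace if isinstance(reference, LabeledSeries) else reference
    t_resp = response.trace if isinstance(response, LabeledSeries) else response
    fs = t_resp.fs_hz
    ref = _resample_to(t_ref, fs)

    def _window(tr: SignalTrace) -> np.ndarray:
        t = tr.t_s
        m = (t > design.onset_s + _EPS) & (t <= design.onset_s + design.post_window_s + _EPS)
        return tr.values[m]

    a = _window(ref)
    b = _window(t_resp)
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    k_max = int(round(cfg.max_lag_s * fs))
    if n - k_max < 3:
        raise ValueError("post-stimulus window too short for max_lag_s")
    lags = np.arange(k_max + 1) / fs
    r = np.empty(k_max + 1)
    for k in range(k_max + 1):
        x, y = a[: n - k], b[k:n]
        sx, sy = x.std(), y.std()
        r[k] = np.nan if sx == 0 or sy == 0 else float(np.corrcoef(x, y)[0, 1])
    order = np.argsort(r if cfg.polarity == "negative" else -r, kind="stable")
    order = order[~np.isnan(r[order])]
    ext = np.sort(lags[order[: cfg.n_extrema]])
    return LagResult(lags_s=lags, r=r, extremal_lags_s=ext,
                     mean_lag_s=float(ext.mean()), polarity=cfg.polarity)


# ---------------------------------------------------------------------------
# model / results

class EventStudy:
    """Event-locked study of per-subject physiological channels.

    Parameters
    ----------
    data
        Mapping ``subject -> channel -> series`` where each series is a
        :class:`LabeledSeries` or :class:`SignalTrace` (already z-scored;
        the model compares window means, so any common affine scale works).
    design
        The stimulus/window design shared by all subjects.
    thermal_channels
        Channels over which the BH-FDR correction is applied (per-channel
        t-tests are reported for every channel regardless).
    reference_channel
        Channel used as the lag reference (typically ``"gsr"``); lag
        estimation is skipped for subjects lacking it.
    lag_channels
        Response channels entered into the lag analysis.
    """

    def __init__(self, data: Mapping[str, Mapping[str, object]], design: EventDesign,
                 config: StatsConfig = StatsConfig(),
                 thermal_channels: Sequence[str] = THERMAL_CHANNELS,
                 reference_channel: str = "gsr",
                 lag_channels: Sequence[str] = DEFAULT_LAG_CHANNELS,
                 lag_config: LagConfig = LagConfig()):
        if len(data) < 3:
            raise ValueError("need at least 3 subjects for paired statistics")
        self.data = dict(data)
        self.design = design
        self.config = config
        self.thermal_channels = tuple(thermal_channels)
        self.reference_channel = reference_channel
        self.lag_channels = tuple(lag_channels)
        self.lag_config = lag_config
        self.channels = sorted({ch for subj in data.values() for ch in subj})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design: EventDesign, **kwargs) -> "EventStudy":
        """Build from a tidy frame with columns subject, channel, time_s, value."""
        required = {"subject", "channel", "time_s", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"data frame needs columns {sorted(required)}")
        data: dict[str, dict[str, SignalTrace]] = {}
        for (subj, ch), g in df.groupby(["subject", "channel"], sort=True):
            t = g["time_s"].to_numpy(dtype=float)
            dt = np.diff(t)
            if len(t) < 2 or np.any(np.abs(dt - np.median(dt)) > 1e-6):
                raise ValueError(f"non-uniform sampling for {subj}/{ch}")
            data.setdefault(str(subj), {})[str(ch)] = SignalTrace(
                g["value"].to_numpy(dtype=float), fs_hz=1.0 / float(np.median(dt)),
                t0_s=float(t[0]))
        return cls(data, design, **kwargs)

    def fit(self) -> "EventStudyResults":
        rows = []
        per_subject = []
        for ch in self.channels:
            pre_vals, post_vals = [], []
            for subj, channels in self.data.items():
                if ch not in channels:
                    continue
                pre, post = window_means(channels[ch], self.design)
                pre_vals.append(pre)
                post_vals.append(post)
                per_subject.append({"subject": subj, "channel": ch,
                                    "pre_mean": pre, "post_mean": post})
            n = len(pre_vals)
            if n < 3:
                raise ValueError(f"channel {ch!r} present for fewer than 3 subjects")
            pre_a, post_a = np.array(pre_vals), np.array(post_vals)
            t, df_, p = paired_ttest(pre_a, post_a)
            rows.append({
                "channel": ch, "n": n,
                "pre_mean": pre_a.mean(), "post_mean": post_a.mean(),
                "pre_sem": pre_a.std(ddof=1) / np.sqrt(n),
                "post_sem": post_a.std(ddof=1) / np.sqrt(n),
                "t": t, "df": df_, "p": p,
                "effect_size": cohens_d_paired(pre_a, post_a),
            })
        table = pd.DataFrame(rows).set_index("channel")
        thermal = [ch for ch in self.thermal_channels if ch in table.index]
        table["fdr_significant"] = False
        table["p_fdr"] = np.nan
        if thermal:
            reject, p_adj = fdr_correct(table.loc[thermal, "p"].to_numpy(),
                                        q=self.config.fdr_q)
            table.loc[thermal, "fdr_significant"] = reject
            table.loc[thermal, "p_fdr"] = p_adj

        lag_rows, lag_curves = [], {}
        for subj, channels in self.data.items():
            ref = channels.get(self.reference_channel)
            if ref is None:
                continue
            for ch in self.lag_channels:
                if ch not in channels:
                    continue
                res = crosscorr_lag(ref, channels[ch], self.design, self.lag_config)
                lag_curves[(subj, ch)] = res
                lag_rows.append({"subject": subj, "channel": ch,
                                 "mean_lag_s": res.mean_lag_s,
                                 "r_at_extreme": float(np.nanmin(res.r))
                                 if res.polarity == "negative" else float(np.nanmax(res.r))})
        lags = pd.DataFrame(lag_rows)
        return EventStudyResults(self, table, pd.DataFrame(per_subject), lags, lag_curves)


@dataclass
class EventStudyResults:
    """Fitted event-locked statistics.

    ``table`` holds per-channel pre/post means and SEMs, paired t, df, p,
    paired Cohen's d, and the BH-FDR decision over the thermal channels;
    ``subject_means`` the per-subject window means behind them; ``lags``
    per-subject mean lags with the correlation extremum; ``lag_curves`` the
    full correlation-vs-lag curves keyed by (subject, channel).
    """

    model: EventStudy
    table: pd.DataFrame
    subject_means: pd.DataFrame
    lags: pd.DataFrame
    lag_curves: dict

    def mean_lags(self) -> pd.Series:
        if self.lags.empty:
            return pd.Series(dtype=float, name="mean_lag_s")
        return self.lags.groupby("channel")["mean_lag_s"].mean()

    def _stars(self, p: float) -> str:
        tiers = sorted(self.model.config.alpha_tiers, reverse=True)
        return "*" * sum(p < a for a in tiers)

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Event-locked study summary",
            f"  subjects: {len(self.model.data)}   channels: {len(self.table)}",
            f"  windows: pre {d.pre_window_s:g} s / post {d.post_window_s:g} s "
            f"around onset at {d.onset_s:g} s",
            "",
            f"  {'channel':<14}{'pre':>8}{'post':>8}{'t':>8}{'df':>4}"
            f"{'p':>10}{'d':>7}  FDR",
        ]
        for ch, row in self.table.iterrows():
            fdr = "sig" if row["fdr_significant"] else (
                "ns" if ch in self.model.thermal_channels else "-")
            lines.append(
                f"  {ch:<14}{row['pre_mean']:>8.3f}{row['post_mean']:>8.3f}"
                f"{row['t']:>8.2f}{int(row['df']):>4}{row['p']:>10.4g}"
                f"{row['effect_size']:>7.2f}  {fdr}{self._stars(row['p'])}")
        ml = self.mean_lags()
        if not ml.empty:
            lines.append("")
            lines.append("  mean lag behind reference (s):")
            for ch, v in ml.items():
                lines.append(f"    {ch:<14}{v:>7.2f}")
        return "\n".join(lines)

    def to_csv(self, stats_path, lags_path=None) -> None:
        cols = ["n", "pre_mean", "post_mean", "pre_sem", "post_sem",
                "t", "df", "p", "effect_size", "p_fdr", "fdr_significant"]
        self.table[cols].to_csv(stats_path, float_format="%.10g")
        if lags_path is not None:
            self.lags.to_csv(lags_path, index=False, float_format="%.10g")
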