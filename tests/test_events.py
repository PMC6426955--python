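import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermoface import (EventDesign, EventStudy, LagConfig, SignalTrace,
                        cohens_d_paired, crosscorr_lag, fdr_correct,
                        paired_ttest, window_means)
from thermoface.synthetic import ResponseConfig, generate_cohort
from thermoface.roi import repair_outliers, zscore


def bh_stepup_oracle(p, q):
    """Independent Benjamini-Hochberg enumeration: largest k with
    p_(k) <= k*q/m rejects the k smallest p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


def gsr_kernel(t, onset, latency, rise=4.0, decay=6.0):
    u = t - onset - latency
    out = np.zeros_like(t)
    m = u > 0
    a = rise / decay
    out[m] = (u[m] / rise) ** a * np.exp((rise - u[m]) / decay)
    return out


class TestWindowMeans:
    def test_constant_series(self):
        s = SignalTrace(np.full(300, 0.5), fs_hz=5.0)
        assert window_means(s, EventDesign()) == (0.5, 0.5)

    def test_step_series(self):
        v = np.where(np.arange(300) / 5.0 <= 40.0, -1.0, 1.0)
        assert window_means(SignalTrace(v, fs_hz=5.0), EventDesign()) == (-1.0, 1.0)

    def test_sample_counts_exclude_onset(self):
        # at 5 Hz with onset 40: pre = samples 175..199, post = 201..250
        v = np.arange(301, dtype=float)
        pre, post = window_means(SignalTrace(v, fs_hz=5.0), EventDesign())
        assert pre == pytest.approx((175 + 199) / 2)
        assert post == pytest.approx((201 + 250) / 2)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_means(SignalTrace(np.zeros(10), fs_hz=5.0), EventDesign())


class TestPairedT:
    def test_worked_example(self):
        t, df, p = paired_ttest([1, 2, 3], [3, 3, 5])
        assert t == pytest.approx(5.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(0.0377, abs=5e-4)

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 30)
            pre = rng.normal(size=n)
            post = pre + rng.normal(0.3, 1.0, size=n)
            if np.std(post - pre, ddof=1) == 0:
                continue
            t, df, p = paired_ttest(pre, post)
            d = post - pre
            t_oracle = d.mean() / (np.std(d, ddof=1) / np.sqrt(n))
            assert t == pytest.approx(t_oracle, abs=1e-10)
            assert df == n - 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestEffectSize:
    def test_worked_example(self):
        assert cohens_d_paired([1, 2, 3], [3, 3, 5]) == pytest.approx(2.887, abs=1e-3)

    def test_antisymmetric(self):
        rng = np.random.default_rng(1)
        pre, post = rng.normal(size=20), rng.normal(0.5, 1, size=20)
        assert cohens_d_paired(pre, post) == pytest.approx(
            -cohens_d_paired(post, pre), abs=1e-12)

    def test_symmetric_noise_gives_near_zero(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(size=20000)
        post = pre + rng.normal(0, 1, size=20000)
        assert abs(cohens_d_paired(pre, post)) < 0.03


class TestFDR:
    def test_all_rejected_when_largest_p_clears_stepup(self):
        reject, _ = fdr_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_none_rejected(self):
        reject, _ = fdr_correct([0.9, 0.95], q=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = fdr_correct([0.04], q=0.05)
        assert reject.all()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
           st.floats(0.01, 0.2))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_stepup_enumeration(self, p, q):
        reject, _ = fdr_correct(p, q=q)
        assert np.array_equal(reject, bh_stepup_oracle(p, q))

    def test_flags_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 0.3, 8)
        reject, _ = fdr_correct(p, q=0.1)
        if reject.any():
            assert p[reject].max() <= p[~reject].min() if (~reject).any() else True


class TestCrossCorrLag:
    def _design(self):
        return EventDesign()

    def _ref(self):
        t = np.arange(300) / 5.0
        return SignalTrace(gsr_kernel(t, 40.0, 1.5), fs_hz=5.0)

    def test_pure_shift_recovered(self):
        design = self._design()
        ref = self._ref()
        t = ref.t_s
        resp = SignalTrace(-gsr_kernel(t, 40.0, 1.5 + 0.6), fs_hz=5.0)
        res = crosscorr_lag(ref, resp, design)
        assert res.lags_s[np.argmin(res.r)] == pytest.approx(0.6, abs=1e-9)
        assert abs(res.mean_lag_s - 0.6) <= 0.4

    def test_zero_shift_minimum_at_origin(self):
        ref = self._ref()
        resp = SignalTrace(-ref.values, fs_hz=5.0)
        res = crosscorr_lag(ref, resp, self._design())
        assert res.lags_s[np.argmin(res.r)] == 0.0
        assert res.r[0] == pytest.approx(-1.0, abs=1e-12)

    def test_identity_with_positive_polarity(self):
        ref = self._ref()
        res = crosscorr_lag(ref, ref, self._design(),
                            LagConfig(polarity="positive"))
        assert res.lags_s[np.argmax(res.r)] == 0.0
        assert res.r[0] == pytest.approx(1.0, abs=1e-12)

    def test_window_too_short_for_lag_range_rejected(self):
        ref = self._ref()
        with pytest.raises(ValueError):
            crosscorr_lag(ref, ref, self._design(), LagConfig(max_lag_s=10.0))

    def test_reference_resampled_from_its_own_rate(self):
        # GSR at 100 Hz against a 5 Hz thermal series
        design = self._design()
        t_hi = np.arange(6000) / 100.0
        ref = SignalTrace(gsr_kernel(t_hi, 40.0, 1.5), fs_hz=100.0)
        t_lo = np.arange(300) / 5.0
        resp = SignalTrace(-gsr_kernel(t_lo, 40.0, 2.5), fs_hz=5.0)
        res = crosscorr_lag(ref, resp, design)
        assert res.lags_s[np.argmin(res.r)] == pytest.approx(1.0, abs=1e-9)


def test_programmed_lags_recovered_under_noise():
    """Shifted rise-decay pairs: lags 0.2-2.0 s recovered within one sample
    when noiseless; with additive noise at SNR 5 the estimate averaged over
    20 seeds stays within 0.4 s (two samples) of the programmed lag."""
    design = EventDesign()
    t = np.arange(300) / 5.0
    ref_clean = gsr_kernel(t, 40.0, 1.5)
    sig_rms = np.sqrt(np.mean(ref_clean[t > 40] ** 2))
    for lag in np.arange(0.2, 2.01, 0.2):
        resp_clean = -gsr_kernel(t, 40.0, 1.5 + lag)
        res = crosscorr_lag(SignalTrace(ref_clean, fs_hz=5.0),
                            SignalTrace(resp_clean, fs_hz=5.0), design)
        assert abs(res.lags_s[np.argmin(res.r)] - lag) <= 0.2 + 1e-9
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(1000 * seed + int(round(lag * 10)))
            noise = sig_rms / 5.0
            res_n = crosscorr_lag(
                SignalTrace(ref_clean + rng.normal(0, noise, t.size), fs_hz=5.0),
                SignalTrace(resp_clean + rng.normal(0, noise, t.size), fs_hz=5.0),
                design)
            estimates.append(res_n.lags_s[np.argmin(res_n.r)])
        assert abs(np.mean(estimates) - lag) <= 0.4 + 1e-9


class TestEventStudy:
    def _cohort_data(self, n=15, seed=0, null=False):
        resp = ResponseConfig()
        if null:
            resp = ResponseConfig(amplitudes_C=tuple((k, 0.0)
                                                     for k, _ in resp.amplitudes_C))
        subjects = generate_cohort(n_subjects=n, resp=resp, seed=seed,
                                   include_gsr=False)
        return {s.subject_id: {name: zscore(repair_outliers(series))
                               for name, series in s.roi_series.items()}
                for s in subjects}

    def test_fit_produces_full_table(self):
        data = self._cohort_data()
        res = EventStudy(data, EventDesign()).fit()
        assert set(res.table.index) == {"nose_tip", "right_cheek", "left_cheek",
                                        "forehead"}
        for col in ("pre_mean", "post_mean", "pre_sem", "post_sem", "t", "df",
                    "p", "effect_size", "fdr_significant"):
            assert col in res.table.columns
        assert (res.table["df"] == 14).all()

    def test_nose_dip_detected_and_null_forehead_spared(self):
        res = EventStudy(self._cohort_data(seed=42), EventDesign()).fit()
        assert res.table.loc["nose_tip", "fdr_significant"]
        assert res.table.loc["nose_tip", "post_mean"] < res.table.loc["nose_tip", "pre_mean"]
        assert not res.table.loc["forehead", "fdr_significant"]

    def test_summary_lists_channels(self):
        res = EventStudy(self._cohort_data(), EventDesign()).fit()
        text = res.summary()
        assert "nose_tip" in text and "forehead" in text

    def test_from_dataframe_round_trip(self):
        data = self._cohort_data(n=4)
        rows = []
        for subj, channels in data.items():
            for ch, series in channels.items():
                tr = series.trace
                for t, v in zip(tr.t_s, tr.values):
                    rows.append({"subject": subj, "channel": ch,
                                 "time_s": t, "value": v})
        model = EventStudy.from_dataframe(pd.DataFrame(rows), EventDesign())
        res = model.fit()
        direct = EventStudy(data, EventDesign()).fit()
        pd.testing.assert_frame_equal(res.table, direct.table)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            EventStudy(dict(list(self._cohort_data(n=4).items())[:2]), EventDesign())
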