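"""Bioristor response processing: R arithmetic, smoothing, normalization,
event detection and treatment divergence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fieldscale.bioristor import (compute_response, daily_smooth,
                                  detect_events, minmax_normalize,
                                  treatment_divergence)
from fieldscale.containers import BioristorTrace
from fieldscale.errors import ValidationError
from fieldscale.synthetic import simulate_bioristor_trace


def make_trace(ids, ids0, plot="p"):
    n = len(ids)
    ts = pd.date_range("2019-06-01", periods=n, freq="15min")
    return BioristorTrace(plot, ts, np.asarray(ids, float), np.asarray(ids0, float))


FLAT_SCHEDULE = pd.Series(0.0, index=np.arange(30, 91))


class TestResponse:
    def test_identity_gives_zero(self):
        r = compute_response(make_trace([-10e-6] * 4, [-10e-6] * 4))
        assert np.allclose(r, 0.0)

    @pytest.mark.parametrize("ids, ids0", [(5e-6, 10e-6), (-5e-6, -10e-6)])
    def test_half_current_gives_half_response(self, ids, ids0):
        r = compute_response(make_trace([ids] * 4, [ids0] * 4))
        assert np.allclose(r, 0.5)

    def test_scale_invariance(self, rng):
        ids = rng.uniform(-20e-6, -5e-6, 16)
        ids0 = rng.uniform(-15e-6, -8e-6, 16)
        a = compute_response(make_trace(ids, ids0))
        b = compute_response(make_trace(ids * 3.7, ids0 * 3.7))
        assert np.allclose(a, b)

    def test_zero_reference_handling(self):
        with pytest.raises(ValidationError):
            compute_response(make_trace([1e-6] * 4, [0.0] * 4))
        with pytest.warns(UserWarning, match="Ids0 == 0"):
            r = compute_response(make_trace([1e-6] * 4, [1e-6, 0.0, 1e-6, 1e-6]))
        assert np.isnan(r.iloc[1]) and r.notna().sum() == 3


class TestSmoothing:
    def test_constant_series_unchanged(self):
        s = compute_response(make_trace([-15e-6] * 96 * 3, [-10e-6] * 96 * 3))
        daily = daily_smooth(s, transplant_date="2019-05-01")
        assert np.allclose(daily, 0.5)

    def test_diurnal_oscillation_averages_out(self):
        ts = pd.date_range("2019-06-01", periods=96 * 4, freq="15min")
        hours = np.arange(96 * 4) * 0.25
        x = pd.Series(1.0 + 0.3 * np.sin(2 * np.pi * hours / 24), index=ts)
        daily = daily_smooth(x, transplant_date="2019-05-01")
        inner = daily.iloc[1:-1]  # edge days have partial windows
        assert np.allclose(inner, 1.0, atol=0.01)

    def test_short_series_best_effort(self):
        ts = pd.date_range("2019-06-01", periods=8, freq="15min")
        with pytest.warns(UserWarning, match="shorter than one smoothing window"):
            daily = daily_smooth(pd.Series(np.arange(8.0), index=ts))
        assert len(daily) == 1

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            daily_smooth(pd.Series(dtype=float, index=pd.DatetimeIndex([])))


class TestNormalize:
    def test_arithmetic(self):
        out = minmax_normalize(pd.Series([2.0, 4.0, 6.0]))
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        s = pd.Series([0.0, 0.3, 1.0])
        assert np.allclose(minmax_normalize(s), s)

    def test_constant_series_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant series"):
            out = minmax_normalize(pd.Series([3.0, 3.0]))
        assert np.allclose(out, 0.0)

    def test_monotone(self, rng):
        s = pd.Series(rng.normal(size=50))
        out = minmax_normalize(s)
        assert (np.argsort(out.to_numpy()) == np.argsort(s.to_numpy())).all()


class TestEvents:
    def test_flat_series_has_no_events(self):
        ts = pd.date_range("2019-06-01", periods=200, freq="15min")
        assert detect_events(pd.Series(1.0, index=ts), 0.05).empty

    def test_injected_rain_kernels_recovered(self):
        events = ((40, "rain", 5.0), (50, "rain", 10.0), (60, "rain", 7.0))
        tr = simulate_bioristor_trace("p", FLAT_SCHEDULE, events,
                                      noise_sd=0.0, diurnal_amplitude=0.0)
        found = detect_events(compute_response(tr), 0.04)
        assert len(found) == 3
        expected = [pd.Timestamp("2019-05-01") + pd.Timedelta(days=d, hours=10)
                    for d, _, _ in events]
        step = pd.Timedelta(minutes=15)
        for t_found, t_true in zip(found["time"], expected):
            assert abs(t_found - t_true) <= step

    def test_amplitude_proportional_to_intensity(self):
        tr = simulate_bioristor_trace(
            "p", FLAT_SCHEDULE, ((40, "rain", 5.0), (55, "rain", 10.0)),
            noise_sd=0.002, diurnal_amplitude=0.0, seed=9)
        found = detect_events(compute_response(tr), 0.04)
        ratio = found["amplitude"].iloc[1] / found["amplitude"].iloc[0]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_drought_ramp_lowers_final_response(self):
        ramp = pd.Series(np.clip((np.arange(30, 91) - 60) / 20, 0, 1),
                         index=np.arange(30, 91))
        tr = simulate_bioristor_trace("p", ramp, noise_sd=0.0)
        daily = daily_smooth(compute_response(tr), transplant_date="2019-05-01")
        assert daily.iloc[-2] < daily.iloc[1]


class TestDivergence:
    @staticmethod
    def daily_table(offsets_by_treatment, n_traces=3, dats=range(40, 60), sd=0.0,
                    seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for trt, offset in offsets_by_treatment.items():
            for k in range(n_traces):
                for dat in dats:
                    rows.append({"dat": dat, "treatment": trt,
                                 "trace_id": f"{trt}#{k}",
                                 "r": offset + (rng.normal(0, sd) if sd else 0.0)})
        return pd.DataFrame(rows)

    def test_identical_traces_never_diverge(self):
        onset, p = treatment_divergence(self.daily_table({100: 1.0, 40: 1.0}))
        assert onset is None and p.isna().all()

    def test_alpha_one_diverges_immediately(self):
        tbl = self.daily_table({100: 1.0, 40: 0.9}, sd=0.01, seed=3)
        onset, _ = treatment_divergence(tbl, alpha=1.0, consecutive=1)
        assert onset == 40

    def test_single_replicate_rejected(self):
        tbl = self.daily_table({100: 1.0, 40: 0.5}, n_traces=1)
        with pytest.raises(ValidationError):
            treatment_divergence(tbl)

    def test_onset_located_at_separation_start(self):
        rng = np.random.default_rng(5)
        rows = []
        for trt, drop in ((100, 0.0), (80, 0.0), (40, 0.04)):
            for k in range(5):
                for dat in range(55, 80):
                    level = 1.0 - drop * max(0, dat - 65)
                    rows.append({"dat": dat, "treatment": trt,
                                 "trace_id": f"{trt}#{k}",
                                 "r": level + rng.normal(0, 0.01)})
        onset, _ = treatment_divergence(pd.DataFrame(rows), alpha=0.001)
        assert onset is not None and abs(onset - 65) <= 3
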