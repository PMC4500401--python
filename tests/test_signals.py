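import numpy as np
import pytest
from scipy.signal import lfilter

from n2mbw.domain import ARGON_N2_RATIO, SignalTrace
from n2mbw.signals import (align_signals, btps_factors, correct_co2_dynamic,
                           correct_o2_drift, correct_o2_response_time,
                           derive_n2, preprocess, saturation_pressure_hPa)

FS = 200.0


def _trace(fo2, fco2=None, flow=None):
    n = len(fo2)
    if fco2 is None:
        fco2 = np.zeros(n)
    if flow is None:
        flow = np.zeros(n)
    return SignalTrace(sample_rate=FS, time=np.arange(n) / FS,
                       flow=flow, fo2=np.asarray(fo2, float), fco2=fco2)


class TestAlign:
    def test_zero_delays_identity(self):
        tr = _trace(np.random.default_rng(0).random(100))
        out = align_signals(tr, 0.0, 0.0)
        np.testing.assert_array_equal(out.fo2, tr.fo2)
        np.testing.assert_array_equal(out.fco2, tr.fco2)

    def test_step_round_trip_integer_samples(self):
        # a step delayed by exactly 600 ms is restored within one sample
        x = np.zeros(1000)
        x[500:] = 1.0
        shift = int(0.6 * FS)
        delayed = np.concatenate([np.full(shift, x[0]), x[:-shift]])
        out = align_signals(_trace(delayed), 600.0, 0.0)
        edge = np.flatnonzero(out.fo2 > 0.5)[0]
        assert abs(edge - 500) <= 1

    def test_fractional_delay_round_trip_band_limited(self):
        # respiratory-band signal: advance by 602.5 ms (fractional sample),
        # then shift back; linear interpolation round-trips to ~1e-5
        t = np.arange(4000) / FS
        x = 0.5 + 0.3 * np.sin(2 * np.pi * 0.25 * t) \
            + 0.05 * np.sin(2 * np.pi * 1.0 * t)
        adv = align_signals(_trace(x), 602.5, 0.0).fo2
        idx = np.arange(len(adv)) - 602.5 / 1000.0 * FS
        back = np.interp(idx, np.arange(len(adv)), adv)
        core = slice(200, -200)  # away from held edges
        assert np.max(np.abs(back[core] - x[core])) < 1e-4

    def test_flow_untouched_and_delay_too_long_raises(self):
        tr = _trace(np.ones(100), flow=np.arange(100.0))
        out = align_signals(tr, 100.0, 0.0)
        np.testing.assert_array_equal(out.flow, tr.flow)
        with pytest.raises(ValueError):
            align_signals(tr, 2000.0, 0.0)


class TestResponseTime:
    def test_tau_zero_identity_and_constant_unchanged(self):
        x = np.full(50, 0.7)
        np.testing.assert_array_equal(correct_o2_response_time(x, 0.0, FS), x)
        np.testing.assert_allclose(correct_o2_response_time(x, 30.0, FS), x,
                                   atol=1e-12)

    def test_step_recovery_through_forward_lag(self):
        # forward first-order lag (tau 30 ms), then inversion: >= 95% of the
        # step height recovered within 2 samples of the edge
        tau, dt = 0.030, 1.0 / FS
        x = np.zeros(400)
        x[200:] = 1.0
        b0 = dt / (2 * tau + dt)
        a1 = (2 * tau - dt) / (2 * tau + dt)
        lagged = lfilter([b0, b0], [1.0, -a1], x)
        rec = correct_o2_response_time(lagged, 30.0, FS)
        assert rec[202] >= 0.95


class TestDrift:
    def _washout_like(self, drift_per_min):
        # alternating inspiration (fo2 = 1) / expiration (fo2 = 0.93) breaths
        n_half = 300
        breaths = 12
        fo2, flow = [], []
        for _ in range(breaths):
            fo2 += [np.full(n_half, 1.0), np.full(n_half, 0.93)]
            flow += [np.full(n_half, 200.0), np.full(n_half, -200.0)]
        fo2 = np.concatenate(fo2)
        t = np.arange(len(fo2)) / FS
        return fo2 + drift_per_min * t / 60.0, np.concatenate(flow), t

    def test_injected_drift_removed(self):
        fo2, flow, t = self._washout_like(0.001)
        out = correct_o2_drift(fo2, flow, t, enabled=True)
        # inspired plateaus back at 1.0
        insp = out[(flow > 0)]
        assert np.abs(np.median(insp) - 1.0) < 1e-4

    def test_zero_drift_near_identity(self):
        fo2, flow, t = self._washout_like(0.0)
        out = correct_o2_drift(fo2, flow, t, enabled=True)
        assert np.max(np.abs(out - fo2)) < 1e-5

    def test_disabled_bit_identical(self):
        fo2, flow, t = self._washout_like(0.002)
        np.testing.assert_array_equal(
            correct_o2_drift(fo2, flow, t, enabled=False), fo2)

    def test_no_plateaus_warns_and_returns_identity(self):
        fo2 = np.full(100, 0.2)
        flow = np.concatenate([np.full(50, 100.0), np.full(50, -100.0)])
        with pytest.warns(UserWarning):
            out = correct_o2_drift(fo2, flow, np.arange(100) / FS, enabled=True)
        np.testing.assert_array_equal(out, fo2)


class TestDynamicCO2:
    def test_identity_cases(self):
        fco2 = np.array([0.01, 0.05])
        fo2 = np.array([0.5, 0.9])
        np.testing.assert_array_equal(
            correct_co2_dynamic(fco2, fo2, enabled=True, kd=0.0), fco2)
        np.testing.assert_allclose(
            correct_co2_dynamic(fco2, np.full(2, 0.2095), True, 0.05), fco2)

    def test_worked_example(self):
        out = correct_co2_dynamic(np.array([0.05]), np.array([1.0]), True, 0.05)
        assert out[0] == pytest.approx(0.051976, abs=1e-6)


class TestDeriveN2:
    @pytest.mark.parametrize("fo2,fco2,expected", [
        (1.0, 0.0, 0.0),
        (0.2095, 0.0004, 0.78080),
        (0.6, 0.04, 0.35576),
    ])
    def test_worked_examples(self, fo2, fco2, expected):
        fn2, _ = derive_n2(np.array([fo2]), np.array([fco2]))
        assert fn2[0] == pytest.approx(expected, abs=1e-5)

    def test_gas_sum_closes_with_argon(self):
        rng = np.random.default_rng(1)
        fo2 = rng.uniform(0.15, 0.95, 100)
        fco2 = rng.uniform(0.0, 0.05, 100)
        fn2, raw = derive_n2(fo2, fco2)
        total = fo2 + fco2 + fn2 * (1 + ARGON_N2_RATIO)
        np.testing.assert_allclose(total[fn2 == raw], 1.0, atol=1e-9)

    def test_clipping_kept_separately(self):
        fn2, raw = derive_n2(np.array([1.02]), np.array([0.05]))
        assert fn2[0] == 0.0 and raw[0] < 0.0


class TestBTPS:
    def test_disabled(self):
        assert btps_factors(21.0, 980.0, enabled=False) == (1.0, 1.0)

    def test_saturated_body_temperature_identity(self):
        # ambient at body temperature and 100% humidity: no conversion
        f_insp, _ = btps_factors(37.0, 900.0, True, rh=1.0)
        assert f_insp == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_21C_980hPa(self):
        f_insp, f_exp = btps_factors(21.0, 980.0, True, rh=0.5)
        assert f_insp == pytest.approx(1.1121, abs=2e-4)
        assert f_exp > 1.0  # expired gas at 34 C expands toward 37 C

    def test_low_pressure_raises(self):
        with pytest.raises(ValueError):
            btps_factors(21.0, 50.0, True)

    def test_magnus_at_body_temperature(self):
        assert saturation_pressure_hPa(37.0) == pytest.approx(62.66, abs=0.05)


class TestPipeline:
    def test_null_settings_identity(self, one_comp_clean):
        trace, _, null_profile = one_comp_clean
        null = null_profile.replace(btps_enabled=False,
                                    o2_drift_correction=False,
                                    dynamic_co2_correction=False)
        out = preprocess(trace, null)
        np.testing.assert_array_equal(out.trace.fo2, trace.fo2)
        np.testing.assert_array_equal(out.trace.fco2, trace.fco2)
        assert out.btps_factors == (1.0, 1.0)

    def test_fn2_within_bounds_and_sum_invariant(self, one_comp_full):
        trace, _, profile = one_comp_full
        out = preprocess(trace, profile)
        assert np.all(out.fn2 >= 0.0) and np.all(out.fn2 <= 1.0)
        unclipped = out.fn2 == out.fn2_raw
        total = (out.trace.fo2 + out.trace.fco2
                 + out.fn2 * (1 + ARGON_N2_RATIO))
        np.testing.assert_allclose(total[unclipped], 1.0, atol=1e-9)
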