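import numpy as np
import pytest

from n2mbw.breaths import detect_breaths, reinspired_n2, segment
from n2mbw.domain import SignalTrace, default_profile
from n2mbw.signals import AlignedTrace, preprocess

FS = 200.0


def _sinusoid_trace(period_s=4.0, vt_mL=500.0, duration_s=60.0):
    t = np.arange(int(duration_s * FS)) / FS
    amp = np.pi * vt_mL / period_s
    flow = amp * np.sin(2 * np.pi * t / period_s)
    return SignalTrace(sample_rate=FS, time=t, flow=flow,
                       fo2=np.full(len(t), 0.21), fco2=np.zeros(len(t)))


def _aligned(trace, fn2=None):
    prof = default_profile(2).replace(btps_enabled=False)
    n = trace.n_samples
    tr = trace.copy()
    tr.fn2 = np.full(n, 0.5) if fn2 is None else fn2
    return AlignedTrace(trace=tr, fn2_raw=tr.fn2, applied_settings=prof,
                        btps_factors=(1.0, 1.0))


class TestDetectBreaths:
    def test_counts_15_breaths_in_60s_at_period_4(self):
        spans = detect_breaths(_sinusoid_trace(), min_tidal_volume_mL=25.0)
        assert len(spans) == 15

    def test_all_below_threshold_raises(self):
        with pytest.raises(ValueError, match="minimum tidal volume"):
            detect_breaths(_sinusoid_trace(), min_tidal_volume_mL=600.0)

    def test_mini_breath_merged_not_dropped(self):
        # regular breathing with one interposed 40 mL mini-breath
        t_reg = _sinusoid_trace(duration_s=20.0)  # 5 regular breaths
        mini_t = np.arange(int(1.0 * FS)) / FS
        mini = np.pi * 40.0 * np.sin(2 * np.pi * mini_t / 1.0)
        flow = np.concatenate([t_reg.flow[:int(8 * FS)], mini,
                               t_reg.flow[int(8 * FS):]])
        n = len(flow)
        tr = SignalTrace(sample_rate=FS, time=np.arange(n) / FS, flow=flow,
                         fo2=np.full(n, 0.21), fco2=np.zeros(n))
        merged = detect_breaths(tr, min_tidal_volume_mL=100.0)
        plain = detect_breaths(t_reg, min_tidal_volume_mL=100.0)
        assert len(merged) == len(plain)
        # volume conservation: merged spans still cover all expired volume
        total = sum(np.trapezoid(np.clip(-flow[a:c], 0, None), dx=1 / FS)
                    for a, _, c in merged)
        covered = np.trapezoid(
            np.clip(-flow[merged[0][0]:merged[-1][2]], 0, None), dx=1 / FS)
        assert total == pytest.approx(covered, rel=1e-3)

    def test_no_zero_crossings_raises(self):
        n = 100
        tr = SignalTrace(sample_rate=FS, time=np.arange(n) / FS,
                         flow=np.full(n, 100.0), fo2=np.full(n, 0.21),
                         fco2=np.zeros(n))
        with pytest.raises(ValueError, match="no breaths"):
            detect_breaths(tr, min_tidal_volume_mL=25.0)


class TestBreathQuantities:
    def _rect_breath(self, f_exp=1.0, fn2_val=0.5):
        # 1 s inspiration then 1 s constant expiratory flow of 500 mL/s
        n = int(2 * FS)
        flow = np.concatenate([np.full(n // 2, 500.0), np.full(n // 2, -500.0)])
        tr = SignalTrace(sample_rate=FS, time=np.arange(n) / FS, flow=flow,
                         fo2=np.full(n, 0.2), fco2=np.zeros(n))
        tr.fn2 = np.full(n, fn2_val)
        prof = default_profile(2)
        return AlignedTrace(trace=tr, fn2_raw=tr.fn2, applied_settings=prof,
                            btps_factors=(1.0, f_exp))

    def test_constant_flow_closed_form(self):
        from n2mbw.breaths import breath_quantities
        al = self._rect_breath()
        spans = detect_breaths(al, min_tidal_volume_mL=25.0)
        rec = breath_quantities(al, spans[0], 0)
        assert rec.vt_exp_mL == pytest.approx(500.0, rel=2e-2)
        assert rec.exp_n2_volume_mL == pytest.approx(250.0, rel=2e-2)
        assert rec.et_n2 == pytest.approx(0.5)

    def test_expiratory_btps_scaling_is_linear(self):
        from n2mbw.breaths import breath_quantities
        al = self._rect_breath(f_exp=1.1)
        spans = detect_breaths(al, min_tidal_volume_mL=25.0)
        rec = breath_quantities(al, spans[0], 0)
        assert rec.vt_exp_mL == pytest.approx(550.0, rel=2e-2)

    def test_simulated_volumes_conserved_across_breaths(self, one_comp_full):
        trace, _, profile = one_comp_full
        aligned = preprocess(trace, profile)
        breaths = segment(aligned, profile)
        f_exp = aligned.btps_factors[1]
        total = sum(b.vt_exp_mL for b in breaths)
        whole = np.trapezoid(
            np.clip(-trace.flow[breaths[0].insp_start:breaths[-1].exp_end],
                    0, None), dx=trace.dt) * f_exp
        assert total == pytest.approx(whole, rel=1e-3)


class TestReinspiredN2:
    def test_disabled_is_zero(self, one_comp_full):
        trace, _, profile = one_comp_full
        aligned = preprocess(trace, profile)
        breaths = segment(aligned, profile)
        off = profile.replace(reinspired_n2_correction=False)
        assert reinspired_n2(aligned, breaths[6], off, 0.2) == 0.0

    def test_pure_o2_inspiration_reduces_to_storage_term(self):
        n = int(2 * FS)
        flow = np.concatenate([np.full(n // 2, 400.0), np.full(n // 2, -400.0)])
        tr = SignalTrace(sample_rate=FS, time=np.arange(n) / FS, flow=flow,
                         fo2=np.ones(n), fco2=np.zeros(n))
        tr.fn2 = np.zeros(n)
        prof = default_profile(2)  # ds_post 9.5
        al = AlignedTrace(trace=tr, fn2_raw=tr.fn2, applied_settings=prof,
                          btps_factors=(1.0, 1.0))
        from n2mbw.breaths import breath_quantities
        rec = breath_quantities(al, detect_breaths(al, 25.0)[0], 0)
        assert reinspired_n2(al, rec, prof, prev_et_n2=0.2) == \
            pytest.approx(1.9, abs=1e-9)

    def test_correction_lowers_net_tracer_every_washout_breath(self, one_comp_full):
        trace, _, profile = one_comp_full
        aligned = preprocess(trace, profile)
        breaths = segment(aligned, profile)
        washout = [b for b in breaths if b.insp_o2 > 0.6]
        assert all(b.reinsp_n2_volume_mL > 0 for b in washout)


def test_et_n2_strictly_decreasing_during_washout(one_comp_full):
    trace, _, profile = one_comp_full
    aligned = preprocess(trace, profile)
    breaths = segment(aligned, profile)
    ets = [b.et_n2 for b in breaths if b.insp_o2 > 0.6]
    assert all(a > b for a, b in zip(ets, ets[1:]))
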