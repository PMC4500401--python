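import numpy as np
import pytest

from n2mbw.domain import BreathRecord, SIIIRecord, default_profile
from n2mbw.outcomes import (analyze_trace, compute_frc, compute_lci,
                            find_washout_window, phase3_slope, scond_sacin)
from n2mbw.simulate import analytic_breath_count


def _breath(i, et, insp_o2=1.0, vt_exp=300.0, exp_n2=50.0, reinsp=0.0):
    b = BreathRecord(index=i, insp_start=0, insp_end=1, exp_end=2)
    b.et_n2, b.insp_o2, b.vt_exp_mL = et, insp_o2, vt_exp
    b.exp_n2_volume_mL, b.reinsp_n2_volume_mL = exp_n2, reinsp
    return b


def _series(c0=0.78, ratio=0.8, n=40, prephase=2):
    breaths = [_breath(i, c0, insp_o2=0.21) for i in range(prephase)]
    for k in range(n):
        breaths.append(_breath(prephase + k, c0 * ratio ** (k + 1)))
    return breaths


class TestFindWashoutWindow:
    def test_geometric_series_matches_analytic_count(self):
        breaths = _series(ratio=0.8)
        start, end, c0 = find_washout_window(breaths, 1 / 40, 3)
        assert c0 == pytest.approx(0.78)
        n_washout = end - start + 1
        assert n_washout == analytic_breath_count(1000.0, 250.0, 1 / 40) == 17

    def test_run_restarts_after_recrossing(self):
        c0, thr = 0.78, 0.78 / 40
        ets = [thr * f for f in
               (2.0, 1.5, 0.9, 0.95, 1.1, 0.8, 0.7, 0.6, 0.5, 0.4)]
        breaths = [_breath(0, c0, insp_o2=0.21)]
        breaths += [_breath(i + 1, et) for i, et in enumerate(ets)]
        start, end, _ = find_washout_window(breaths, 1 / 40, 3)
        # the dip at breaths 3-4 recrosses; the qualifying run starts at the
        # 6th washout breath (et 0.8*thr)
        assert end == 6

    def test_end_fraction_one_ends_at_first_breath(self):
        breaths = _series()
        start, end, _ = find_washout_window(breaths, 1.0, 1)
        assert end == start

    def test_incomplete_washout_raises(self):
        breaths = _series(n=3)
        with pytest.raises(ValueError, match="incomplete"):
            find_washout_window(breaths, 1 / 4000, 3)

    def test_no_prephase_raises_without_c0(self):
        breaths = [_breath(i, 0.5) for i in range(5)]
        with pytest.raises(ValueError, match="pre-phase"):
            find_washout_window(breaths, 1 / 40, 3)


class TestComputeFrc:
    def test_affine_in_ds_pre(self, one_comp_full):
        trace, gt, profile = one_comp_full
        out_a = analyze_trace(trace, profile)
        out_b = analyze_trace(trace, profile.replace(ds_pre_mL=19.0))
        assert out_b.frc_mL - out_a.frc_mL == pytest.approx(5.0, abs=1e-9)

    def test_degenerate_concentrations_raise(self):
        breaths = [_breath(0, 0.5, exp_n2=10.0)]
        with pytest.raises(ValueError):
            compute_frc(breaths, 0.5, default_profile(2))


class TestComputeLci:
    def test_worked_example(self):
        prof = default_profile(2).replace(ds_pre_mL=40.5, ds_post_mL=9.5)
        breaths = [_breath(i, 0.1, vt_exp=300.0) for i in range(17)]
        cev, lci = compute_lci(breaths, 1000.0, prof)
        assert cev == pytest.approx(4250.0)
        assert lci == pytest.approx(4.25)

    def test_uniform_volume_scaling_invariance(self):
        prof = default_profile(2)
        big = prof.replace(ds_pre_mL=48.0, ds_post_mL=19.0)
        b1 = [_breath(i, 0.1, vt_exp=300.0) for i in range(10)]
        b2 = [_breath(i, 0.1, vt_exp=600.0) for i in range(10)]
        _, lci1 = compute_lci(b1, 1000.0, prof)
        _, lci2 = compute_lci(b2, 2000.0, big)
        assert lci1 == pytest.approx(lci2)

    def test_nonpositive_frc_raises(self):
        with pytest.raises(ValueError):
            compute_lci([_breath(0, 0.1)], 0.0, default_profile(2))

    def test_sub_deadspace_breath_clamped_with_warning(self):
        prof = default_profile(2)
        breaths = [_breath(0, 0.1, vt_exp=10.0)]
        with pytest.warns(UserWarning):
            cev, _ = compute_lci(breaths, 1000.0, prof)
        assert cev == 0.0


class TestPhase3Slope:
    def test_exactly_linear_expirogram(self):
        v = np.linspace(0.0, 500.0, 200)
        fn2 = 0.05 + 1e-4 * v
        siii, sniii, ok = phase3_slope((v, fn2), (0.65, 0.95), 500.0)
        assert ok
        assert siii == pytest.approx(0.1, rel=1e-6)
        assert sniii == pytest.approx(0.1 / 0.09, rel=1e-3)

    def test_flat_plateau_zero_slope(self):
        v = np.linspace(0.0, 500.0, 200)
        siii, _, ok = phase3_slope((v, np.full(200, 0.05)), (0.65, 0.95))
        assert ok and siii == pytest.approx(0.0, abs=1e-12)

    def test_wider_window_catches_phase_ii(self):
        # steep phase II ending near 55% of expired volume
        v = np.linspace(0.0, 400.0, 400)
        from scipy.special import expit
        fn2 = 0.06 * expit((v - 0.45 * 400) / 15.0) + 1e-5 * v
        s_wide, _, _ = phase3_slope((v, fn2), (0.50, 0.80), 400.0)
        s_std, _, _ = phase3_slope((v, fn2), (0.65, 0.95), 400.0)
        assert s_wide > s_std

    def test_too_few_samples_flagged(self):
        v = np.linspace(0, 500, 6)
        _, _, ok = phase3_slope((v, np.full(6, 0.05)), (0.90, 0.95), 500.0)
        assert not ok


class TestScondSacin:
    def _records(self, sniii_fn, tos):
        return [SIIIRecord(breath_index=i, siii=np.nan, sniii=sniii_fn(t),
                           to=t, vt_mL=500.0) for i, t in enumerate(tos)]

    def test_exact_linear_recovery(self):
        tos = np.linspace(0.3, 7.0, 25)
        recs = self._records(lambda t: 0.02 + 0.03 * t, tos)
        scond, sacin, scond_vt, sacin_vt = scond_sacin(recs)
        assert scond == pytest.approx(0.03, rel=1e-9)
        assert sacin == pytest.approx(0.02, rel=1e-6)
        # VT correction scales both by vt in litres (0.5 L)
        assert scond_vt == pytest.approx(0.015, rel=1e-9)

    def test_constant_sniii(self):
        recs = self._records(lambda t: 0.07, np.linspace(0.3, 7.0, 20))
        scond, sacin, _, _ = scond_sacin(recs)
        assert scond == pytest.approx(0.0, abs=1e-12)
        assert sacin == pytest.approx(0.07)

    def test_too_few_in_turnover_range(self):
        recs = self._records(lambda t: 0.05, [0.2, 0.5, 7.5, 8.0])
        assert scond_sacin(recs) == (None, None, None, None)

    def test_positive_scond_on_skewed_two_compartment(self, two_comp_full):
        trace, _, profile = two_comp_full
        out = analyze_trace(trace, profile)
        assert out.scond is not None and out.scond > 0
        assert all(r.siii > 0 for r in out.siii_records if r.ok)


def test_outcomeset_lci_identity(one_comp_full):
    trace, _, profile = one_comp_full
    out = analyze_trace(trace, profile)
    assert out.lci == pytest.approx(out.cev_mL / out.frc_mL, abs=1e-12)
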