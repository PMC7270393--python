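import numpy as np
import pytest

from lungkin.core import TimeActivityCurve, build_frame_schedule
from oracles import analytic_tissue as _analytic_tissue, ode_tissue as _ode_tissue

from lungkin.kinetics import (
    KineticParameters,
    KineticResults,
    OneTissueModel,
    TwoTissueModel,
    compare_models,
    exp_conv,
    frame_average,
    solve_model_tac,
)


class TestForwardSolver:
    def test_zero_k1_leaves_scaled_blood(self, input_fn, schedule38):
        p = KineticParameters(k1=0.0, k2=0.01, vb=0.21, delta_s=3.0)
        model = solve_model_tac(p, input_fn, schedule38)
        wb = input_fn.whole_blood_at(input_fn.t_s, 3.0)
        expected = 0.21 * frame_average(wb, input_fn.t_s, schedule38)
        assert np.allclose(model, expected, atol=1e-12)

    def test_equilibrium_with_constant_input(self, flat_input):
        sched = build_frame_schedule("40x600")
        p = KineticParameters(k1=0.04, k2=0.02, vb=0.0)
        model = solve_model_tac(p, flat_input, sched)
        assert model[-1] == pytest.approx(10.0 * 0.04 / 0.02, rel=5e-3)

    def test_two_tissue_with_zero_k3_reduces_to_one_tissue(self, input_fn, schedule38):
        p1 = KineticParameters(k1=0.03, k2=0.012, vb=0.1, delta_s=2.0)
        p2 = KineticParameters(k1=0.03, k2=0.012, k3=0.0, k4=0.01, vb=0.1, delta_s=2.0)
        m1 = solve_model_tac(p1, input_fn, schedule38)
        m2 = solve_model_tac(p2, input_fn, schedule38)
        assert np.max(np.abs(m1 - m2)) < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_stiff_ode_integration(self, input_fn, schedule38, seed):
        rng = np.random.default_rng(seed)
        if seed % 2:
            p = KineticParameters(
                k1=rng.uniform(0.02, 0.05), k2=rng.uniform(0.03, 0.2),
                k3=rng.uniform(0.005, 0.05), k4=rng.uniform(0.005, 0.05),
                delta_s=rng.uniform(0, 10),
            )
        else:
            p = KineticParameters(
                k1=rng.uniform(0.02, 0.05), k2=rng.uniform(0.01, 0.02),
                delta_s=rng.uniform(0, 10),
            )
        # evaluate at frame boundaries (input-grid points), where the
        # analytic recursion needs no interpolation of the fine curve
        t_eval = schedule38.frame_end_s / 60.0
        ana = _analytic_tissue(p, input_fn, t_eval)
        num = _ode_tissue(p, input_fn, t_eval)
        assert np.max(np.abs(ana - num)) / np.max(num) < 1e-6

    def test_increasing_vb_raises_early_frames(self, input_fn, schedule38):
        base = dict(k1=0.03, k2=0.012, delta_s=0.0)
        lo = solve_model_tac(KineticParameters(vb=0.05, **base), input_fn, schedule38)
        hi = solve_model_tac(KineticParameters(vb=0.25, **base), input_fn, schedule38)
        assert np.all(hi[:9] > lo[:9])  # bolus-dominated first frames

    def test_additive_convention_variant(self, input_fn, schedule38):
        p = KineticParameters(k1=0.03, k2=0.012, vb=0.2)
        vol = solve_model_tac(p, input_fn, schedule38, convention="volume")
        add = solve_model_tac(p, input_fn, schedule38, convention="additive")
        tis = solve_model_tac(KineticParameters(k1=0.03, k2=0.012), input_fn, schedule38)
        assert np.allclose(add, vol + 0.2 * tis, atol=1e-10)

    def test_insufficient_input_coverage_rejected(self, schedule38):
        from lungkin.input_function import InputFunction

        t = np.arange(0.0, 1000.0)
        short = InputFunction(t, np.ones(t.size), np.ones(t.size), 1.0)
        with pytest.raises(ValueError):
            solve_model_tac(KineticParameters(k1=0.03, k2=0.01), short, schedule38)


class TestOneTissueFit:
    def test_noiseless_recovery_within_one_percent(self, lung_tac, lung_truth, input_fn):
        res = OneTissueModel(lung_tac, input_fn).fit()
        for name in ("k1", "k2", "vb", "delta_s"):
            est, tru = getattr(res.params, name), getattr(lung_truth, name)
            assert abs(est - tru) / tru < 0.01, name
        assert res.vt == pytest.approx(2.5, rel=0.01)
        assert res.converged

    def test_vt_in_observed_range_for_high_binding_subject(self, input_fn, schedule38):
        from lungkin.simulate import simulate_lung_tac

        p = KineticParameters(k1=0.038, k2=0.010, vb=0.2)
        tac = simulate_lung_tac(p, input_fn, schedule38)
        res = OneTissueModel(tac, input_fn).fit()
        assert res.vt == pytest.approx(3.8, rel=0.01)
        assert 1.8 <= res.vt <= 3.8 + 1e-6

    def test_vt_recomputable_from_parameters(self, lung_tac, input_fn):
        res = OneTissueModel(lung_tac, input_fn).fit()
        assert res.vt == res.params.k1 / res.params.k2

    def test_fixed_vb_and_delta(self, lung_tac, lung_truth, input_fn):
        res = OneTissueModel(
            lung_tac, input_fn, fit_vb=False, fit_delta=False,
            fixed={"vb": lung_truth.vb, "delta_s": lung_truth.delta_s},
        ).fit()
        assert res.p == 2
        assert res.params.vb == lung_truth.vb
        assert res.params.k1 == pytest.approx(lung_truth.k1, rel=1e-6)

    def test_weight_options(self, lung_tac, input_fn):
        res = OneTissueModel(lung_tac, input_fn, weights="duration-decay").fit()
        assert res.vt == pytest.approx(2.5, rel=0.01)
        with pytest.raises(ValueError):
            OneTissueModel(lung_tac, input_fn, weights=np.ones(5))

    def test_summary_renders(self, lung_tac, input_fn):
        text = OneTissueModel(lung_tac, input_fn).fit().summary()
        assert "V_T" in text and "k2" in text


class TestTwoTissueFit:
    def test_noiseless_two_tissue_recovery(self, input_fn, schedule38):
        from lungkin.simulate import simulate_lung_tac

        p = KineticParameters(k1=0.03, k2=0.06, k3=0.02, k4=0.01, vb=0.1)
        tac = simulate_lung_tac(p, input_fn, schedule38)
        res = TwoTissueModel(tac, input_fn).fit()
        assert res.vt == pytest.approx(1.5, rel=0.01)

    def test_vt_formula_limit_k3_to_zero(self):
        p = KineticParameters(k1=0.03, k2=0.012, k3=0.0, k4=0.01)
        assert p.vt == pytest.approx(0.03 / 0.012)

    def test_irreversible_k4_zero_flags_undefined_vt(self):
        p = KineticParameters(k1=0.03, k2=0.012, k3=0.02, k4=0.0)
        assert np.isnan(p.vt)

    def test_one_tissue_data_gives_vanishing_or_unidentifiable_k3(
        self, lung_tac, input_fn
    ):
        res = TwoTissueModel(lung_tac, input_fn).fit()
        assert res.params.k3 < 1e-4 or "k3" in res.non_identifiable


class TestCompareModels:
    def _toy(self, model_id, rss, p, n=10):
        sched = build_frame_schedule(f"{n}x60")
        tac = TimeActivityCurve(sched, np.linspace(1, 2, n))
        return KineticResults(
            model_id=model_id, params=KineticParameters(k1=0.03, k2=0.01),
            vt=3.0, rss=rss, n=n, p=p, tac=tac,
        )

    def test_hand_computed_f_statistic(self):
        cmp = compare_models(self._toy("1TCM", 2.0, 4), self._toy("2TCM", 1.0, 6))
        assert cmp.f_stat == pytest.approx(2.0)
        assert 0 < cmp.f_pvalue < 1

    def test_identical_rss_prefers_simpler(self):
        cmp = compare_models(self._toy("1TCM", 1.0, 4), self._toy("2TCM", 1.0, 6))
        assert cmp.f_stat == 0.0
        assert cmp.preferred == "1TCM"

    def test_zero_rss_larger_model_warns_and_uses_aic(self):
        with pytest.warns(UserWarning):
            cmp = compare_models(self._toy("1TCM", 1.0, 4), self._toy("2TCM", 0.0, 6))
        assert "F undefined" in cmp.note

    def test_numerical_floor_tie_goes_to_simpler_model(self):
        cmp = compare_models(self._toy("1TCM", 1e-25, 4), self._toy("2TCM", 1e-27, 6))
        assert cmp.tie
        assert cmp.preferred == "1TCM"

    def test_real_improvement_prefers_larger_model(self):
        cmp = compare_models(self._toy("1TCM", 10.0, 4), self._toy("2TCM", 0.5, 6))
        assert cmp.preferred == "2TCM"

    def test_aic_formula(self):
        res = self._toy("1TCM", 2.0, 4, n=10)
        assert res.aic == pytest.approx(10 * np.log(2.0 / 10) + 8)
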