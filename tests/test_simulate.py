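import numpy as np
import pytest

from lungkin.core import extract_roi_tac
from lungkin.input_function import RichardsParentModel
from lungkin.kinetics import (
    C11_LAMBDA_PER_MIN,
    KineticParameters,
    frame_average,
    solve_model_tac,
)
from lungkin.simulate import (
    ArterialInputParams,
    CohortSpec,
    PhantomSpec,
    add_tac_noise,
    simulate_arterial_input,
    simulate_dynamic_phantom,
    simulate_lung_tac,
    simulate_parent_fraction,
    simulate_test_retest_cohort,
)


class TestArterialInput:
    def test_zero_at_injection(self, input_fn):
        assert input_fn.whole_blood[0] == 0.0
        assert input_fn.plasma[0] == 0.0

    def test_plasma_to_blood_ratio_exact_on_grid(self, input_fn):
        nz = input_fn.whole_blood > 0
        assert np.allclose(input_fn.plasma[nz] / input_fn.whole_blood[nz], 1.71,
                           rtol=0, atol=1e-12)

    def test_rapid_early_decline(self, input_fn):
        """Plasma activity falls several-fold between the bolus peak and
        10 min; the later decline is an order of magnitude slower per
        unit time."""
        peak = input_fn.plasma.max()
        t_peak_min = np.argmax(input_fn.plasma) / 60.0
        at10 = input_fn.plasma[600]
        at90 = input_fn.plasma[5400]
        assert peak / at10 > 3
        rate_early = np.log(peak / at10) / (10.0 - t_peak_min)
        rate_late = np.log(at10 / at90) / 80.0
        assert rate_early > 5 * rate_late

    def test_zero_washout_plateaus_after_peak(self):
        p = ArterialInputParams(washout_rates=(0.0, 0.0, 0.0))
        t = np.arange(0.0, 3601.0)
        inp = simulate_arterial_input(p, t)
        assert np.all(np.diff(inp.whole_blood) >= -1e-12)
        assert inp.whole_blood[-1] == pytest.approx(p.amplitude, rel=1e-6)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            ArterialInputParams(amplitude=-1.0)
        with pytest.raises(ValueError):
            ArterialInputParams(washout_rates=(-0.1, 0.2, 0.3))


class TestParentFractionSimulation:
    def test_unity_at_injection(self):
        assert simulate_parent_fraction(RichardsParentModel(), [0.0])[0] == pytest.approx(1.0)

    def test_asymptote_one_gives_constant_curve(self):
        m = RichardsParentModel(f_inf=1.0)
        f = simulate_parent_fraction(m, np.linspace(0, 90, 50))
        assert np.allclose(f, 1.0)

    def test_values_within_unit_interval(self):
        f = simulate_parent_fraction(RichardsParentModel(), np.linspace(0, 500, 100))
        assert np.all((f >= 0) & (f <= 1))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_parent_fraction(RichardsParentModel(), [-1.0])


class TestSimulateLungTac:
    def test_no_uptake_leaves_pure_blood_signal(self, input_fn, schedule38):
        p = KineticParameters(k1=0.0, k2=0.01, vb=0.13, delta_s=0.0)
        tac = simulate_lung_tac(p, input_fn, schedule38)
        wb_frames = frame_average(input_fn.whole_blood, input_fn.t_s, schedule38)
        assert np.allclose(tac.values, 0.13 * wb_frames, atol=1e-12)

    def test_equilibrium_ratio_tends_to_vt(self, flat_input):
        """With a flat input tail and no blood signal, lung/plasma -> K1/k2."""
        from lungkin.core import build_frame_schedule

        sched = build_frame_schedule("40x600")  # 400 min
        p = KineticParameters(k1=0.03, k2=0.012, vb=0.0)
        tac = simulate_lung_tac(p, flat_input, sched)
        ratio = tac.values[-1] / flat_input.plasma[-1]
        assert ratio == pytest.approx(2.5, rel=0.01)

    def test_blood_corrected_shape_rises_then_declines_slowly(self, input_fn, schedule38):
        p = KineticParameters(k1=0.03, k2=0.015, vb=0.0)
        tac = simulate_lung_tac(p, input_fn, schedule38)
        peak_idx = np.argmax(tac.values)
        peak_min = schedule38.mid_times_min[peak_idx]
        assert 15 < peak_min < 90          # rises over tens of minutes
        assert tac.values[-1] > 0.7 * tac.values[peak_idx]  # declines slowly


class TestAddTacNoise:
    def test_zero_scale_is_identity(self, lung_tac):
        out = add_tac_noise(lung_tac, 0.0, seed=1)
        assert np.array_equal(out.values, lung_tac.values)

    def test_seed_reproducibility(self, lung_tac):
        a = add_tac_noise(lung_tac, 0.1, seed=42)
        b = add_tac_noise(lung_tac, 0.1, seed=42)
        assert np.array_equal(a.values, b.values)
        c = add_tac_noise(lung_tac, 0.1, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_empirical_variance_matches_model(self, lung_tac):
        """Monte-Carlo check of the variance formula
        var = scale^2 * value * exp(lambda t) / duration, per frame."""
        scale = 0.08
        reps = np.stack(
            [add_tac_noise(lung_tac, scale, seed=s).values for s in range(4000)]
        )
        emp = reps.var(axis=0, ddof=1)
        t = lung_tac.schedule.mid_times_min
        dur = lung_tac.schedule.frame_duration / 60.0
        expected = scale**2 * lung_tac.values * np.exp(C11_LAMBDA_PER_MIN * t) / dur
        assert np.all(np.abs(emp - expected) / expected < 0.10)


class TestTestRetestCohort:
    def test_bookkeeping_n6_gives_12_sessions(self):
        cohort = simulate_test_retest_cohort(CohortSpec(n_subjects=6, seed=0))
        assert cohort.n_sessions == 12
        assert all(len(s.sessions) == 2 for s in cohort.subjects)

    def test_zero_cov_zero_noise_gives_identical_sessions(self, noiseless_cohort):
        for subj in noiseless_cohort.subjects:
            t0, t1 = (s.truth.params for s in subj.sessions)
            assert t0 == t1
            assert np.array_equal(subj.sessions[0].tac.values, subj.sessions[1].tac.values)

    def test_same_seed_bit_identical(self):
        a = simulate_test_retest_cohort(CohortSpec(n_subjects=2, seed=11))
        b = simulate_test_retest_cohort(CohortSpec(n_subjects=2, seed=11))
        for sa, sb in zip(a.subjects, b.subjects):
            for xa, xb in zip(sa.sessions, sb.sessions):
                assert np.array_equal(xa.tac.values, xb.tac.values)
                assert np.array_equal(xa.blood_samples.plasma, xb.blood_samples.plasma)
                assert xa.truth.params == xb.truth.params

    def test_truths_inside_configured_ranges(self):
        spec = CohortSpec(n_subjects=5, seed=3, param_cov=0.0)
        cohort = simulate_test_retest_cohort(spec)
        for subj in cohort.subjects:
            p = subj.sessions[0].truth.params
            assert spec.k1_range[0] <= p.k1 <= spec.k1_range[1]
            assert spec.k2_range[0] <= p.k2 <= spec.k2_range[1]
            assert spec.vb_range[0] <= p.vb <= spec.vb_range[1]

    def test_blood_table_at_nominal_times_with_exact_ratio(self):
        cohort = simulate_test_retest_cohort(CohortSpec(n_subjects=1, seed=5))
        s = cohort.subjects[0].sessions[0]
        assert np.allclose(s.blood_samples.time_min,
                           [2.5, 5, 7.5, 10, 15, 20, 30, 45, 90])
        assert np.allclose(s.blood_samples.plasma,
                           s.truth.ratio * s.blood_samples.whole_blood, rtol=1e-12)


class TestDynamicPhantom:
    def test_aorta_roi_mean_is_whole_blood_curve(self, phantom):
        img, mask, truth = phantom
        tac = extract_roi_tac(img, mask, "aorta")
        inp = truth["input_fn"]
        wb_frames = frame_average(inp.whole_blood, inp.t_s, truth["schedule"])
        assert np.allclose(tac.values, wb_frames, atol=1e-9)

    def test_region_masks_are_disjoint_and_truth_confined_to_lung(self, phantom):
        img, mask, truth = phantom
        assert set(np.unique(mask.data)) <= {0, 1, 2, 3, 4}
        lung = mask.data == 1
        assert np.all(np.isfinite(truth["vt"][lung]))
        assert np.all(np.isnan(truth["vt"][~lung]))

    def test_gradients_run_the_documented_directions(self, phantom):
        img, mask, truth = phantom
        lung = mask.data == 1
        zz = np.argwhere(lung)[:, 2]
        vt = truth["vt"][lung]
        # apex (high z) low, base (low z) high
        assert np.corrcoef(zz, vt)[0, 1] < -0.8

    def test_zero_gradient_amplitude_collapses_lung_to_one_tac(self):
        img, mask, truth = simulate_dynamic_phantom(PhantomSpec(gradient_amplitude=0.0))
        lung_tacs = img.data[mask.data == 1]
        assert np.allclose(lung_tacs, lung_tacs[0], atol=1e-9)
        assert np.nanstd(truth["vt"]) == pytest.approx(0.0, abs=1e-12)

    def test_lung_voxel_matches_forward_model(self, phantom):
        """One spot-check voxel equals the forward compartment solution for
        its stored truth parameters."""
        img, mask, truth = phantom
        x, y, z = np.argwhere(mask.data == 1)[100]
        p = KineticParameters(
            k1=truth["k1"][x, y, z], k2=truth["k2"][x, y, z], vb=truth["vb"][x, y, z]
        )
        model = solve_model_tac(p, truth["input_fn"], truth["schedule"])
        assert np.allclose(img.data[x, y, z], model, atol=1e-9)
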