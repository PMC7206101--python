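import numpy as np
import pytest

from vfa import spot_map as sm
from vfa import synthetic_data as syn


class TestDoseResponse:
    def test_limits_at_zero_concentration(self):
        hook = syn.DoseResponseModel("Ab", "sandwich_hook", amplitude=1.0)
        comp = syn.DoseResponseModel("Ag", "competitive_decreasing", amplitude=0.8)
        assert syn.condition_response(hook, 0.0) == 0.0
        assert syn.condition_response(comp, 0.0) == pytest.approx(0.8)
        const = syn.DoseResponseModel("S", "constant_control", amplitude=0.9)
        assert syn.condition_response(const, 123.0) == pytest.approx(0.9)
        bg = syn.DoseResponseModel("B", "background")
        assert syn.condition_response(bg, 5.0) == 0.0

    def test_hook_suppresses_high_concentration(self):
        m = syn.DoseResponseModel("Ab", "sandwich_hook", k_a=1.0, k_h=100.0)
        grid = np.logspace(-2, 4, 500)
        resp = syn.condition_response(m, grid)
        assert resp[-1] < resp.max()

    def test_hook_argmax_matches_closed_form(self):
        # critical point of c/((K_a+c)(1+c/K_h)) is sqrt(K_a * K_h)
        m = syn.DoseResponseModel("Ab", "sandwich_hook", k_a=2.0, k_h=150.0)
        grid = np.logspace(-2, 4, 20001)
        resp = syn.condition_response(m, grid)
        c_star = grid[int(np.argmax(resp))]
        assert c_star == pytest.approx(np.sqrt(2.0 * 150.0), rel=1e-3)

    def test_competitive_strictly_decreasing(self):
        m = syn.DoseResponseModel("Ag", "competitive_decreasing")
        grid = np.linspace(0, 1000, 200)
        resp = syn.condition_response(m, grid)
        assert np.all(np.diff(resp) < 0)

    def test_hook_unimodal_on_log_grid(self):
        m = syn.DoseResponseModel("Ab", "sandwich_hook")
        grid = np.logspace(-2, 4, 300)
        diffs = np.diff(syn.condition_response(m, grid))
        signs = np.sign(diffs[diffs != 0])
        assert int((np.diff(signs) != 0).sum()) == 1

    def test_negative_concentration_rejected(self):
        m = syn.DoseResponseModel("Ab", "sandwich_hook")
        with pytest.raises(ValueError):
            syn.condition_response(m, -1.0)

    def test_mixture_is_weighted_sum(self):
        models = syn.default_dose_models()
        c = 3.7
        expected = 0.5 * syn.condition_response(models["Ab"], c) + \
            0.5 * syn.condition_response(models["Ag"], c)
        assert syn.condition_response(models["Mix1"], c) == pytest.approx(expected)


class TestMembraneSimulation:
    def test_zero_noise_like_spots_identical(self, default_map, dose_models):
        flat = syn.BatchEffectModel(radial_alpha=0.0)
        clean = syn.NoiseModel(cv=0.0, background_sd=0.0)
        t = syn.simulate_membrane_signals(
            default_map, 2.0, 1, 1, dose_models, flat, clean, seed=0
        )
        net = t.net()
        for cond in default_map.condition_names:
            vals = net.loc[[tuple(rc) for rc in default_map.spots_of(cond)]]
            expected = syn.condition_response(dose_models[cond], 2.0)
            assert np.allclose(vals, expected)

    def test_radial_bias_attenuates_corner_spots(self, default_map, dose_models):
        biased = syn.BatchEffectModel(radial_alpha=0.5)
        clean = syn.NoiseModel(cv=0.0, background_sd=0.0)
        t = syn.simulate_membrane_signals(
            default_map, 2.0, 1, 1, dose_models, biased, clean, seed=0
        )
        net = t.net()
        for cond in default_map.condition_names:
            spots = default_map.spots_of(cond)
            radii = {rc: default_map.radius(*rc) for rc in spots}
            inner = min(radii, key=radii.get)
            outer = max(radii, key=radii.get)
            if radii[outer] > radii[inner]:
                assert net.loc[outer] < net.loc[inner]

    def test_rid_gain_ratio_between_batches(self, default_map, dose_models):
        batch = syn.BatchEffectModel(
            rid_gains={1: 1.0, 2: 1.3}, fid_gains={1: 1.0}, radial_alpha=0.0
        )
        clean = syn.NoiseModel(cv=0.0, background_sd=0.0)
        t1 = syn.simulate_membrane_signals(
            default_map, 2.0, 1, 1, dose_models, batch, clean, seed=0
        )
        t2 = syn.simulate_membrane_signals(
            default_map, 2.0, 2, 1, dose_models, batch, clean, seed=0
        )
        ratio = t2.net() / t1.net()
        assert np.allclose(ratio, 1.3)

    def test_missing_dose_model_raises(self, default_map, dose_models):
        incomplete = {k: v for k, v in dose_models.items() if k != "Ab"}
        with pytest.raises(KeyError, match="Ab"):
            syn.simulate_membrane_signals(
                default_map, 2.0, 1, 1, incomplete, seed=0
            )

    def test_empirical_cv_matches_configuration(self, dose_models):
        # 1000 replicate membranes of a tiny grid: per-spot CV of the
        # background-subtracted signal must recover the configured 10%
        conds = [sm.SpottingCondition("Ab", replicates_requested=4)]
        tiny = sm.generate_spot_map(2, 2, 1.3, conds, seed=0)
        noise = syn.NoiseModel(cv=0.10)
        rng = np.random.default_rng(11)
        nets = np.array([
            syn.simulate_membrane_signals(
                tiny, 2.0, 1, 1, dose_models, syn.BatchEffectModel(),
                noise, seed=rng,
            ).net().to_numpy()
            for _ in range(1000)
        ])
        cv = nets.std(axis=0, ddof=1) / nets.mean(axis=0)
        assert np.all(np.abs(cv - 0.10) / 0.10 < 0.10)


class TestCohort:
    def test_study_scale_counts_and_tags(self, default_map):
        cohort = syn.simulate_cohort(syn.CohortDesign(), default_map, seed=0)
        hs = [t for t in cohort.tests if t.truth_mg_l <= 10]
        acute = [t for t in cohort.tests if t.truth_mg_l > 10]
        assert len(hs) == 85 * 3
        assert len(acute) == 10 * 3  # outlier + 3 spiked samples x 3 levels
        assert {t.rid for t in cohort.tests} == {1, 2}
        assert {t.fid for t in cohort.tests} == {1, 2, 3}
        spikes = {t.truth_mg_l for t in acute}
        assert spikes == {83.6, 200.0, 500.0, 1000.0}

    def test_replicates_share_concentration(self, small_cohort):
        by_sample = {}
        for t in small_cohort.tests:
            by_sample.setdefault(t.sample_id, set()).add(t.truth_mg_l)
        assert all(len(v) == 1 for v in by_sample.values())

    def test_single_test_design(self, default_map):
        design = syn.CohortDesign(
            n_hs_samples=1, replicates=1, acute_concentrations=()
        )
        cohort = syn.simulate_cohort(design, default_map, seed=0)
        assert len(cohort.tests) == 1

    def test_deterministic_under_seed(self, default_map):
        design = syn.CohortDesign(n_hs_samples=3, replicates=2,
                                  acute_concentrations=(200.0,))
        a = syn.simulate_cohort(design, default_map, seed=5).table()
        b = syn.simulate_cohort(design, default_map, seed=5).table()
        assert a.equals(b)

    def test_hs_concentrations_within_range(self, small_cohort):
        lo, hi = small_cohort.design.concentration_range
        for t in small_cohort.tests:
            if t.truth_mg_l <= 10:
                assert lo <= t.truth_mg_l <= hi


class TestRendering:
    def test_flat_render_recovers_net_signal(self, default_map, dose_models):
        t = syn.simulate_membrane_signals(
            default_map, 2.0, 1, 1, dose_models, seed=4
        )
        img = syn.render_membrane_image(t, default_map, syn.ImageParams(), seed=0)
        centers = img.metadata["true_centers"]
        spot_r = img.metadata["spot_radius_px"]
        base = img.metadata["base_level"]
        net = t.net().to_numpy()
        for i, (cy, cx) in enumerate(centers):
            yy, xx = np.mgrid[
                int(cy - spot_r) : int(cy + spot_r) + 1,
                int(cx - spot_r) : int(cx + spot_r) + 1,
            ]
            disk = np.hypot(yy - cy, xx - cx) <= spot_r * 0.8  # interior only
            mean_in = img.pixels[yy[disk], xx[disk]].mean()
            assert mean_in - base == pytest.approx(net[i], rel=0.01)

    def test_rotation_moves_centers_per_metadata(self, default_map, dose_models):
        t = syn.simulate_membrane_signals(
            default_map, 2.0, 1, 1, dose_models, seed=4
        )
        img0 = syn.render_membrane_image(t, default_map, syn.ImageParams(), seed=0)
        img2 = syn.render_membrane_image(
            t, default_map, syn.ImageParams(rotation_deg=2.0), seed=0
        )
        c0 = img0.metadata["true_centers"]
        c2 = img2.metadata["true_centers"]
        center = np.array([(img0.pixels.shape[0] - 1) / 2.0,
                           (img0.pixels.shape[1] - 1) / 2.0])
        th = np.deg2rad(2.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expected = (c0 - center) @ rot.T + center
        assert np.allclose(c2, expected, atol=1e-8)
        assert img2.metadata["true_rotation_deg"] == 2.0

    def test_grid_exceeding_bounds_raises(self, default_map, dose_models):
        t = syn.simulate_membrane_signals(
            default_map, 2.0, 1, 1, dose_models, seed=4
        )
        params = syn.ImageParams(margin_mm=0.1, offset_px=(500.0, 0.0))
        with pytest.raises(ValueError, match="bounds"):
            syn.render_membrane_image(t, default_map, params, seed=0)
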