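import numpy as np
import pytest
from scipy import stats

import catrep as cr
from catrep.rsa import cv_euclidean_distance
from catrep.synth import GeometrySchedule, _ramp


def closed_form_upper_probability(a, v, s, z_rel):
    """Independent oracle: exact absorption probability at the upper boundary
    of a drifted Wiener process on [0, a] started at z = z_rel * a."""
    z = z_rel * a
    if v == 0:
        return z / a
    num = 1.0 - np.exp(-2.0 * v * z / s**2)
    den = 1.0 - np.exp(-2.0 * v * a / s**2)
    return num / den


class TestSimulateDDM:
    def test_zero_drift_symmetric(self):
        sim = cr.simulate_ddm(cr.DDMParams(a=1.0, v=0.0, t=0.2), 20000, seed=0)
        p = (sim["correct"] == True).mean()  # noqa: E712
        se = np.sqrt(0.25 / 20000)
        assert abs(p - 0.5) < 3 * se

    def test_rt_floor_is_nondecision_time(self):
        params = cr.DDMParams(a=1.0, v=2.0, t=0.35)
        sim = cr.simulate_ddm(params, 2000, seed=1)
        assert sim["rt_ms"].min() >= params.t * 1000.0

    @pytest.mark.parametrize("a,v", [(1.0, 2.0), (1.4, 1.0)])
    def test_choice_probability_matches_closed_form(self, a, v):
        params = cr.DDMParams(a=a, v=v, t=0.3)
        sim = cr.simulate_ddm(params, 20000, seed=3)
        responded = sim["correct"].notna()
        p = (sim["correct"] == True).sum() / responded.sum()  # noqa: E712
        p_exact = closed_form_upper_probability(a, v, 1.0, 0.5)
        se = np.sqrt(p_exact * (1 - p_exact) / responded.sum())
        assert abs(p - p_exact) < 3 * se

    def test_determinism(self):
        p = cr.DDMParams(a=1.2, v=1.5, t=0.25)
        a = cr.simulate_ddm(p, 500, seed=9)
        b = cr.simulate_ddm(p, 500, seed=9)
        assert a.equals(b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            cr.DDMParams(a=-1.0, v=1.0, t=0.2)
        with pytest.raises(ValueError):
            cr.DDMParams(a=1.0, v=np.nan, t=0.2)


class TestGenerateBehavior:
    def test_design_counts(self):
        table = cr.generate_behavior(seed=0)
        sup = table[table["task"] == "superordinate"]
        bas = table[table["task"] == "basic"]
        assert len(sup) == 1000 and len(bas) == 1000
        assert (sup["category"] == "vehicle").sum() == 500
        assert (bas["category"] == "bird").sum() == 500
        assert (sup["category"] == "bird").sum() == 250

    def test_determinism(self):
        a = cr.generate_behavior(cr.DesignSpec(n_trials_per_task=100), seed=4)
        b = cr.generate_behavior(cr.DesignSpec(n_trials_per_task=100), seed=4)
        assert a.equals(b)

    def test_invalid_proportions_rejected(self):
        design = cr.DesignSpec(
            proportions={
                "superordinate": {"bird": 0.5, "nonbird_animal": 0.4, "vehicle": 0.4},
                "basic": {"bird": 0.5, "nonbird_animal": 0.25, "vehicle": 0.25},
            }
        )
        with pytest.raises(ValueError, match="sum to 1"):
            cr.generate_behavior(design, seed=0)


class TestGeometrySchedule:
    def test_default_schedule_matches_hypothesis_structure(self):
        sched = GeometrySchedule()
        t = np.array([-100.0, 100.0, 200.0, 300.0, 400.0])
        assert np.allclose(sched.d_bn("superordinate", t), 0.0)
        bn = sched.d_bn("basic", t)
        assert bn[0] == 0 and bn[2] == 0 and 0 < bn[3] < 1 and bn[4] == 1.0
        cv = sched.d_cv(t)
        assert cv[0] == 0 and cv[1] == 0 and cv[2] == 1.0

    def test_declared_distances_are_euclidean(self):
        sched = GeometrySchedule()
        t = np.linspace(-150, 500, 27)
        for task in ("superordinate", "basic"):
            d_bn = sched.pair_distance(task, ("bird", "nonbird_animal"), t)
            d_bv = sched.pair_distance(task, ("bird", "vehicle"), t)
            d_av = sched.pair_distance(task, ("nonbird_animal", "vehicle"), t)
            # symmetry under pair reversal
            assert np.allclose(d_bv, sched.pair_distance(task, ("vehicle", "bird"), t))
            # triangle inequality at every timepoint
            assert np.all(d_bn <= d_bv + d_av + 1e-12)
            assert np.all(d_bv <= d_bn + d_av + 1e-12)
            # declared magnitudes
            assert np.allclose(d_bv, sched.d_cv(t), atol=1e-12)
            assert np.allclose(d_bn, sched.d_bn(task, t), atol=1e-12)

    def test_ramp_breakpoints(self):
        t = np.array([0.0, 250.0, 300.0, 350.0, 500.0])
        assert np.allclose(_ramp(t, 250, 350), [0, 0, 0.5, 1, 1])


class TestGenerateEpochs:
    def test_bookkeeping(self, small_session):
        ep, gt = small_session
        assert ep.n_trials == 240
        assert ep.n_channels == 16 + 2  # scalp + VEOG pair
        assert ep.srate == 256.0
        assert ep.times[0] == -150.0

    def test_ground_truth_distances_match_latent_means(self, small_session):
        _, gt = small_session
        for (task, pair), d2 in gt.channel_sq_distances.items():
            ma = gt.latent_means[(task, pair[0])]
            mb = gt.latent_means[(task, pair[1])]
            recomputed = np.sum((gt.mixing @ (ma - mb)) ** 2, axis=0)
            assert np.allclose(d2, recomputed, atol=1e-9)

    def test_noiseless_cv_distance_equals_channel_separation(self):
        ep, gt = cr.generate_epochs(
            design=cr.DesignSpec(n_trials_per_task=40),
            noise=cr.NoiseSpec(sd_uv=0.0, pink=False),
            n_channels=8,
            seed=5,
        )
        sub = ep.where(task="basic")
        xa = sub.data[(sub.labels["category"] == "bird").to_numpy()][:, :8]
        xb = sub.data[(sub.labels["category"] == "nonbird_animal").to_numpy()][:, :8]
        d = cv_euclidean_distance(xa, xb, n_pseudo=5, n_iterations=2, seed=0)
        expected = gt.channel_sq_distances[("basic", ("bird", "nonbird_animal"))]
        assert np.abs(d - expected).max() < 1e-9

    def test_planted_eye_artifacts_are_rejected(self):
        ep, gt = cr.generate_epochs(
            design=cr.DesignSpec(n_trials_per_task=30),
            n_channels=8,
            n_eye_artifacts=5,
            seed=2,
        )
        kept, mask = cr.reject_eye_epochs(ep, 150.0)
        assert set(gt.artifact_trials) <= set(np.flatnonzero(mask))

    def test_determinism(self):
        kwargs = dict(design=cr.DesignSpec(n_trials_per_task=20), n_channels=6, seed=11)
        a, _ = cr.generate_epochs(**kwargs)
        b, _ = cr.generate_epochs(**kwargs)
        assert np.array_equal(a.data, b.data)

    def test_group_shares_scalp_mixing_but_not_noise(self):
        data = cr.generate_dataset(
            2, seed=3, design=cr.DesignSpec(n_trials_per_task=20), n_channels=8,
            simulate_responses=False,
        )
        (_, gt0), (_, gt1) = data
        assert np.allclose(gt0.mixing, gt1.mixing)
        assert not np.array_equal(data[0][0].data, data[1][0].data)

    def test_explicit_mixing_plants_signal_in_known_subspace(self):
        t, _, _ = cr.generate_templates(4, 16, seed=0)
        ep, gt = cr.generate_epochs(
            design=cr.DesignSpec(n_trials_per_task=20), n_channels=16,
            mixing=t[:2].T, simulate_responses=False, seed=1,
        )
        # mixing columns span exactly the two template topographies
        q, _ = np.linalg.qr(t[:2].T)
        residual = gt.mixing - q @ (q.T @ gt.mixing)
        assert np.linalg.norm(residual) / np.linalg.norm(gt.mixing) < 1e-9


class TestPosteriorSamples:
    def test_identical_truths_give_half_overlap(self):
        params = {("superordinate", "bird"): cr.DDMParams(a=1.4, v=2.0, t=0.3),
                  ("basic", "bird"): cr.DDMParams(a=1.4, v=2.0, t=0.3)}
        post = cr.generate_posterior_samples(params, spread=0.05, n_samples=4000, seed=0)
        p = cr.posterior_overlap_probability(
            post[("superordinate", "bird", "v")], post[("basic", "bird", "v")]
        )
        assert abs(p - 0.5) < 0.03

    def test_separated_truths_fully_separate(self):
        params = {("superordinate", "bird"): cr.DDMParams(a=1.4, v=3.0, t=0.3),
                  ("basic", "bird"): cr.DDMParams(a=1.4, v=1.0, t=0.3)}
        post = cr.generate_posterior_samples(params, spread=0.05, n_samples=2000, seed=1)
        p = cr.posterior_overlap_probability(
            post[("superordinate", "bird", "v")], post[("basic", "bird", "v")]
        )
        assert p > 0.999

    def test_overlap_matches_normal_difference_oracle(self):
        delta, sigma = 0.12, 0.1
        params = {("basic", "bird"): cr.DDMParams(a=1.4, v=2.0 + delta, t=0.3),
                  ("superordinate", "bird"): cr.DDMParams(a=1.4, v=2.0, t=0.3)}
        post = cr.generate_posterior_samples(params, spread=sigma, n_samples=20000, seed=2)
        p = cr.posterior_overlap_probability(
            post[("basic", "bird", "v")], post[("superordinate", "bird", "v")]
        )
        expected = stats.norm.cdf(delta / (sigma * np.sqrt(2)))
        assert abs(p - expected) < 3 * np.sqrt(expected * (1 - expected) / 20000) + 0.01


class TestGenerateTemplates:
    def test_unit_norm_rows(self):
        t, areas, chs = cr.generate_templates(6, 64, seed=0)
        assert t.shape == (6, 64)
        assert np.allclose(np.linalg.norm(t, axis=1), 1.0, atol=1e-12)

    def test_determinism(self):
        a, _, _ = cr.generate_templates(6, 32, seed=3)
        b, _, _ = cr.generate_templates(6, 32, seed=3)
        assert np.array_equal(a, b)

    def test_pairwise_distinguishability(self):
        t, _, _ = cr.generate_templates(6, 32, seed=0)
        gram = np.abs(t @ t.T - np.eye(6))
        assert gram.max() < 0.95

    def test_infeasible_configuration_raises(self):
        with pytest.raises(RuntimeError, match="channels"):
            cr.generate_templates(8, 3, smoothness=3.0, seed=0, max_tries=3)
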