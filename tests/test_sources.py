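import numpy as np
import pytest
from scipy import stats

import catrep as cr
from catrep.decoding import _batch_lda
from catrep.sources import (
    consecutive_significance,
    gaussian_z_pvalue,
    localize_templates,
    signflip_bootstrap_null,
    source_analysis,
    weights_to_pattern,
)


def orthonormal_templates(n_areas, n_channels, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_areas)))
    return q.T


class TestWeightsToPattern:
    def test_isotropic_pattern_is_mean_difference(self, rng):
        n, c = 2000, 10
        delta = rng.standard_normal(c)
        x = rng.standard_normal((n, c, 1))
        y = np.repeat([0, 1], n // 2)
        x[y == 1] += delta[None, :, None]
        w, _, _, _, _ = _batch_lda(x, y, "auto")
        pattern = weights_to_pattern(w, x)[:, 0]
        cos = abs(np.dot(pattern, delta)) / (np.linalg.norm(pattern) * np.linalg.norm(delta))
        assert cos > 0.99

    def test_pattern_matches_erp_difference(self, rng):
        # correlated noise: raw weights differ from the ERP difference but the
        # Haufe-transformed pattern must recover it per timepoint
        n, c, t = 2000, 8, 5
        chol = np.linalg.cholesky(0.5 * np.eye(c) + 0.5 * np.ones((c, c)))
        x = np.einsum("cd,ndt->nct", chol, rng.standard_normal((n, c, t)))
        y = np.repeat([0, 1], n // 2)
        delta = rng.standard_normal((c, t))
        x[y == 1] += delta[None]
        w, _, _, _, _ = _batch_lda(x, y, "auto")
        pattern = weights_to_pattern(w, x)
        erp_diff = x[y == 0].mean(0) - x[y == 1].mean(0)
        cos = np.abs(np.sum(pattern * erp_diff, axis=0)) / (
            np.linalg.norm(pattern, axis=0) * np.linalg.norm(erp_diff, axis=0)
        )
        assert cos.min() > 0.95

    def test_decoupled_channel_stays_near_zero(self, rng):
        n, c = 5000, 6
        x = rng.standard_normal((n, c, 1))  # independent channels
        w = np.zeros((1, c))
        w[0, :3] = rng.standard_normal(3)
        pattern = weights_to_pattern(w, x)[:, 0]
        # channels with zero weight and independent noise get ~zero pattern
        assert np.abs(pattern[3:]).max() < 0.1 * np.abs(pattern[:3]).max()

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            weights_to_pattern(np.zeros((4, 3)), rng.standard_normal((10, 5, 4)))


class TestLocalizeTemplates:
    def test_exact_member_recovered(self):
        t = orthonormal_templates(4, 16)
        coef, resid = localize_templates(t[2], t)
        expected = np.zeros(4)
        expected[2] = 1.0
        assert np.allclose(coef, expected, atol=1e-9)
        assert resid < 1e-12

    def test_linear_combination_recovered(self):
        t = orthonormal_templates(4, 16)
        coef, _ = localize_templates(2.0 * t[0] + 3.0 * t[1], t)
        assert np.allclose(coef, [2.0, 3.0, 0.0, 0.0], atol=1e-9)

    def test_exact_linearity_in_pattern(self, rng):
        t, _, _ = cr.generate_templates(5, 24, seed=0)
        pattern = rng.standard_normal((24, 7))
        c1, _ = localize_templates(pattern, t)
        c2, _ = localize_templates(3.5 * pattern, t)
        assert np.allclose(c2, 3.5 * c1, atol=1e-12)

    def test_white_noise_mostly_residual(self, rng):
        t = orthonormal_templates(4, 64)
        coef, resid = localize_templates(rng.standard_normal(64), t)
        assert resid > 0.8

    def test_rank_deficient_templates_rejected(self):
        t = orthonormal_templates(3, 16)
        bad = np.vstack([t, t[0]])
        with pytest.raises(ValueError, match="collinear"):
            localize_templates(np.zeros(16), bad)


class TestSignflipBootstrap:
    def test_null_mean_near_zero(self, rng):
        patterns = rng.standard_normal((8, 16, 10))
        t = orthonormal_templates(4, 16)
        null = signflip_bootstrap_null(patterns, t, n_boot=400, seed=0)
        z = null.mean(axis=0) / (null.std(axis=0, ddof=1) / np.sqrt(400))
        assert np.abs(z).mean() < 2  # symmetric null

    def test_determinism(self, rng):
        patterns = rng.standard_normal((5, 16, 4))
        t = orthonormal_templates(3, 16)
        a = signflip_bootstrap_null(patterns, t, n_boot=200, seed=7)
        b = signflip_bootstrap_null(patterns, t, n_boot=200, seed=7)
        assert np.array_equal(a, b)

    def test_strong_pattern_outside_null(self, rng):
        t = orthonormal_templates(3, 16)
        # all participants share a strong, consistent template-0 pattern;
        # with 15 participants even the all-positive sign draw (p = 2^-15)
        # is effectively never sampled, so the null tail is empty
        patterns = np.tile(t[0][None, :, None], (15, 1, 5))
        patterns += 0.05 * rng.standard_normal(patterns.shape)
        from catrep.sources import group_pattern

        observed, _ = localize_templates(group_pattern(patterns), t)
        null = signflip_bootstrap_null(patterns, t, n_boot=1000, seed=1)
        tail = np.sum(null[:, 0, :] >= observed[0, :], axis=0)
        assert tail.max() == 0


class TestGaussianZ:
    def test_observed_at_null_mean(self, rng):
        null = rng.standard_normal(500)
        z, p = gaussian_z_pvalue(null.mean(), null)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_critical_value(self):
        null = np.array([-1.0, 1.0]) / np.sqrt(2)  # mean 0, sd 1
        z, p = gaussian_z_pvalue(1.959964, null)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_even_in_z(self, rng):
        null = rng.standard_normal(100)
        _, p_plus = gaussian_z_pvalue(null.mean() + 2 * null.std(ddof=1), null)
        _, p_minus = gaussian_z_pvalue(null.mean() - 2 * null.std(ddof=1), null)
        assert p_plus == pytest.approx(p_minus, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            gaussian_z_pvalue(1.0, np.ones(10))


class TestConsecutiveSignificance:
    def test_all_nonsignificant(self):
        assert not consecutive_significance(np.ones(50), srate=1000).any()

    def test_long_run_kept_short_run_dropped(self):
        p = np.ones(100)
        p[10:30] = 1e-4  # 20 ms at 1000 Hz
        p[60:70] = 1e-4  # 10 ms
        mask = consecutive_significance(p, p_threshold=0.005, min_duration_ms=15, srate=1000)
        assert mask[10:30].all()
        assert not mask[60:70].any()
        assert mask.sum() == 20

    def test_run_at_exact_minimum_is_kept(self):
        p = np.ones(50)
        p[5:20] = 1e-4  # exactly 15 samples = 15 ms
        mask = consecutive_significance(p, srate=1000)
        assert mask.sum() == 15


class TestSourceAnalysisEndToEnd:
    def test_planted_area_detected_with_onset(self, rng):
        # the sign-flip z score saturates at sqrt(n_participants) for a
        # perfectly consistent effect; p < 0.005 needs |z| > 2.81, so a
        # study-sized group (16) is required for the rule to fire
        t = orthonormal_templates(4, 24)
        n_participants, n_times, srate = 16, 120, 200.0
        times = -150.0 + 1000.0 / srate * np.arange(n_times)
        ramp = np.clip((times - 250.0) / 50.0, 0.0, 1.0)
        patterns = 0.15 * rng.standard_normal((n_participants, 24, n_times))
        patterns += t[1][None, :, None] * ramp[None, None, :]
        res = source_analysis(patterns, t, [f"a{i}" for i in range(4)], times,
                              srate=srate, n_boot=500, seed=0)
        assert res.mask[1].any()
        onset = times[np.argmax(res.mask[1])]
        assert 220.0 <= onset <= 330.0
        # other areas stay silent
        assert not res.mask[[0, 2, 3]].any()

    def test_global_null_rate_below_pointwise_level(self, rng):
        t = orthonormal_templates(3, 12)
        rates = []
        for _ in range(60):
            patterns = rng.standard_normal((6, 12, 60))
            null = signflip_bootstrap_null(patterns, t, n_boot=200, seed=rng.integers(2**31))
            from catrep.sources import group_pattern

            observed, _ = localize_templates(group_pattern(patterns), t)
            _, p = gaussian_z_pvalue(observed, null)
            mask = consecutive_significance(p, 0.005, 15.0, srate=1000.0)
            rates.append(mask.mean())
        assert np.mean(rates) < 0.005
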