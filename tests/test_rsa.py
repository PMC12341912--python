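import numpy as np
import pytest

import catrep as cr
from catrep.rsa import (
    DissimilarityMatrix,
    RDMSeries,
    classical_mds,
    cv_euclidean_distance,
    make_pseudotrials,
    noise_normalize,
    procrustes_align,
    rdm_at_window,
)

from conftest import make_epochs


class TestNoiseNormalize:
    def test_identity_noise_gives_identity_whitener(self, rng):
        data = rng.standard_normal((2000, 8, 3))
        ep = make_epochs(data=data, categories=["bird"] * 1000 + ["vehicle"] * 1000)
        _, w = noise_normalize(ep)
        op_norm = np.linalg.norm(w - np.eye(8), 2)
        assert op_norm < 0.2

    def test_unequal_variances_equalized(self, rng):
        data = rng.standard_normal((2000, 2, 4))
        data[:, 1] *= 2.0  # variances (1, 4)
        ep = make_epochs(data=data, categories=["bird"] * 1000 + ["vehicle"] * 1000)
        out, _ = noise_normalize(ep)
        v = out.data.var(axis=(0, 2))
        assert np.allclose(v, 1.0, atol=0.15)

    def test_double_whitening_is_near_identity(self, rng):
        chol = np.linalg.cholesky(np.array([[2.0, 0.6], [0.6, 1.0]]))
        data = np.einsum("cd,ndt->nct", chol, rng.standard_normal((1500, 2, 4)))
        ep = make_epochs(data=data, categories=["bird"] * 750 + ["vehicle"] * 750)
        once, _ = noise_normalize(ep)
        _, w2 = noise_normalize(once)
        assert np.linalg.norm(w2 - np.eye(2), 2) < 0.2

    def test_few_trials_warns(self, rng):
        ep = make_epochs(n_trials=6, n_channels=8, seed=0)
        with pytest.warns(UserWarning, match="unstable"):
            noise_normalize(ep)


class TestMakePseudotrials:
    def test_n_pseudo_equal_trial_count_is_identity(self, rng):
        ep = make_epochs(n_trials=10, seed=1)
        out = make_pseudotrials(ep, n_pseudo=5, seed=0)
        # 2 conditions x 5 pseudotrials, each the average of exactly 1 trial
        assert out.n_trials == 10
        sums = sorted(out.data.sum(axis=(1, 2)).round(9))
        assert sums == sorted(ep.data.sum(axis=(1, 2)).round(9))

    def test_identical_trials_give_identical_pseudotrials(self):
        data = np.tile(np.arange(12.0).reshape(1, 3, 4), (10, 1, 1))
        ep = make_epochs(data=data, categories=["bird"] * 10)
        out = make_pseudotrials(ep, n_pseudo=5, seed=3)
        assert np.allclose(out.data, data[0])

    def test_mean_preserved_for_equal_partition(self, rng):
        ep = make_epochs(n_trials=20, categories=["bird"] * 20, seed=2)
        out = make_pseudotrials(ep, n_pseudo=5, seed=1)
        assert np.allclose(out.data.mean(axis=0), ep.data.mean(axis=0), atol=1e-12)

    def test_too_few_trials_raises(self):
        ep = make_epochs(n_trials=4, categories=["bird"] * 4)
        with pytest.raises(ValueError, match="fewer than"):
            make_pseudotrials(ep, n_pseudo=5)


class TestCvEuclideanDistance:
    def test_null_mean_near_zero_and_naive_biased(self, rng):
        vals, naive = [], []
        for i in range(40):
            a = rng.standard_normal((25, 6, 4))
            b = rng.standard_normal((25, 6, 4))
            vals.append(cv_euclidean_distance(a, b, n_iterations=5, seed=i).mean())
            naive.append(np.sum((a.mean(0) - b.mean(0)) ** 2, axis=0).mean())
        vals = np.array(vals)
        z = vals.mean() / (vals.std(ddof=1) / np.sqrt(len(vals)))
        assert abs(z) < 3
        assert min(naive) > 0  # plain distance is strictly positive under the null

    def test_noiseless_distance_is_exact(self, rng):
        delta = rng.standard_normal(6)
        a = np.tile(delta[None, :, None], (10, 1, 5))
        b = np.zeros((10, 6, 5))
        d = cv_euclidean_distance(a, b, n_iterations=3, seed=0)
        assert np.abs(d - np.sum(delta**2)).max() < 1e-9

    def test_split_half_self_distance_unbiased(self, rng):
        vals = []
        for i in range(40):
            x = rng.standard_normal((30, 5, 3))
            vals.append(cv_euclidean_distance(x[:15], x[15:], n_iterations=5, seed=i).mean())
        vals = np.array(vals)
        z = vals.mean() / (vals.std(ddof=1) / np.sqrt(len(vals)))
        assert abs(z) < 3

    def test_orthogonal_invariance(self, rng):
        a = rng.standard_normal((15, 6, 4))
        b = rng.standard_normal((15, 6, 4)) + 0.5
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        d1 = cv_euclidean_distance(a, b, n_iterations=4, seed=2)
        d2 = cv_euclidean_distance(
            np.einsum("cd,ndt->nct", q, a), np.einsum("cd,ndt->nct", q, b),
            n_iterations=4, seed=2,
        )
        assert np.allclose(d1, d2, atol=1e-9)

    def test_seed_stability_on_planted_signal(self, rng):
        delta = np.zeros((6, 1))
        delta[0] = 1.5
        a = rng.standard_normal((40, 6, 30)) + delta[None]
        b = rng.standard_normal((40, 6, 30))
        d1 = cv_euclidean_distance(a, b, n_iterations=20, seed=1)
        d2 = cv_euclidean_distance(a, b, n_iterations=20, seed=2)
        assert np.corrcoef(d1, d2)[0, 1] > 0.95

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            cv_euclidean_distance(rng.standard_normal((10, 4, 5)), rng.standard_normal((10, 3, 5)))


class TestRdmWindow:
    def _series(self, values):
        times = np.arange(0.0, 100.0, 10.0)
        return RDMSeries(times=times, task="basic",
                         distances={("bird", "nonbird_animal"): values,
                                    ("bird", "vehicle"): values * 2,
                                    ("nonbird_animal", "vehicle"): values * 3})

    def test_constant_series(self):
        s = self._series(np.full(10, 2.5))
        dm = rdm_at_window(s, 50.0, 15.0)
        assert dm.matrix[dm.labels.index("bird"), dm.labels.index("nonbird_animal")] == 2.5
        assert np.allclose(np.diag(dm.matrix), 0.0)

    def test_single_sample_window(self):
        s = self._series(np.arange(10.0))
        dm = rdm_at_window(s, 30.0, 4.0)
        assert dm.matrix[0, 1] == 3.0 or dm.matrix[1, 0] == 3.0

    def test_linear_ramp_gives_midpoint(self):
        s = self._series(np.arange(10.0))
        dm = rdm_at_window(s, 50.0, 15.0)  # samples 40,50,60 -> values 4,5,6
        i, j = dm.labels.index("bird"), dm.labels.index("nonbird_animal")
        assert dm.matrix[i, j] == pytest.approx(5.0)

    def test_empty_window_raises(self):
        s = self._series(np.zeros(10))
        with pytest.raises(ValueError, match="no samples"):
            rdm_at_window(s, 500.0, 4.0)


class TestClassicalMds:
    def test_zero_matrix_gives_coincident_points(self):
        coords, evals = classical_mds(np.zeros((4, 4)), k=2)
        assert np.allclose(coords, 0.0)

    def test_equilateral_triangle(self):
        d = 1.7
        m = np.full((3, 3), d)
        np.fill_diagonal(m, 0.0)
        coords, _ = classical_mds(m, k=2)
        dist = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        off = dist[~np.eye(3, dtype=bool)]
        assert np.allclose(off, d, atol=1e-9)

    def test_round_trip_from_known_2d_points(self, rng):
        pts = rng.standard_normal((6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        coords, evals = classical_mds(d, k=2)
        d2 = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        assert np.abs(d - d2).max() < 1e-9
        # only two meaningful dimensions
        assert np.abs(evals[2:]).max() < 1e-9 * max(1, evals[0])

    def test_negative_eigenvalues_reported_not_clipped(self):
        # a signed 'squared distance' matrix with non-Euclidean structure
        s = np.array([[0.0, -1.0, 1.0], [-1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        coords, evals = classical_mds(s, k=2, input_kind="squared")
        assert evals.min() < 0

    def test_non_embeddable_raises(self):
        s = -np.ones((3, 3))
        np.fill_diagonal(s, 0.0)
        with pytest.raises(ValueError, match="embeddable"):
            classical_mds(s, k=2, input_kind="squared")

    def test_procrustes_alignment_removes_rotation(self, rng):
        pts = rng.standard_normal((5, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        aligned = procrustes_align(pts @ rot.T, pts)
        assert np.allclose(aligned, pts, atol=1e-9)


class TestDissimilarityMatrix:
    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), 0.0, 15.0)
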