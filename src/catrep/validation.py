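"""Simulation studies validating the pipeline's statistical guarantees.

These are the package's own calibration and parameter-recovery experiments,
runnable at desk scale on one CPU: family-wise error calibration of the
cluster permutation test, unbiasedness of the cross-validated distance
estimator, equivalence of Haufe-transformed LDA patterns with ERP
differences, recovery of the planted task-dependent separation onset, and
agreement of the diffusion simulator with closed-form first-passage theory.
Each function is deterministic given its seed and returns a plain dict of
numbers.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from ._utils import child_seed
from .cluster import cluster_permutation_test, condition_erp, differential_waveform
from .decoding import _batch_lda
from .epochs import baseline_correct
from .rsa import cv_euclidean_distance, rdm_timecourses
from .sources import weights_to_pattern
from .synth import (
    DDMParams,
    DesignSpec,
    generate_dataset,
    simulate_ddm,
    zero_schedule,
)


def cluster_fwer_study(
    n_datasets: int = 200,
    n_participants: int = 17,
    n_trials_per_task: int = 40,
    n_channels: int = 8,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error of the 1D cluster test under the global null.

    Each dataset is a group of synthetic participants generated with the
    zero-effect schedule; the tested statistic is each participant's
    channel-mean differential ERP between bird and non-bird-animal trials of
    the basic task (true difference identically zero). The family-wise error
    is the fraction of datasets in which any cluster reaches significance.
    """
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ds in range(n_datasets):
            diffs = []
            dataset = generate_dataset(
                n_participants,
                seed=child_seed(seed, "fwer", ds),
                scalp_only=True,
                design=DesignSpec(n_trials_per_task=n_trials_per_task),
                schedule=zero_schedule(),
                n_channels=n_channels,
                simulate_responses=False,
            )
            for ep, _ in dataset:
                ep = baseline_correct(ep)
                erp_a = condition_erp(ep, {"task": "basic", "category": "bird"})
                erp_b = condition_erp(ep, {"task": "basic", "category": "nonbird_animal"})
                diffs.append(differential_waveform(erp_a, erp_b).mean(axis=0))
            res = cluster_permutation_test(
                np.array(diffs), 0, n_perm=n_perm, alpha=alpha,
                seed=child_seed(seed, "fwer-test", ds),
            )
            hits += int(res.significant)
    return {"fwer": hits / n_datasets, "n_datasets": n_datasets, "alpha": alpha}


def distance_unbiasedness_study(
    n_sims: int = 100,
    n_trials: int = 25,
    n_channels: int = 8,
    n_times: int = 5,
    n_iterations: int = 5,
    seed: int = 0,
) -> dict:
    """Null-mean of the cross-validated squared distance vs the plain one.

    Two conditions drawn from the same distribution: the cross-validated
    estimator must average 0 (|z| < 3 across simulations) while the plain
    squared Euclidean distance between condition means is strictly positive
    — the bias the cross-validation removes.
    """
    rng = np.random.default_rng(child_seed(seed, "unbiased"))
    cv_means, naive = [], []
    for i in range(n_sims):
        a = rng.standard_normal((n_trials, n_channels, n_times))
        b = rng.standard_normal((n_trials, n_channels, n_times))
        d = cv_euclidean_distance(a, b, n_iterations=n_iterations, seed=child_seed(seed, "cv", i))
        cv_means.append(d.mean())
        naive.append(np.sum((a.mean(0) - b.mean(0)) ** 2, axis=0).mean())
    cv_means = np.array(cv_means)
    se = cv_means.std(ddof=1) / np.sqrt(n_sims)
    return {
        "mean_cv_distance": float(cv_means.mean()),
        "se": float(se),
        "z": float(cv_means.mean() / se),
        "mean_naive_distance": float(np.mean(naive)),
        "min_naive_distance": float(np.min(naive)),
        "n_sims": n_sims,
    }


def pattern_erp_equivalence_study(
    n_trials: int = 2000,
    n_channels: int = 8,
    n_times: int = 6,
    seed: int = 0,
) -> dict:
    """Cosine between Haufe-transformed LDA patterns and ERP differences.

    Well-conditioned two-class data with spatially correlated noise: the
    classifier weights themselves are rotated away from the mean-difference
    direction by the noise covariance, but the activation pattern must
    align with the ERP difference at every timepoint.
    """
    rng = np.random.default_rng(child_seed(seed, "haufe"))
    chol = np.linalg.cholesky(0.5 * np.eye(n_channels) + 0.5 * np.ones((n_channels, n_channels)))
    x = np.einsum("cd,ndt->nct", chol, rng.standard_normal((n_trials, n_channels, n_times)))
    y = np.repeat([0, 1], n_trials // 2)
    delta = rng.standard_normal((n_channels, n_times))
    x[y == 1] += delta[None]
    w, _, _, _, _ = _batch_lda(x, y, "auto")
    pattern = weights_to_pattern(w, x)
    erp_diff = x[y == 0].mean(0) - x[y == 1].mean(0)
    cos = np.abs(np.sum(pattern * erp_diff, axis=0)) / (
        np.linalg.norm(pattern, axis=0) * np.linalg.norm(erp_diff, axis=0)
    )
    return {"min_cosine": float(cos.min()), "mean_cosine": float(cos.mean()), "n_times": n_times}


def headline_recovery_study(
    n_seeds: int = 20,
    n_participants: int = 17,
    n_trials_per_task: int = 300,
    n_channels: int = 32,
    n_perm: int = 200,
    onset_tolerance_ms: float = 30.0,
    planted_onset_ms: float = 250.0,
    seed: int = 0,
) -> dict:
    """Recovery of the planted task effect from full synthetic sessions.

    For each replicate, a group of synthetic participants is generated with
    the default geometry (bird/non-bird separation only in the basic task,
    ramping from 250 ms; category/vehicle separation equal in both tasks).
    The RSA stage produces cross-validated distance time courses per
    participant and the between-task cluster test is run for both contrasts.
    Success: a significant bird/non-bird cluster with onset within the
    tolerance of the planted onset, and no significant between-task
    animal/vehicle cluster.
    """
    onsets = []
    bn_ok = 0
    av_clean = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_seeds):
            rep_seed = child_seed(seed, "recovery", rep)
            dataset = generate_dataset(
                n_participants,
                seed=rep_seed,
                scalp_only=True,
                shared_mixing=False,
                design=DesignSpec(n_trials_per_task=n_trials_per_task),
                n_channels=n_channels,
                simulate_responses=False,
            )
            series = {}
            for task in ("basic", "superordinate"):
                bn, av = [], []
                for i, (ep, _) in enumerate(dataset):
                    ep = baseline_correct(ep)
                    s = rdm_timecourses(ep, task, seed=child_seed(rep_seed, "rsa", task, i))
                    bn.append(s.get(("bird", "nonbird_animal")))
                    av.append(s.get(("nonbird_animal", "vehicle")))
                series[task] = (np.array(bn), np.array(av))
            times = dataset[0][0].times
            bn_test = cluster_permutation_test(
                series["basic"][0], series["superordinate"][0],
                n_perm=n_perm, seed=child_seed(rep_seed, "bn-test"),
            )
            av_test = cluster_permutation_test(
                series["basic"][1], series["superordinate"][1],
                n_perm=n_perm, seed=child_seed(rep_seed, "av-test"),
            )
            onset = bn_test.onset_ms(times)
            if onset is not None:
                onsets.append(onset)
                if abs(onset - planted_onset_ms) <= onset_tolerance_ms:
                    bn_ok += 1
            av_clean += int(not av_test.significant)
    return {
        "recovery_rate": bn_ok / n_seeds,
        "no_spurious_task_effect_rate": av_clean / n_seeds,
        "mean_onset_ms": float(np.mean(onsets)) if onsets else float("nan"),
        "n_seeds": n_seeds,
        "planted_onset_ms": planted_onset_ms,
    }


def closed_form_upper_probability(a: float, v: float, s: float, z_rel: float) -> float:
    """Exact upper-boundary absorption probability of the drifted Wiener
    process on [0, a] started at z_rel * a (the diffusion simulator's
    independent oracle)."""
    z = z_rel * a
    if v == 0:
        return z / a
    return float((1.0 - np.exp(-2.0 * v * z / s**2)) / (1.0 - np.exp(-2.0 * v * a / s**2)))


DDM_ORACLE_SETS = (
    DDMParams(a=1.0, v=2.0, t=0.30),
    DDMParams(a=1.4, v=1.0, t=0.25),
    DDMParams(a=0.8, v=3.0, t=0.35),
)


def ddm_oracle_study(n_trials: int = 20000, seed: int = 0) -> dict:
    """Simulated choice probability vs closed-form first-passage theory,
    plus the non-decision-time floor, for three parameter sets."""
    results = []
    for i, params in enumerate(DDM_ORACLE_SETS):
        sim = simulate_ddm(params, n_trials, seed=child_seed(seed, "ddm", i))
        responded = sim["correct"].notna()
        p_sim = float((sim["correct"] == True).sum() / responded.sum())  # noqa: E712
        p_exact = closed_form_upper_probability(params.a, params.v, params.s, params.z_rel)
        se = float(np.sqrt(p_exact * (1 - p_exact) / int(responded.sum())))
        results.append(
            {
                "p_sim": p_sim,
                "p_exact": p_exact,
                "abs_z": abs(p_sim - p_exact) / se,
                "min_rt_minus_t_ms": float(sim["rt_ms"].min() - params.t * 1000.0),
            }
        )
    return {
        "max_abs_z": max(r["abs_z"] for r in results),
        "min_rt_margin_ms": min(r["min_rt_minus_t_ms"] for r in results),
        "per_set": results,
        "n_trials": n_trials,
    }


def analytic_checks() -> dict:
    """Deterministic closed-form checks of the inferential building blocks."""
    from .behavior import dprime_corrected
    from .rsa import classical_mds
    from .sources import gaussian_z_pvalue

    null = np.array([-1.0, 1.0]) / np.sqrt(2)  # mean 0, sd 1
    _, p_zero = gaussian_z_pvalue(0.0, null)
    _, p_crit = gaussian_z_pvalue(1.959964, null)
    d_perfect = dprime_corrected(10, 0, 0, 10)
    d_swapped = dprime_corrected(0, 10, 10, 0)
    rng = np.random.default_rng(123)
    pts = rng.standard_normal((6, 2))
    dist = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    coords, _ = classical_mds(dist, k=2)
    dist2 = np.linalg.norm(coords[:, None] - coords[None], axis=2)
    return {
        "p_at_z0": float(p_zero),
        "p_at_z196": float(p_crit),
        "dprime_perfect": float(d_perfect),
        "dprime_antisymmetry_error": float(abs(d_perfect + d_swapped)),
        "mds_roundtrip_max_error": float(np.abs(dist - dist2).max()),
    }
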