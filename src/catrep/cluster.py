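"""Condition ERPs, differential waveforms, and cluster-based permutation tests.

The permutation engine controls family-wise error over a 1D time axis or a
2D (train x test) grid: pointwise paired t statistics are thresholded at a
cluster-forming alpha, contiguous suprathreshold points form clusters whose
mass is the summed t, and each observed cluster's |mass| is compared against
the permutation distribution of the maximum |mass| under random within-unit
sign flips (equivalently, condition swaps for paired data). Participants are
the exchangeable units. For 2D grids, nonsignificant points fully enclosed
by a significant cluster can be filled into the significance mask.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .epochs import EpochSet


def condition_erp(epochs: EpochSet, selector: dict) -> np.ndarray:
    """Mean over all trials matching the selector -> channels x time."""
    mask = epochs.trial_mask(**selector)
    if not mask.any():
        raise ValueError(f"no trials match selector {selector!r}")
    return epochs.data[mask].mean(axis=0)


def differential_waveform(erp_a: np.ndarray, erp_b: np.ndarray) -> np.ndarray:
    """Elementwise ERP difference a - b."""
    erp_a, erp_b = np.asarray(erp_a), np.asarray(erp_b)
    if erp_a.shape != erp_b.shape:
        raise ValueError(f"shape mismatch: {erp_a.shape} vs {erp_b.shape}")
    return erp_a - erp_b


@dataclass
class Cluster:
    indices: np.ndarray  # flat indices into the (raveled) domain
    mass: float
    p_value: float
    sign: int


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    mask: np.ndarray  # significant mask over the domain (after hole filling)
    mask_prefill: np.ndarray
    t_obs: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.mask.any())

    def cluster_extent(self, times: np.ndarray, cluster: Cluster):
        """(onset, offset) latencies in ms of a 1D cluster."""
        return float(times[cluster.indices.min()]), float(times[cluster.indices.max()])

    def onset_ms(self, times: np.ndarray, alpha: float | None = None):
        """Earliest latency covered by any significant cluster (1D), or None."""
        alpha = alpha if alpha is not None else self.params.get("alpha", 0.05)
        sig = [c for c in self.clusters if c.p_value < alpha]
        if not sig:
            return None
        return float(times[min(c.indices.min() for c in sig)])


def _pointwise_t(mean, var, n, cap):
    """t statistic from precomputed means/variances; zero-variance points get
    +/-inf, then capped at the largest finite |t| to keep masses finite."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.where((var == 0) & (mean == 0), 0.0, t)
    infinite = ~np.isfinite(t)
    if infinite.any():
        finite = np.abs(t[np.isfinite(t)])
        capval = cap if cap is not None else (finite.max() if finite.size else 100.0)
        t = np.where(infinite, np.sign(mean) * capval, t)
    return t


def _max_cluster_mass(t_map, t_crit, structure):
    """Maximum |summed t| over suprathreshold clusters of both signs."""
    best = 0.0
    for sign in (1, -1):
        lab, n_lab = ndimage.label(sign * t_map > t_crit, structure=structure)
        if n_lab:
            masses = np.abs(ndimage.sum_labels(t_map, lab, index=np.arange(1, n_lab + 1)))
            best = max(best, masses.max())
    return best


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b=0,
    paired: bool = True,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    tail: str = "two",
    fill_holes: bool = False,
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-based permutation test of ``cond_a`` vs ``cond_b`` (or zero).

    ``cond_a`` is units x domain where the domain is a 1D time axis or a 2D
    grid (connectivity is inferred from dimensionality; 2D uses 4-neighbor
    faces). ``cond_b`` is an array of the same shape or the scalar 0. The
    null distribution is the max cluster |mass| over ``n_perm`` random sign
    flips of the within-unit differences; all 2^n flips are enumerated
    exactly when testing against zero with <= 12 units. Cluster
    p = (1 + #{null >= observed}) / (1 + n_perm) for sampled permutations.
    """
    cond_a = np.asarray(cond_a, dtype=float)
    against_zero = np.isscalar(cond_b) and cond_b == 0
    diffs = cond_a if against_zero else cond_a - np.asarray(cond_b, dtype=float)
    if not paired:
        raise NotImplementedError("only paired (within-unit) designs are supported")
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units (participants)")
    domain_shape = diffs.shape[1:]
    if len(domain_shape) not in (1, 2):
        raise ValueError("domain must be 1D (time) or 2D (grid)")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution will be coarse")
    if tail not in ("two",):
        raise NotImplementedError("only two-sided tests are implemented")

    flat = diffs.reshape(n, -1)
    d = flat.shape[1]
    sumsq = np.sum(flat**2, axis=0)  # invariant under sign flips
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, n - 1)
    structure = None
    if len(domain_shape) == 2:
        structure = ndimage.generate_binary_structure(2, 1)  # faces only

    def t_from_signs(signs):
        mean = signs @ flat / n
        var = (sumsq - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        return mean, var

    mean_obs = flat.mean(axis=0)
    var_obs = flat.var(axis=0, ddof=1)
    t_obs = _pointwise_t(mean_obs, var_obs, n, cap=None).reshape(domain_shape)
    cap = np.abs(t_obs).max() if np.isfinite(t_obs).all() else None

    # observed clusters (both signs)
    clusters = []
    for sign in (1, -1):
        lab, n_lab = ndimage.label(sign * t_obs > t_crit, structure=structure)
        for k in range(1, n_lab + 1):
            idx = np.flatnonzero((lab == k).ravel())
            mass = float(t_obs.ravel()[idx].sum())
            clusters.append(Cluster(indices=idx, mass=mass, p_value=1.0, sign=sign))

    # null distribution of the max cluster |mass|
    exact = against_zero and n <= 12
    if exact:
        sign_iter = (np.array(s, dtype=float) for s in itertools.product((1.0, -1.0), repeat=n))
        n_total = 2**n
    else:
        rng = np.random.default_rng(seed)
        sign_iter = (rng.choice((-1.0, 1.0), size=n) for _ in range(n_perm))
        n_total = n_perm
    null_max = np.empty(n_total)
    block = max(1, min(n_total, 200_000 // max(d, 1) + 1))
    buf = []
    filled = 0
    for signs in sign_iter:
        buf.append(signs)
        if len(buf) == block:
            mean, var = t_from_signs(np.array(buf))
            t_perm = _pointwise_t(mean, var, n, cap=cap)
            for row in t_perm:
                null_max[filled] = _max_cluster_mass(row.reshape(domain_shape), t_crit, structure)
                filled += 1
            buf = []
    if buf:
        mean, var = t_from_signs(np.array(buf))
        t_perm = _pointwise_t(mean, var, n, cap=cap)
        for row in t_perm:
            null_max[filled] = _max_cluster_mass(row.reshape(domain_shape), t_crit, structure)
            filled += 1

    for c in clusters:
        ge = int(np.sum(null_max >= abs(c.mass) - 1e-12))
        c.p_value = ge / n_total if exact else (1 + ge) / (1 + n_total)
        c.p_value = max(c.p_value, np.finfo(float).tiny)

    mask = np.zeros(domain_shape, dtype=bool).ravel()
    for c in clusters:
        if c.p_value < alpha:
            mask[c.indices] = True
    mask = mask.reshape(domain_shape)
    mask_prefill = mask.copy()
    if fill_holes and len(domain_shape) == 2 and mask.any():
        mask = ndimage.binary_fill_holes(mask, structure=structure)

    params = dict(
        n_units=n,
        n_perm=n_total,
        exact=exact,
        cluster_alpha=cluster_alpha,
        alpha=alpha,
        tail=tail,
        fill_holes=fill_holes,
        seed=seed,
        t_crit=float(t_crit),
    )
    clusters.sort(key=lambda c: c.p_value)
    return ClusterTestResult(
        clusters=clusters, mask=mask, mask_prefill=mask_prefill, t_obs=t_obs, params=params
    )


def result_to_dict(result: ClusterTestResult, times: np.ndarray | None = None) -> dict:
    """JSON-serializable summary of a cluster test."""
    out = {"params": result.params, "clusters": []}
    for c in result.clusters:
        entry = {"mass": c.mass, "p_value": c.p_value, "size": int(c.indices.size), "sign": c.sign}
        if times is not None and result.t_obs.ndim == 1:
            entry["extent_ms"] = [float(times[c.indices.min()]), float(times[c.indices.max()])]
        out["clusters"].append(entry)
    out["n_significant"] = int(sum(c.p_value < result.params["alpha"] for c in result.clusters))
    return out
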