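"""Cross-validated representational distances, dissimilarity matrices, MDS.

The dissimilarity measure is the cross-validated *squared* Euclidean
distance: trials of each condition are averaged into pseudotrials, and the
distance at each timepoint is the inner product between the pattern
difference on training pseudotrials and the difference on the held-out
pseudotrial, d_k(t) = (ā_train − b̄_train)·(a_k − b_k), averaged over folds
and over repeated random partitions. Because train and test differences
carry independent noise, the estimator is unbiased: its expectation is 0
when the two conditions are identical (sample values may be negative).
Multivariate noise normalization (whitening by the inverse square root of
the shrinkage-estimated within-condition error covariance) is applied to
single trials beforehand so all channels contribute on a common noise
scale. Windowed distances form condition dissimilarity matrices which
classical MDS projects to low-dimensional coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import child_seed, inv_sqrtm_psd, shrinkage_covariance
from .epochs import EpochSet

PAIRS = (("bird", "nonbird_animal"), ("nonbird_animal", "vehicle"), ("bird", "vehicle"))


@dataclass
class RDMSeries:
    """Per-timepoint cross-validated squared distances for condition pairs."""

    times: np.ndarray
    task: str | None
    distances: dict  # (cat_a, cat_b) sorted tuple -> (T,) array
    meta: dict = field(default_factory=dict)

    def get(self, pair) -> np.ndarray:
        return self.distances[tuple(sorted(pair))]


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    matrix: np.ndarray
    center_ms: float
    half_width_ms: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        np.fill_diagonal(m, 0.0)
        self.matrix = m


def noise_normalize(
    epochs: EpochSet,
    shrinkage="auto",
    scope: str = "time-average",
    by=("task", "category"),
):
    """Whiten trials by the inverse square root of the error covariance.

    The within-condition residual covariance is estimated per timepoint with
    analytic shrinkage toward the scaled identity; with
    ``scope='time-average'`` (default, the recommended variant) the
    estimates are averaged over timepoints before inversion, with
    ``scope='per-timepoint'`` each timepoint gets its own whitener.

    Returns (whitened EpochSet, whitening matrix (C, C) or (T, C, C)).
    """
    n, c, t = epochs.data.shape
    if n < c + 1:
        warnings.warn(
            f"{n} trials for {c} channels: error-covariance estimate may be unstable"
        )
    keys = epochs.labels[list(by)].apply(tuple, axis=1)
    residuals = epochs.data.copy()
    for key in keys.unique():
        idx = np.flatnonzero((keys == key).to_numpy())
        residuals[idx] -= residuals[idx].mean(axis=0, keepdims=True)
    sigma_t, _ = shrinkage_covariance(residuals, shrinkage)  # (T, C, C)
    if scope == "time-average":
        whitener = inv_sqrtm_psd(sigma_t.mean(axis=0))
        data = np.einsum("cd,ndt->nct", whitener, epochs.data, optimize=True)
    elif scope == "per-timepoint":
        whitener = inv_sqrtm_psd(sigma_t)  # (T, C, C)
        data = np.einsum("tcd,ndt->nct", whitener, epochs.data, optimize=True)
    else:
        raise ValueError("scope must be 'time-average' or 'per-timepoint'")
    out = replace(epochs, data=data, log=list(epochs.log))
    out.log.append(f"noise_normalize scope={scope}")
    return out, whitener


def _partition(n: int, n_pseudo: int, rng) -> list[np.ndarray]:
    """Random partition of range(n) into n_pseudo subsets, sizes differing <= 1."""
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_pseudo)]


def make_pseudotrials(epochs: EpochSet, n_pseudo: int = 5, seed: int = 0, by=("task", "category")) -> EpochSet:
    """Average random equal-size subsets of each condition into pseudotrials."""
    keys = epochs.labels[list(by)].apply(tuple, axis=1)
    rng = np.random.default_rng(seed)
    data_rows, label_rows = [], []
    for key in sorted(keys.unique()):
        idx = np.flatnonzero((keys == key).to_numpy())
        if idx.size < n_pseudo:
            raise ValueError(
                f"condition {key!r} has {idx.size} trials, fewer than n_pseudo={n_pseudo}"
            )
        for chunk in _partition(idx.size, n_pseudo, rng):
            data_rows.append(epochs.data[idx[chunk]].mean(axis=0))
            row = epochs.labels.iloc[idx[0]].copy()
            row["rt_ms"] = np.nan
            row["correct"] = None
            label_rows.append(row)
    labels = pd.DataFrame(label_rows).reset_index(drop=True)
    labels["correct"] = labels["correct"].astype("boolean")
    out = replace(
        epochs, data=np.array(data_rows), labels=labels, log=list(epochs.log)
    )
    out.log.append(f"make_pseudotrials n_pseudo={n_pseudo} seed={seed}")
    return out


def cv_euclidean_distance(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_pseudo: int = 5,
    n_iterations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated squared Euclidean distance time course between two
    conditions given their (whitened) single-trial arrays (n, C, T).

    Each iteration re-partitions both conditions into ``n_pseudo``
    pseudotrials; fold k uses pseudotrial k of each condition as the test
    pair and the mean of the remaining pseudotrials as the training
    pattern. Returns the (T,) distance averaged over folds and iterations.
    """
    a = np.asarray(trials_a, dtype=float)
    b = np.asarray(trials_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("conditions must be (n, channels, times) with matching channels/times")
    if n_pseudo < 2:
        raise ValueError("need at least 2 pseudotrials for cross-validation")
    if a.shape[0] < n_pseudo or b.shape[0] < n_pseudo:
        raise ValueError("each condition needs at least n_pseudo trials")
    t = a.shape[2]
    total = np.zeros(t)
    for it in range(n_iterations):
        rng = np.random.default_rng(child_seed(seed, "iteration", it))
        pa = np.stack([a[chunk].mean(axis=0) for chunk in _partition(a.shape[0], n_pseudo, rng)])
        pb = np.stack([b[chunk].mean(axis=0) for chunk in _partition(b.shape[0], n_pseudo, rng)])
        diff = pa - pb  # (K, C, T)
        s = diff.sum(axis=0)
        # train difference excluding fold k, dotted with held-out difference
        train = (s[None] - diff) / (n_pseudo - 1)
        total += np.einsum("kct,kct->t", train, diff, optimize=True) / n_pseudo
    return total / n_iterations


def rdm_timecourses(
    epochs: EpochSet,
    task: str,
    pairs=PAIRS,
    n_pseudo: int = 5,
    n_iterations: int = 20,
    seed: int = 0,
    whiten: bool = True,
    equalize_seed: int | None = None,
) -> RDMSeries:
    """Full RSA stage for one task: equalize trials, whiten, cv distances.

    Trial counts are equalized to the smallest condition, multivariate noise
    normalization is applied to the selected single trials, and
    cross-validated squared distances are computed per condition pair.
    """
    from .epochs import subsample_equal

    sub = epochs.where(task=task)
    eq = subsample_equal(
        sub, grouping=("category",),
        seed=child_seed(seed, "equalize") if equalize_seed is None else equalize_seed,
    )
    if whiten:
        eq, _ = noise_normalize(eq)
    distances = {}
    for pair in pairs:
        xa = eq.data[(eq.labels["category"] == pair[0]).to_numpy()]
        xb = eq.data[(eq.labels["category"] == pair[1]).to_numpy()]
        distances[tuple(sorted(pair))] = cv_euclidean_distance(
            xa, xb, n_pseudo=n_pseudo, n_iterations=n_iterations,
            seed=child_seed(seed, "pair", *sorted(pair)),
        )
    return RDMSeries(
        times=eq.times.copy(), task=task, distances=distances,
        meta=dict(n_pseudo=n_pseudo, n_iterations=n_iterations, seed=seed, whiten=whiten),
    )


def rdm_at_window(series: RDMSeries, center_ms: float, half_width_ms: float = 15.0) -> DissimilarityMatrix:
    """Average each pair's distance over |t − center| <= half_width and
    arrange as a symmetric zero-diagonal condition matrix. Negative windowed
    averages are retained (the estimator is signed)."""
    mask = np.abs(series.times - center_ms) <= half_width_ms
    if not mask.any():
        raise ValueError(
            f"window {center_ms}±{half_width_ms} ms contains no samples of the epoch "
            f"[{series.times[0]:g}, {series.times[-1]:g}] ms"
        )
    labels = sorted({c for pair in series.distances for c in pair})
    m = np.zeros((len(labels), len(labels)))
    for pair, values in series.distances.items():
        i, j = labels.index(pair[0]), labels.index(pair[1])
        m[i, j] = m[j, i] = values[mask].mean()
    return DissimilarityMatrix(labels=labels, matrix=m, center_ms=center_ms, half_width_ms=half_width_ms)


def classical_mds(matrix, k: int = 2, input_kind: str = "distance"):
    """Classical (Torgerson) multidimensional scaling.

    ``matrix`` is a DissimilarityMatrix or a symmetric array; with
    ``input_kind='distance'`` entries are distances (squared internally),
    with ``'squared'`` they are already squared dissimilarities (the
    convention of the cross-validated estimator, where entries may be
    negative). The Gram matrix B = −½ J S J is eigendecomposed; coordinates
    come from the top-k nonnegative eigenvalues, and the full eigenvalue
    spectrum is returned so callers can detect dimensionality loss or
    non-Euclidean (negative) structure.

    Returns (coordinates (n, k), eigenvalues (n,) descending).
    """
    d = matrix.matrix if isinstance(matrix, DissimilarityMatrix) else np.asarray(matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("input must be a square symmetric matrix")
    if input_kind == "distance":
        s = d**2
    elif input_kind == "squared":
        s = d.copy()
    else:
        raise ValueError("input_kind must be 'distance' or 'squared'")
    n = s.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ s @ j
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-12 * max(1.0, float(np.abs(s).max()))
    if np.all(evals <= tol):
        if np.abs(evals).max() <= tol:  # numerically zero input: coincident points
            return np.zeros((n, k)), evals
        raise ValueError("matrix is not embeddable: no positive eigenvalue in the Gram spectrum")
    coords = np.zeros((n, k))
    for dim in range(min(k, n)):
        if evals[dim] > 0:
            coords[:, dim] = evecs[:, dim] * np.sqrt(evals[dim])
    # deterministic sign convention: largest-|coordinate| entry positive
    for dim in range(coords.shape[1]):
        col = coords[:, dim]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, dim] = -col
    return coords, evals


def procrustes_align(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate/reflect coords onto a reference configuration (presentation
    only; MDS solutions are defined up to orthogonal transforms)."""
    from scipy.linalg import orthogonal_procrustes

    r, _ = orthogonal_procrustes(coords, reference)
    return coords @ r
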