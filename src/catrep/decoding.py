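"""Pairwise LDA decoding over time, shuffled-label baselines, and temporal
generalization.

Per timepoint, a linear discriminant is trained on the channel vector
(w ∝ Σ̂⁻¹(μ₁ − μ₂), with Σ̂ the shrinkage-regularized pooled within-class
covariance) under stratified 10-fold cross-validation; trial counts are
equalized by random subsampling, and the whole procedure is repeated
(default 10 times) with fresh subsamples and folds. The shuffled-label twin
runs the identical procedure on permuted labels, giving an empirical chance
distribution. Temporal generalization trains at each (binned) timepoint and
tests at all timepoints with the same folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import child_seed, shrinkage_covariance
from .epochs import EpochSet, bin_time, subsample_equal


@dataclass
class LDAModel:
    """A fitted two-class linear discriminant at one timepoint.

    Decision value = w . x + b; positive values map to ``classes[0]`` and
    exact zeros are broken toward ``classes[1]``.
    """

    weights: np.ndarray
    bias: float
    classes: tuple
    shrinkage: float
    class_means: np.ndarray  # (2, channels)
    covariance: np.ndarray  # pooled within-class, regularized

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        score = self.decision_values(x)
        return np.where(score > 0, self.classes[0], self.classes[1])


@dataclass
class DecodingResult:
    times: np.ndarray
    accuracy: np.ndarray  # (T,) mean over folds x repetitions
    per_repetition: np.ndarray  # (reps, T)
    baseline: "DecodingResult | None" = None
    meta: dict = field(default_factory=dict)


@dataclass
class TGMatrix:
    times: np.ndarray
    accuracy: np.ndarray  # (T_train, T_test)
    per_repetition: np.ndarray  # (reps, T_train, T_test)
    baseline: "TGMatrix | None" = None
    meta: dict = field(default_factory=dict)


def _batch_lda(x: np.ndarray, y01: np.ndarray, shrinkage="auto"):
    """Fit per-timepoint LDA weights in one shot.

    x : (n, C, T) training data; y01 : (n,) 0/1 class codes (0 = first class).
    Returns W (T, C), b (T,), lam (T,), means (2, C, T), sigma (T, C, C).
    """
    n, c, t = x.shape
    m0 = x[y01 == 0].mean(axis=0)  # (C, T)
    m1 = x[y01 == 1].mean(axis=0)
    centered = x - np.where(y01[:, None, None] == 0, m0, m1)
    if shrinkage == 0 or shrinkage == 0.0:
        s = np.einsum("ict,idt->tcd", centered, centered, optimize=True) / n
        lam = np.zeros(t)
        w = np.empty((t, c))
        for k in range(t):
            try:
                w[k] = np.linalg.solve(s[k], (m0 - m1)[:, k])
            except np.linalg.LinAlgError:
                w[k] = np.linalg.pinv(s[k]) @ (m0 - m1)[:, k]
        sigma = s
    else:
        sigma, lam = shrinkage_covariance(centered, shrinkage)
        w = np.linalg.solve(sigma, (m0 - m1).T[:, :, None])[:, :, 0]  # (T, C)
    mid = 0.5 * (m0 + m1)  # (C, T)
    b = -np.einsum("tc,ct->t", w, mid)
    return w, b, np.atleast_1d(lam), np.stack([m0, m1]), sigma


def fit_lda(x: np.ndarray, y, shrinkage="auto") -> LDAModel:
    """Fit a two-class LDA on trials x channels data.

    ``shrinkage`` is 'auto' (analytic Ledoit–Wolf intensity toward the
    scaled identity), a fixed intensity in [0, 1], or 0 for the unregularized
    pooled covariance with a pseudo-inverse fallback.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = tuple(dict.fromkeys(y.tolist()))  # order of first appearance
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    counts = [(y == cls).sum() for cls in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 trials")
    y01 = (y == classes[1]).astype(int)
    w, b, lam, means, sigma = _batch_lda(x[:, :, None], y01, shrinkage)
    return LDAModel(
        weights=w[0],
        bias=float(b[0]),
        classes=classes,
        shrinkage=float(lam[0]),
        class_means=means[:, :, 0],
        covariance=sigma[0],
    )


def _stratified_folds(y01: np.ndarray, folds: int, rng) -> np.ndarray:
    """Fold assignment (0..folds-1 per trial) with per-class balance."""
    assign = np.empty(y01.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        if idx.size < folds:
            raise ValueError(f"class {cls} has {idx.size} trials, fewer than {folds} folds")
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def _select_pair(epochs: EpochSet, pair, task, correct_only=False):
    conditions = {"category": tuple(pair)}
    if task is not None:
        conditions["task"] = task
    sub = epochs.where(**conditions)
    if correct_only:
        sub = sub.select_trials((sub.labels["correct"] == True).to_numpy())  # noqa: E712
    for cat in pair:
        n = int((sub.labels["category"] == cat).sum())
        if n == 0:
            raise ValueError(f"no trials for category {cat!r} (task={task!r})")
    return sub


def _cv_accuracy_timecourse(data, y01, folds, rng, shrinkage, tg=False):
    """One repetition of stratified k-fold decoding.

    Returns (T,) fold-averaged accuracy, or (T_train, T_test) when ``tg``.
    """
    n, c, t = data.shape
    assign = _stratified_folds(y01, folds, rng)
    acc = np.zeros((t, t)) if tg else np.zeros(t)
    for k in range(folds):
        train = assign != k
        test = ~train
        w, b, _, _, _ = _batch_lda(data[train], y01[train], shrinkage)
        if tg:
            # scores[trial, train_time, test_time]
            scores = np.einsum("tc,ncs->nts", w, data[test], optimize=True) + b[None, :, None]
            pred = (scores <= 0).astype(int)  # ties -> second class
            acc += (pred == y01[test][:, None, None]).mean(axis=0)
        else:
            scores = np.einsum("tc,nct->nt", w, data[test], optimize=True) + b
            pred = (scores <= 0).astype(int)
            acc += (pred == y01[test][:, None]).mean(axis=0)
    return acc / folds


def decode_timecourse(
    epochs: EpochSet,
    pair: tuple[str, str],
    task: str | None = None,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
    shrinkage="auto",
    correct_only: bool = False,
    shuffle_labels: bool = False,
    with_baseline: bool = False,
) -> DecodingResult:
    """Pairwise decoding accuracy per timepoint.

    Each repetition equalizes trial counts by random subsampling, assigns
    stratified folds, trains per-timepoint discriminants on the training
    folds and scores the held-out trials; accuracies are averaged over folds
    then repetitions. Fully reproducible from ``seed``.
    """
    sub = _select_pair(epochs, pair, task, correct_only)
    per_rep = np.empty((repetitions, sub.n_times))
    for rep in range(repetitions):
        eq = subsample_equal(sub, grouping=("category",), seed=child_seed(seed, "subsample", rep))
        y01 = (eq.labels["category"] == pair[1]).to_numpy().astype(int)
        if shuffle_labels:
            y01 = np.random.default_rng(child_seed(seed, "shuffle", rep)).permutation(y01)
        rng = np.random.default_rng(child_seed(seed, "folds", rep))
        per_rep[rep] = _cv_accuracy_timecourse(eq.data, y01, folds, rng, shrinkage)
    result = DecodingResult(
        times=sub.times.copy(),
        accuracy=per_rep.mean(axis=0),
        per_repetition=per_rep,
        meta=dict(
            pair=tuple(pair), task=task, folds=folds, repetitions=repetitions,
            seed=seed, shuffled=shuffle_labels, correct_only=correct_only,
        ),
    )
    if with_baseline:
        result.baseline = shuffled_baseline(
            epochs, pair, task, folds=folds, repetitions=repetitions,
            seed=seed, shrinkage=shrinkage, correct_only=correct_only,
        )
    return result


def shuffled_baseline(epochs, pair, task=None, folds=10, repetitions=10, seed=0,
                      shrinkage="auto", correct_only=False) -> DecodingResult:
    """Chance-level twin of :func:`decode_timecourse`: labels are permuted
    independently per repetition before fold assignment."""
    return decode_timecourse(
        epochs, pair, task, folds=folds, repetitions=repetitions,
        seed=child_seed(seed, "baseline"), shrinkage=shrinkage,
        correct_only=correct_only, shuffle_labels=True,
    )


def temporal_generalization(
    epochs: EpochSet,
    pair: tuple[str, str],
    task: str | None = None,
    bin_factor: int = 4,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
    shrinkage="auto",
    shuffle_labels: bool = False,
) -> TGMatrix:
    """Train x test accuracy matrix on time-binned epochs.

    Epochs are first averaged every ``bin_factor`` samples; per repetition
    and fold, the classifier trained at each timepoint is applied at every
    timepoint of the held-out trials. With the same seed, the diagonal
    equals :func:`decode_timecourse` run on the binned epochs.
    """
    binned = bin_time(epochs, bin_factor)
    sub = _select_pair(binned, pair, task)
    per_rep = np.empty((repetitions, sub.n_times, sub.n_times))
    for rep in range(repetitions):
        eq = subsample_equal(sub, grouping=("category",), seed=child_seed(seed, "subsample", rep))
        y01 = (eq.labels["category"] == pair[1]).to_numpy().astype(int)
        if shuffle_labels:
            y01 = np.random.default_rng(child_seed(seed, "shuffle", rep)).permutation(y01)
        rng = np.random.default_rng(child_seed(seed, "folds", rep))
        per_rep[rep] = _cv_accuracy_timecourse(eq.data, y01, folds, rng, shrinkage, tg=True)
    return TGMatrix(
        times=sub.times.copy(),
        accuracy=per_rep.mean(axis=0),
        per_repetition=per_rep,
        meta=dict(pair=tuple(pair), task=task, folds=folds, repetitions=repetitions,
                  seed=seed, bin_factor=bin_factor, shuffled=shuffle_labels),
    )
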