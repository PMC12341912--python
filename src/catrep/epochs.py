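"""Epoched EEG container and epoch-level conditioning operations.

The :class:`EpochSet` is the common currency of every analysis stage: a
``trials x channels x timepoints`` array in microvolts, with per-trial labels
(task, category, correctness, reaction time, participant) and a millisecond
time axis locked to stimulus onset. Operations here implement the standard
conditioning steps applied between epoching and multivariate analysis:
baseline correction, vertical-EOG artifact rejection, equal-trial
subsampling, temporal binning, and ROI averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TASKS = ("superordinate", "basic")
CATEGORIES = ("bird", "nonbird_animal", "vehicle")

#: Default region-of-interest electrode sets for a 64-channel 10-10 montage.
DEFAULT_ROIS = {
    "occipital": ["O1", "PO3", "PO7", "Oz", "O2", "PO4", "PO8"],
    "central": ["C3", "C1", "Cz", "C2", "C4"],
    "frontal": ["AF3", "F1", "AFz", "Fz", "F2", "AF4"],
}

LABEL_COLUMNS = ("task", "category", "correct", "rt_ms", "participant")


@dataclass
class RoiSpec:
    """A named set of electrodes averaged together for ERP summaries."""

    name: str
    electrodes: list[str]


@dataclass
class EpochSet:
    """Epoched EEG: ``data`` is trials x channels x timepoints in microvolts.

    ``times`` holds the latency of every sample in milliseconds relative to
    stimulus onset and must be uniform at ``1000/srate``. ``labels`` is a
    DataFrame with one row per trial and at least the columns ``task`` and
    ``category``; ``correct`` may contain missing values for no-response
    trials. ``veog_pair`` names the two vertically placed eye channels used
    for artifact screening.
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    channels: list[str]
    labels: pd.DataFrame
    veog_pair: tuple[str, str] | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = [str(c) for c in self.channels]
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n, c, t = self.data.shape
        if len(self.channels) != c:
            raise ValueError(f"{len(self.channels)} channel labels for {c} data channels")
        if self.times.shape != (t,):
            raise ValueError(f"times has length {self.times.size}, expected {t}")
        if len(self.labels) != n:
            raise ValueError(f"labels has {len(self.labels)} rows for {n} trials")
        dt = np.diff(self.times)
        if t > 1:
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt - 1000.0 / self.srate)) > 1e-9:
                raise ValueError("time spacing must equal 1000/srate")
        for col in ("task", "category"):
            if col not in self.labels.columns:
                raise ValueError(f"labels missing required column {col!r}")
            if self.labels[col].isna().any():
                raise ValueError(f"every trial must carry a {col} label")
        if self.veog_pair is not None:
            missing = [ch for ch in self.veog_pair if ch not in self.channels]
            if missing:
                raise ValueError(f"veog_pair channels not found: {missing}")
        self.labels = self.labels.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not found; available: {self.channels}") from None

    def select_trials(self, index) -> "EpochSet":
        """New EpochSet restricted to the given trial indices or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            data=self.data[index],
            labels=self.labels.iloc[index].reset_index(drop=True),
            log=list(self.log),
        )

    def where(self, **conditions) -> "EpochSet":
        """Restrict to trials whose labels equal the given values,
        e.g. ``epochs.where(task='basic', category='bird')``."""
        mask = self.trial_mask(**conditions)
        return self.select_trials(mask)

    def trial_mask(self, **conditions) -> np.ndarray:
        mask = np.ones(self.n_trials, dtype=bool)
        for col, value in conditions.items():
            if col not in self.labels.columns:
                raise KeyError(f"no label column {col!r}")
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= self.labels[col].isin(list(value)).to_numpy()
            else:
                mask &= (self.labels[col] == value).to_numpy()
        return mask


def baseline_correct(epochs: EpochSet, window: tuple[float, float] = (-150.0, 0.0)) -> EpochSet:
    """Subtract each trial x channel mean over the baseline window.

    The window is a closed interval on sample latencies in ms; the default
    spans the pre-stimulus period −150..0 ms.
    """
    lo, hi = float(window[0]), float(window[1])
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    if not mask.any():
        raise ValueError(
            f"baseline window ({lo}, {hi}) ms does not overlap the epoch range "
            f"[{epochs.times[0]:g}, {epochs.times[-1]:g}] ms"
        )
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    out = replace(epochs, data=epochs.data - baseline, log=list(epochs.log))
    out.log.append(f"baseline_correct window=({lo},{hi}) ms")
    return out


def reject_eye_epochs(epochs: EpochSet, threshold_uv: float = 150.0):
    """Drop trials whose vertical-EOG difference exceeds ``threshold_uv``.

    The screening statistic is the maximum absolute instantaneous difference
    between the two eye channels over the whole epoch. Returns the kept
    EpochSet and a boolean rejection mask over the *original* trials.
    """
    if epochs.veog_pair is None:
        raise ValueError(
            "veog_pair is not set on this EpochSet; set it to the two vertical "
            "eye channel labels or skip eye-artifact rejection"
        )
    i, j = (epochs.channel_index(ch) for ch in epochs.veog_pair)
    diff = epochs.data[:, i, :] - epochs.data[:, j, :]
    rejected = np.max(np.abs(diff), axis=1) > threshold_uv
    kept = epochs.select_trials(~rejected)
    kept.log.append(
        f"reject_eye_epochs threshold={threshold_uv} uV removed {int(rejected.sum())}"
        f"/{epochs.n_trials} trials"
    )
    return kept, rejected


def subsample_equal(
    epochs: EpochSet,
    grouping=("category",),
    seed: int = 0,
    groups=None,
) -> EpochSet:
    """Randomly subsample trials so every label group has the minimum count.

    ``grouping`` names the label columns defining the groups (default: the
    three categories). ``groups`` may list the expected group keys explicitly;
    a listed group with no trials raises. Selection is uniform without
    replacement and reproducible from ``seed``; original trial order is kept.
    """
    grouping = list(grouping)
    keys = epochs.labels[grouping].apply(tuple, axis=1)
    observed = {}
    for idx, key in enumerate(keys):
        observed.setdefault(key, []).append(idx)
    if groups is not None:
        expected = [tuple(g) if isinstance(g, (list, tuple)) else (g,) for g in groups]
        for g in expected:
            if g not in observed:
                raise ValueError(f"group {g!r} has no trials")
        observed = {g: observed[g] for g in expected}
    if len(observed) < 2:
        raise ValueError("need at least 2 groups to equalize trial counts")
    n_min = min(len(v) for v in observed.values())
    rng = np.random.default_rng(seed)
    chosen = []
    for key in sorted(observed):  # sorted for seed-stable iteration order
        idx = np.asarray(observed[key])
        chosen.append(rng.choice(idx, size=n_min, replace=False))
    take = np.sort(np.concatenate(chosen))
    out = epochs.select_trials(take)
    out.log.append(f"subsample_equal by {grouping} -> {n_min} trials/group (seed={seed})")
    return out


def bin_time(epochs: EpochSet, factor: int) -> EpochSet:
    """Average every ``factor`` consecutive samples, dropping any remainder.

    Output latencies are block centers (the mean of each block's latencies)
    and the sampling rate is divided by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return replace(epochs, log=list(epochs.log))
    n_out = epochs.n_times // factor
    if n_out == 0:
        raise ValueError(f"epoch has {epochs.n_times} samples, fewer than factor {factor}")
    trimmed = epochs.data[:, :, : n_out * factor]
    data = trimmed.reshape(epochs.n_trials, epochs.n_channels, n_out, factor).mean(axis=3)
    times = epochs.times[: n_out * factor].reshape(n_out, factor).mean(axis=1)
    out = replace(epochs, data=data, times=times, srate=epochs.srate / factor, log=list(epochs.log))
    out.log.append(f"bin_time factor={factor}: {epochs.n_times} -> {n_out} samples")
    return out


def roi_average(erp: np.ndarray, channels: list[str], roi: RoiSpec) -> np.ndarray:
    """Average a channels x time ERP over the electrodes of one ROI."""
    erp = np.asarray(erp)
    if erp.ndim != 2 or erp.shape[0] != len(channels):
        raise ValueError("erp must be channels x time matching the channel list")
    unknown = [e for e in roi.electrodes if e not in channels]
    if unknown:
        raise KeyError(f"unknown electrodes {unknown}; available: {list(channels)}")
    idx = [channels.index(e) for e in roi.electrodes]
    return erp[idx].mean(axis=0)
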