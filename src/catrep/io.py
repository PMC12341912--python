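"""File I/O: HDF5 epoch interchange container, EEGLAB .set epochs, TSV tables.

The interchange container is a plain HDF5 file with datasets ``data``
(trials x channels x time, microvolts), ``times`` (ms), ``srate``,
``channels`` (UTF-8), a ``labels`` group with one dataset per label column,
and a ``schema_version`` attribute. It exists so epochs can round-trip
between runs and between languages without loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import LABEL_COLUMNS, EpochSet

SCHEMA_VERSION = "1"

_REQUIRED = ("data", "times", "srate", "channels", "labels")


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an EpochSet to the HDF5 interchange container."""
    import h5py

    str_dt = "S64"
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("data", data=epochs.data.astype(np.float64))
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("srate", data=float(epochs.srate))
        f.create_dataset("channels", data=np.array(epochs.channels, dtype=str_dt))
        g = f.create_group("labels")
        lab = epochs.labels
        g.create_dataset("task", data=lab["task"].astype(str).to_numpy(dtype=str_dt))
        g.create_dataset("category", data=lab["category"].astype(str).to_numpy(dtype=str_dt))
        # correct: 1/0, -1 for missing (no response)
        if "correct" in lab.columns:
            correct = np.array(
                [-1 if pd.isna(v) else int(bool(v)) for v in lab["correct"]], dtype=np.int8
            )
        else:
            correct = np.full(len(lab), -1, dtype=np.int8)
        g.create_dataset("correct", data=correct)
        rt = lab["rt_ms"].to_numpy(dtype=float) if "rt_ms" in lab.columns else np.full(len(lab), np.nan)
        g.create_dataset("rt_ms", data=rt)
        part = lab["participant"].astype(str) if "participant" in lab.columns else pd.Series(["0"] * len(lab))
        g.create_dataset("participant", data=part.to_numpy(dtype=str_dt))
        if epochs.veog_pair is not None:
            f.attrs["veog_pair"] = np.array(list(epochs.veog_pair), dtype=str_dt)


def read_epochs(path) -> EpochSet:
    """Read an EpochSet from the HDF5 interchange container."""
    import h5py

    with h5py.File(path, "r") as f:
        for name in _REQUIRED:
            if name not in f:
                raise ValueError(f"missing field {name}")
        data = np.asarray(f["data"], dtype=float)
        times = np.asarray(f["times"], dtype=float)
        srate = float(f["srate"][()])
        channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
        g = f["labels"]
        for col in LABEL_COLUMNS:
            if col not in g:
                raise ValueError(f"missing field labels/{col}")
        correct_raw = np.asarray(g["correct"], dtype=int)
        correct = pd.array([None if v < 0 else bool(v) for v in correct_raw], dtype="boolean")
        labels = pd.DataFrame(
            {
                "task": [v.decode() for v in g["task"][()]],
                "category": [v.decode() for v in g["category"][()]],
                "correct": correct,
                "rt_ms": np.asarray(g["rt_ms"], dtype=float),
                "participant": [v.decode() for v in g["participant"][()]],
            }
        )
        veog = None
        if "veog_pair" in f.attrs:
            veog = tuple(v.decode() if isinstance(v, bytes) else str(v) for v in f.attrs["veog_pair"])
    return EpochSet(data=data, times=times, srate=srate, channels=channels, labels=labels, veog_pair=veog)


def read_epochs_eeglab(path, task: str = "unknown") -> EpochSet:
    """Read epoched EEGLAB ``.set`` data (data + event fields only).

    Event types of the form ``"task/category"`` populate both label columns;
    any other event type becomes the category with ``task`` falling back to
    the given default. Amplitudes are returned in microvolts.
    """
    import mne

    with np.errstate(all="ignore"):
        ep = mne.io.read_epochs_eeglab(path, verbose="error")
    data = ep.get_data(copy=True) * 1e6  # volts -> microvolts
    times = ep.times * 1000.0
    inv_map = {v: k for k, v in ep.event_id.items()}
    tasks, cats = [], []
    for code in ep.events[:, 2]:
        name = inv_map.get(code, "unknown")
        if "/" in name:
            t, c = name.split("/", 1)
        else:
            t, c = task, name
        tasks.append(t)
        cats.append(c)
    labels = pd.DataFrame(
        {
            "task": tasks,
            "category": cats,
            "correct": pd.array([None] * len(tasks), dtype="boolean"),
            "rt_ms": np.nan,
            "participant": "0",
        }
    )
    return EpochSet(
        data=data,
        times=times,
        srate=float(ep.info["sfreq"]),
        channels=list(ep.ch_names),
        labels=labels,
    )


# -- behavior and template tables -------------------------------------------

BEHAVIOR_COLUMNS = ["participant", "task", "category", "response", "correct", "rt_ms"]


def write_behavior(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["correct"] = [("" if pd.isna(v) else int(bool(v))) for v in out["correct"]]
    out.to_csv(path, sep="\t", index=False)


def read_behavior(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table missing columns {missing}")
    table["correct"] = pd.array(
        [None if pd.isna(v) else bool(int(v)) for v in table["correct"]], dtype="boolean"
    )
    return table


def write_templates(templates: np.ndarray, areas: list[str], channels: list[str], path) -> None:
    """Template TSV: header of channel labels, one row per area."""
    df = pd.DataFrame(templates, index=areas, columns=channels)
    df.to_csv(path, sep="\t", index_label="area")


def read_templates(path):
    df = pd.read_csv(path, sep="\t", index_col="area")
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str))
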