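"""End-to-end pipeline: simulate -> behavior -> ERP -> decode -> TG -> RSA/MDS
-> sources, driven by one validated config with deterministic child seeds.

Every stochastic stage receives a child seed derived by hashing the master
seed with the stage name, so adding or toggling a stage never shifts another
stage's random stream, and rerunning with the same config reproduces all
outputs byte-identically. Outputs are plain TSV/JSON; a run manifest records
parameters, seeds, checksums, and wall times per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import io as cio
from ._utils import child_seed
from .cluster import cluster_permutation_test, condition_erp, differential_waveform, result_to_dict
from .decoding import decode_timecourse, shuffled_baseline, temporal_generalization
from .epochs import DEFAULT_ROIS, TASKS, RoiSpec, baseline_correct, reject_eye_epochs, roi_average
from .rsa import PAIRS, classical_mds, rdm_at_window, rdm_timecourses
from .sources import source_analysis, weights_to_pattern
from .synth import DesignSpec, GeometrySchedule, NoiseSpec, generate_dataset, generate_templates

ALL_STAGES = ("simulate", "behavior", "erp", "decode", "tgen", "rsa", "sources")

_DEFAULT_MDS_TIMES = [50, 100, 150, 200, 250, 300, 350, 400, 480]


@dataclass
class GeneratorConfig:
    n_participants: int = 5
    n_trials_per_task: int = 300
    n_channels: int = 32
    srate: float = 256.0
    effect_uv: float = 20.0
    noise_sd_uv: float = 8.0
    noise_spatial_scale: float = 0.5
    noise_pink: bool = True
    bn_onset_ms: float = 250.0
    bn_peak_ms: float = 350.0
    bn_max: float = 1.0
    cv_onset_ms: float = 120.0
    cv_peak_ms: float = 180.0
    cv_max: float = 1.0
    n_eye_artifacts: int = 0
    n_areas: int = 6


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "catrep_run"
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    folds: int = 10
    repetitions: int = 10
    n_pseudo: int = 5
    n_iterations: int = 20
    n_perm: int = 1000
    n_boot: int = 1000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    p_threshold: float = 0.005
    min_duration_ms: float = 15.0
    bin_factor: int = 4
    correct_only: bool = False
    baseline_window: list = field(default_factory=lambda: [-150.0, 0.0])
    eye_threshold_uv: float = 150.0
    mds_times: list = field(default_factory=lambda: list(_DEFAULT_MDS_TIMES))
    mds_half_width_ms: float = 15.0
    rois: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ROIS.items()})


def demo_config(seed: int = 0, out_dir: str = "catrep_demo") -> RunConfig:
    """Reduced-size configuration for a quick end-to-end run on one CPU:
    5 synthetic participants, 600 trials each, 32 channels, 200 permutations
    and bootstrap draws."""
    return validate_config(
        {
            "seed": seed,
            "out_dir": out_dir,
            "generator": {"n_participants": 5, "n_trials_per_task": 300, "n_channels": 32},
            "n_perm": 200,
            "n_boot": 200,
            "repetitions": 5,
            "n_iterations": 10,
        }
    )


def _coerce(cls, data: dict, path: str, errors: list):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"{path}{key}: unknown key")
            continue
        if key == "generator" and isinstance(value, dict):
            kwargs[key] = _coerce(GeneratorConfig, value, f"{path}generator.", errors)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path, dict, or RunConfig, filling
    defaults and rejecting unknown keys. Raises ValueError listing every
    violation with its path into the config."""
    if isinstance(source, RunConfig):
        data = dataclasses.asdict(source)
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    errors: list[str] = []
    cfg = _coerce(RunConfig, data, "", errors)
    if cfg.folds < 2:
        errors.append("folds: must be >= 2")
    if cfg.repetitions < 1:
        errors.append("repetitions: must be >= 1")
    if cfg.n_pseudo < 2:
        errors.append("n_pseudo: must be >= 2")
    if cfg.n_iterations < 1:
        errors.append("n_iterations: must be >= 1")
    for name in ("n_perm", "n_boot"):
        if getattr(cfg, name) < 1:
            errors.append(f"{name}: must be >= 1")
    for name in ("alpha", "cluster_alpha", "p_threshold"):
        if not (0 < getattr(cfg, name) < 1):
            errors.append(f"{name}: must lie in (0, 1)")
    if cfg.bin_factor < 1:
        errors.append("bin_factor: must be >= 1")
    unknown_stages = [s for s in cfg.stages if s not in ALL_STAGES]
    if unknown_stages:
        errors.append(f"stages: unknown stage(s) {unknown_stages}")
    if cfg.generator.n_participants < 2:
        errors.append("generator.n_participants: must be >= 2")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def run_pipeline(config) -> dict:
    """Execute the enabled stages in dependency order and write a manifest.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``).
    Stage dependencies: everything after ``simulate`` needs its outputs;
    ``sources`` additionally needs ``decode``.
    """
    cfg = validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    t_start = time.time()
    stages = [s for s in ALL_STAGES if s in cfg.stages]

    state: dict = {}

    def record(stage, paths, t0, **info):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "seed": child_seed(cfg.seed, stage),
            **info,
        }
        for p in paths:
            manifest["outputs"][str(Path(p).relative_to(out))] = _sha256(Path(p))

    def require(stage, dep):
        if dep not in stages:
            raise ValueError(f"stage {stage!r} requires stage {dep!r} to be enabled")

    # -- simulate -----------------------------------------------------------
    if "simulate" in stages:
        t0 = time.time()
        g = cfg.generator
        schedule = GeometrySchedule(
            bn_onset_ms=g.bn_onset_ms, bn_peak_ms=g.bn_peak_ms, bn_max=g.bn_max,
            cv_onset_ms=g.cv_onset_ms, cv_peak_ms=g.cv_peak_ms, cv_max=g.cv_max,
        )
        dataset = generate_dataset(
            g.n_participants,
            seed=child_seed(cfg.seed, "simulate"),
            design=DesignSpec(n_trials_per_task=g.n_trials_per_task),
            schedule=schedule,
            n_channels=g.n_channels,
            srate=g.srate,
            effect_uv=g.effect_uv,
            noise=NoiseSpec(sd_uv=g.noise_sd_uv, spatial_scale=g.noise_spatial_scale, pink=g.noise_pink),
            n_eye_artifacts=g.n_eye_artifacts,
        )
        templates, areas, t_channels = generate_templates(
            n_areas=g.n_areas, channels=g.n_channels, seed=child_seed(cfg.seed, "templates")
        )
        paths = []
        processed = []
        for i, (ep, gt) in enumerate(dataset):
            ep = baseline_correct(ep, tuple(cfg.baseline_window))
            ep, _ = reject_eye_epochs(ep, cfg.eye_threshold_uv)
            scalp = [k for k, ch in enumerate(ep.channels) if not ch.startswith("VEOG")]
            ep_scalp = dataclasses.replace(
                ep,
                data=ep.data[:, scalp],
                channels=[ep.channels[k] for k in scalp],
                veog_pair=None,
                log=list(ep.log),
            )
            processed.append(ep_scalp)
            p = out / f"epochs_p{i:02d}.h5"
            cio.write_epochs(ep_scalp, p)
            paths.append(p)
        behav = pd.concat(
            [ep.labels.assign(participant=str(i)) for i, ep in enumerate(processed)]
        )
        from .synth import TARGETS

        def _resp(row):
            if pd.isna(row["correct"]):
                return "none"
            is_target = row["category"] in TARGETS[row["task"]]
            return "yes" if bool(row["correct"]) == is_target else "no"

        behav["response"] = behav.apply(_resp, axis=1)
        behav = behav[["participant", "task", "category", "response", "correct", "rt_ms"]]
        bpath = out / "behavior.tsv"
        cio.write_behavior(behav.reset_index(drop=True), bpath)
        tpath = out / "templates.tsv"
        cio.write_templates(templates, areas, t_channels, tpath)
        gt_path = out / "ground_truth.json"
        _write_json(
            {
                "schedule": dataclasses.asdict(schedule),
                "effect_uv": g.effect_uv,
                "n_participants": g.n_participants,
                "pairs": [list(p) for p in PAIRS],
            },
            gt_path,
        )
        state["dataset"] = processed
        state["templates"] = (templates, areas)
        state["behavior"] = behav.reset_index(drop=True)
        record("simulate", paths + [bpath, tpath, gt_path], t0,
               n_participants=g.n_participants, n_trials=2 * g.n_trials_per_task)

    # -- behavior -----------------------------------------------------------
    if "behavior" in stages:
        require("behavior", "simulate")
        t0 = time.time()
        behav = state["behavior"]
        summaries, rates = [], []
        for pid, sub in behav.groupby("participant"):
            s = beh.behavior_summary(sub)
            s.insert(0, "participant", pid)
            summaries.append(s)
            r = beh.category_rates(sub)
            r.insert(0, "participant", pid)
            rates.append(r)
        summary = pd.concat(summaries, ignore_index=True)
        rate_table = pd.concat(rates, ignore_index=True)
        wide = summary.pivot(index="participant", columns="task", values="dprime")
        comps = beh.paired_comparisons(wide.reset_index(), [("superordinate", "basic")], family_size=3)
        p1 = out / "behavior_summary.tsv"
        p2 = out / "behavior_category_rates.tsv"
        p3 = out / "behavior_tests.json"
        _write_tsv(summary, p1)
        _write_tsv(rate_table, p2)
        _write_json([dataclasses.asdict(c) for c in comps], p3)
        record("behavior", [p1, p2, p3], t0)

    # -- ERP ---------------------------------------------------------------
    if "erp" in stages:
        require("erp", "simulate")
        t0 = time.time()
        rows = []
        diff_store = {}  # (task, pair) -> (P, T) occipital-style ROI mean diffs
        for task in TASKS:
            for pair in PAIRS:
                per_participant = []
                for ep in state["dataset"]:
                    erp_a = condition_erp(ep, {"task": task, "category": pair[0]})
                    erp_b = condition_erp(ep, {"task": task, "category": pair[1]})
                    diff = differential_waveform(erp_a, erp_b)
                    per_participant.append(diff.mean(axis=0))  # all-channel mean ROI
                diff_store[(task, pair)] = np.array(per_participant)
        times = state["dataset"][0].times
        tests = {}
        for (task, pair), arr in diff_store.items():
            res = cluster_permutation_test(
                arr, 0, n_perm=cfg.n_perm, cluster_alpha=cfg.cluster_alpha,
                alpha=cfg.alpha, seed=child_seed(cfg.seed, "erp", task, *pair),
            )
            tests[f"{task}:{'-'.join(pair)}"] = result_to_dict(res, times)
            for t_ms, val in zip(times, arr.mean(axis=0)):
                rows.append((task, "-".join(pair), t_ms, val))
        p1 = out / "erp_differentials.tsv"
        _write_tsv(pd.DataFrame(rows, columns=["task", "pair", "time_ms", "mean_diff_uv"]), p1)
        p2 = out / "erp_cluster_tests.json"
        _write_json(tests, p2)
        record("erp", [p1, p2], t0)

    # -- decoding ----------------------------------------------------------
    if "decode" in stages:
        require("decode", "simulate")
        t0 = time.time()
        acc = {}
        rows = []
        for task in TASKS:
            for pair in PAIRS:
                real = np.empty((len(state["dataset"]), state["dataset"][0].n_times))
                base = np.empty_like(real)
                for i, ep in enumerate(state["dataset"]):
                    dseed = child_seed(cfg.seed, "decode", task, *pair, i)
                    r = decode_timecourse(ep, pair, task, folds=cfg.folds,
                                          repetitions=cfg.repetitions, seed=dseed,
                                          correct_only=cfg.correct_only)
                    b = shuffled_baseline(ep, pair, task, folds=cfg.folds,
                                          repetitions=cfg.repetitions, seed=dseed,
                                          correct_only=cfg.correct_only)
                    real[i], base[i] = r.accuracy, b.accuracy
                acc[(task, pair)] = (real, base)
                times = state["dataset"][0].times
                for t_ms, a_val, b_val in zip(times, real.mean(axis=0), base.mean(axis=0)):
                    rows.append((task, "-".join(pair), t_ms, a_val, b_val))
        times = state["dataset"][0].times
        tests = {}
        for (task, pair), (real, base) in acc.items():
            res = cluster_permutation_test(
                real, base, n_perm=cfg.n_perm, cluster_alpha=cfg.cluster_alpha,
                alpha=cfg.alpha, seed=child_seed(cfg.seed, "decode-test", task, *pair),
            )
            tests[f"{task}:{'-'.join(pair)}:vs-baseline"] = result_to_dict(res, times)
        for pair in PAIRS:
            res = cluster_permutation_test(
                acc[("basic", pair)][0], acc[("superordinate", pair)][0],
                n_perm=cfg.n_perm, cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
                seed=child_seed(cfg.seed, "decode-task", *pair),
            )
            tests[f"task-effect:{'-'.join(pair)}"] = result_to_dict(res, times)
        p1 = out / "decoding.tsv"
        _write_tsv(pd.DataFrame(rows, columns=["task", "pair", "time_ms", "accuracy", "baseline"]), p1)
        p2 = out / "decoding_cluster_tests.json"
        _write_json(tests, p2)
        state["decoding"] = acc
        record("decode", [p1, p2], t0)

    # -- temporal generalization -------------------------------------------
    if "tgen" in stages:
        require("tgen", "simulate")
        t0 = time.time()
        pair = PAIRS[0]
        task = "basic"
        real = []
        base = []
        for i, ep in enumerate(state["dataset"]):
            tseed = child_seed(cfg.seed, "tgen", task, *pair, i)
            tg = temporal_generalization(ep, pair, task, bin_factor=cfg.bin_factor,
                                         folds=cfg.folds, repetitions=max(1, cfg.repetitions // 2),
                                         seed=tseed)
            bg = temporal_generalization(ep, pair, task, bin_factor=cfg.bin_factor,
                                         folds=cfg.folds, repetitions=max(1, cfg.repetitions // 2),
                                         seed=tseed, shuffle_labels=True)
            real.append(tg.accuracy)
            base.append(bg.accuracy)
        real, base = np.array(real), np.array(base)
        res = cluster_permutation_test(
            real, base, n_perm=cfg.n_perm, cluster_alpha=cfg.cluster_alpha,
            alpha=cfg.alpha, fill_holes=True, seed=child_seed(cfg.seed, "tgen-test"),
        )
        grid = pd.DataFrame(real.mean(axis=0))
        p1 = out / "tgen_matrix.tsv"
        grid.to_csv(p1, sep="\t", index=False, header=False, float_format="%.10g")
        p2 = out / "tgen_cluster_test.json"
        _write_json(result_to_dict(res), p2)
        p3 = out / "tgen_sig_mask.tsv"
        pd.DataFrame(res.mask.astype(int)).to_csv(p3, sep="\t", index=False, header=False)
        record("tgen", [p1, p2, p3], t0, pair="-".join(pair), task=task)

    # -- RSA + MDS ----------------------------------------------------------
    if "rsa" in stages:
        require("rsa", "simulate")
        t0 = time.time()
        series = {}
        rows = []
        for task in TASKS:
            per_participant = {}
            for i, ep in enumerate(state["dataset"]):
                s = rdm_timecourses(
                    ep, task, n_pseudo=cfg.n_pseudo, n_iterations=cfg.n_iterations,
                    seed=child_seed(cfg.seed, "rsa", task, i),
                )
                for pair_key, values in s.distances.items():
                    per_participant.setdefault(pair_key, []).append(values)
            series[task] = {k: np.array(v) for k, v in per_participant.items()}
            times = state["dataset"][0].times
            for pair_key, arr in series[task].items():
                for t_ms, val in zip(times, arr.mean(axis=0)):
                    rows.append((task, "-".join(pair_key), t_ms, val))
        times = state["dataset"][0].times
        tests = {}
        for task in TASKS:
            for pair_key, arr in series[task].items():
                res = cluster_permutation_test(
                    arr, 0, n_perm=cfg.n_perm, cluster_alpha=cfg.cluster_alpha,
                    alpha=cfg.alpha, seed=child_seed(cfg.seed, "rsa-test", task, *pair_key),
                )
                tests[f"{task}:{'-'.join(pair_key)}:vs-zero"] = result_to_dict(res, times)
        for pair_key in series["basic"]:
            res = cluster_permutation_test(
                series["basic"][pair_key], series["superordinate"][pair_key],
                n_perm=cfg.n_perm, cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
                seed=child_seed(cfg.seed, "rsa-task", *pair_key),
            )
            tests[f"task-effect:{'-'.join(pair_key)}"] = result_to_dict(res, times)
        p1 = out / "rdm_timecourses.tsv"
        _write_tsv(pd.DataFrame(rows, columns=["task", "pair", "time_ms", "cv_sq_distance"]), p1)
        p2 = out / "rsa_cluster_tests.json"
        _write_json(tests, p2)
        # MDS at the configured windows on the group-mean series
        from .rsa import RDMSeries

        mds_rows = []
        for task in TASKS:
            group = RDMSeries(
                times=times, task=task,
                distances={k: v.mean(axis=0) for k, v in series[task].items()},
            )
            for center in cfg.mds_times:
                dm = rdm_at_window(group, center, cfg.mds_half_width_ms)
                try:
                    coords, evals = classical_mds(dm, k=2, input_kind="squared")
                except ValueError:
                    # pure-noise window with an all-negative spectrum: no
                    # embeddable structure, plot the conditions as coincident
                    coords = np.zeros((len(dm.labels), 2))
                    evals = np.zeros(len(dm.labels))
                for lab, (x_c, y_c) in zip(dm.labels, coords):
                    mds_rows.append((task, center, lab, x_c, y_c, evals[0], evals[1], evals[-1]))
        p3 = out / "mds_coordinates.tsv"
        _write_tsv(
            pd.DataFrame(
                mds_rows,
                columns=["task", "center_ms", "category", "dim1", "dim2", "eig1", "eig2", "eig_min"],
            ),
            p3,
        )
        state["rsa"] = series
        record("rsa", [p1, p2, p3], t0)

    # -- sources ------------------------------------------------------------
    if "sources" in stages:
        require("sources", "simulate")
        require("sources", "decode")
        t0 = time.time()
        templates, areas = state["templates"]
        task, pair = "basic", PAIRS[0]
        patterns = []
        for i, ep in enumerate(state["dataset"]):
            sub = ep.where(task=task, category=tuple(pair))
            from .decoding import _batch_lda

            y01 = (sub.labels["category"] == pair[1]).to_numpy().astype(int)
            w, _, _, _, _ = _batch_lda(sub.data, y01, "auto")
            patterns.append(weights_to_pattern(w, sub.data))
        patterns = np.array(patterns)
        res = source_analysis(
            patterns, templates, areas, state["dataset"][0].times,
            srate=state["dataset"][0].srate, n_boot=cfg.n_boot,
            p_threshold=cfg.p_threshold, min_duration_ms=cfg.min_duration_ms,
            seed=child_seed(cfg.seed, "sources"),
        )
        rows = []
        for a_idx, area in enumerate(res.areas):
            for t_idx, t_ms in enumerate(res.times):
                rows.append(
                    (area, t_ms, res.contributions[a_idx, t_idx], res.z[a_idx, t_idx],
                     res.p[a_idx, t_idx], int(res.mask[a_idx, t_idx]))
                )
        p1 = out / "source_timecourses.tsv"
        _write_tsv(pd.DataFrame(rows, columns=["area", "time_ms", "contribution", "z", "p", "significant"]), p1)
        p2 = out / "source_meta.json"
        _write_json({"params": res.params, "areas": res.areas, "task": task, "pair": list(pair)}, p2)
        record("sources", [p1, p2], t0, task=task, pair="-".join(pair))

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    manifest["config"] = dataclasses.asdict(cfg)
    _write_json(manifest, out / "manifest.json")
    return manifest
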