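"""Synthetic data with known ground truth: behavior, EEG epochs, templates.

The generator emulates a two-task category-judgment experiment: blocks of
superordinate (animal / non-animal) and basic-level (bird / non-bird)
decisions on briefly flashed images of birds, non-bird animals, and
vehicles. Behavior comes from a drift-diffusion model per task x category;
EEG epochs are built from category-specific spatiotemporal patterns whose
pairwise separations follow a declared per-task time schedule, embedded in
spatially correlated (optionally 1/f-colored) noise. Everything is seeded
and a :class:`GroundTruth` record suffices to recompute every planted
quantity, so downstream stages have genuine parameter-recovery tests.

The default geometry encodes the hypothesized task effect: the bird vs
non-bird separation is absent in the superordinate task and ramps up from
250 to 350 ms in the basic task, while both categories' separation from
vehicles is identical across tasks and present from ~120 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import child_seed, ring_distance
from .epochs import CATEGORIES, TASKS, EpochSet

#: categories answered "yes" in each task
TARGETS = {"superordinate": ("bird", "nonbird_animal"), "basic": ("bird",)}


# ---------------------------------------------------------------------------
# drift-diffusion behavior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DDMParams:
    """Accuracy-coded drift-diffusion parameters.

    a : boundary separation (evidence units); upper boundary = correct.
    v : drift rate (evidence / s).
    t : non-decision time (s).
    s : within-trial diffusion coefficient (evidence / sqrt(s)); fixed
        scaling constant, 1 by convention.
    z_rel : relative start point in (0, 1).
    """

    a: float
    v: float
    t: float
    s: float = 1.0
    z_rel: float = 0.5

    def __post_init__(self):
        vals = (self.a, self.v, self.t, self.s, self.z_rel)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("DDM parameters must be finite")
        if self.a <= 0 or self.t < 0 or self.s <= 0 or not (0 < self.z_rel < 1):
            raise ValueError("require a > 0, t >= 0, s > 0, 0 < z_rel < 1")


def simulate_ddm(
    params: DDMParams,
    n_trials: int,
    dt_s: float = 5e-4,
    max_t_s: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate first-passage trials of the accuracy-coded diffusion model.

    Euler–Maruyama integration of dX = v dt + s sqrt(dt) N(0,1) from
    ``z_rel * a`` until absorption at 0 or ``a``; the crossing time is
    linearly interpolated within the crossing step. A Brownian-bridge
    correction additionally absorbs paths that cross a boundary *within* a
    step but end it inside the interval (probability
    exp(−2 (b−x0)(b−x1) / (s² dt))), removing the O(sqrt(dt)) bias of the
    naive scheme. Upper crossings are correct. RT = t + first-passage time;
    trials whose RT would exceed ``max_t_s`` (or that never cross) are
    marked no-response.

    Returns a DataFrame with columns ``correct`` (nullable boolean) and
    ``rt_ms`` (NaN when no response).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(max_t_s / dt_s))
    x = np.full(n_trials, params.z_rel * params.a)
    fpt = np.full(n_trials, np.nan)
    upper = np.zeros(n_trials, dtype=bool)
    active = np.ones(n_trials, dtype=bool)
    sq = params.s * np.sqrt(dt_s)
    for step in range(n_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        prev = x[idx]
        nxt = prev + params.v * dt_s + sq * rng.standard_normal(idx.size)
        hi = nxt >= params.a
        lo = nxt <= 0.0
        inside = ~(hi | lo)
        # Brownian-bridge probability of an unobserved within-step crossing
        if np.any(inside):
            p_hi = np.exp(-2.0 * (params.a - prev[inside]) * (params.a - nxt[inside]) / (params.s**2 * dt_s))
            p_lo = np.exp(-2.0 * prev[inside] * nxt[inside] / (params.s**2 * dt_s))
            u = rng.random(int(inside.sum()))
            bridge_hi = u < p_hi
            bridge_lo = ~bridge_hi & (u < p_hi + p_lo)
            hi[inside] |= bridge_hi
            lo[inside] |= bridge_lo
        crossed = hi | lo
        if np.any(crossed):
            ci = idx[crossed]
            bound = np.where(hi[crossed], params.a, 0.0)
            denom = nxt[crossed] - prev[crossed]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(denom != 0, (bound - prev[crossed]) / denom, 0.5)
            frac = np.clip(frac, 0.0, 1.0)
            fpt[ci] = (step + frac) * dt_s
            upper[ci] = hi[crossed]
            active[ci] = False
        x[idx] = nxt
    rt_s = params.t + fpt
    responded = np.isfinite(rt_s) & (rt_s <= max_t_s)
    correct = pd.array([bool(u) if r else None for u, r in zip(upper, responded)], dtype="boolean")
    rt_ms = np.where(responded, rt_s * 1000.0, np.nan)
    return pd.DataFrame({"correct": correct, "rt_ms": rt_ms})


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Trial counts and category mixes of the two-task design.

    The study design is 10 blocks of 200 trials, 5 blocks per task; the
    superordinate blocks show 25% birds, 25% non-bird animals, 50% vehicles,
    and the basic blocks 50% birds, 25% non-bird animals, 25% vehicles.
    """

    n_trials_per_task: int = 1000
    proportions: dict = field(
        default_factory=lambda: {
            "superordinate": {"bird": 0.25, "nonbird_animal": 0.25, "vehicle": 0.50},
            "basic": {"bird": 0.50, "nonbird_animal": 0.25, "vehicle": 0.25},
        }
    )

    def counts(self, task: str) -> dict:
        props = self.proportions[task]
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError(f"category proportions for {task!r} must sum to 1")
        counts = {c: int(round(p * self.n_trials_per_task)) for c, p in props.items()}
        drift = self.n_trials_per_task - sum(counts.values())
        if drift:  # assign rounding remainder to the largest category
            counts[max(counts, key=counts.get)] += drift
        return counts


def default_ddm_params() -> dict:
    """Per task x category DDM parameters.

    The paper reports its fitted magnitudes only graphically, so these are
    arbitrary-but-plausible values producing high accuracy and RTs in the
    0.4–0.7 s range, with the qualitative structure the study found: drift
    is lower at the basic level for bird and non-bird animal, higher for
    vehicle; boundary is task-invariant; non-decision time is slightly
    longer for basic-level non-bird animals.
    """
    return {
        ("superordinate", "bird"): DDMParams(a=1.4, v=3.0, t=0.30),
        ("superordinate", "nonbird_animal"): DDMParams(a=1.4, v=3.0, t=0.30),
        ("superordinate", "vehicle"): DDMParams(a=1.4, v=2.5, t=0.30),
        ("basic", "bird"): DDMParams(a=1.4, v=2.2, t=0.30),
        ("basic", "nonbird_animal"): DDMParams(a=1.4, v=1.8, t=0.33),
        ("basic", "vehicle"): DDMParams(a=1.4, v=3.0, t=0.30),
    }


def generate_behavior(
    design: DesignSpec | None = None,
    ddm_params: dict | None = None,
    seed: int = 0,
    participant: str = "0",
    dt_s: float = 5e-4,
    max_t_s: float = 2.0,
) -> pd.DataFrame:
    """Simulate the full behavioral session: one row per trial.

    Responses are recoded from the accuracy-coded DDM using each task's
    target categories (yes = target present). Trial order is shuffled
    within task.
    """
    design = design or DesignSpec()
    ddm_params = ddm_params or default_ddm_params()
    rows = []
    for task in TASKS:
        counts = design.counts(task)
        for category in CATEGORIES:
            n = counts.get(category, 0)
            if n == 0:
                continue
            sim = simulate_ddm(
                ddm_params[(task, category)],
                n,
                dt_s=dt_s,
                max_t_s=max_t_s,
                seed=child_seed(seed, "ddm", task, category),
            )
            is_target = category in TARGETS[task]
            for correct, rt in zip(sim["correct"], sim["rt_ms"]):
                if pd.isna(correct):
                    response = "none"
                elif bool(correct) == is_target:
                    response = "yes"
                else:
                    response = "no"
                rows.append((participant, task, category, response, correct, rt))
    table = pd.DataFrame(rows, columns=["participant", "task", "category", "response", "correct", "rt_ms"])
    table["correct"] = table["correct"].astype("boolean")
    rng = np.random.default_rng(child_seed(seed, "shuffle"))
    order = np.concatenate(
        [rng.permutation(np.flatnonzero((table["task"] == task).to_numpy())) for task in TASKS]
    )
    return table.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# geometry schedule and EEG epochs
# ---------------------------------------------------------------------------


def design_labels(
    design: DesignSpec | None = None,
    seed: int = 0,
    participant: str = "0",
) -> pd.DataFrame:
    """Trial labels with the design's task/category structure but no
    simulated responses (all correct, fixed RT). Useful when only the EEG
    path is exercised and the diffusion simulation would be wasted work."""
    design = design or DesignSpec()
    rows = []
    for task in TASKS:
        for category, n in design.counts(task).items():
            rows.extend([(participant, task, category)] * n)
    table = pd.DataFrame(rows, columns=["participant", "task", "category"])
    table["response"] = "yes"
    table["correct"] = pd.array([True] * len(table), dtype="boolean")
    table["rt_ms"] = 500.0
    rng = np.random.default_rng(child_seed(seed, "shuffle"))
    order = np.concatenate(
        [rng.permutation(np.flatnonzero((table["task"] == task).to_numpy())) for task in TASKS]
    )
    return table.iloc[order].reset_index(drop=True)


def _ramp(t: np.ndarray, start_ms: float, end_ms: float) -> np.ndarray:
    """Linear 0 -> 1 ramp between the two breakpoints, clipped outside."""
    if end_ms <= start_ms:
        return (t >= start_ms).astype(float)
    return np.clip((t - start_ms) / (end_ms - start_ms), 0.0, 1.0)


@dataclass(frozen=True)
class GeometrySchedule:
    """Latent category geometry over time, per task.

    ``d_bn(task, times)`` and ``d_cv(times)`` give the bird vs non-bird and
    category vs vehicle separations (latent units). Latent means place the
    three categories on an isoceles triangle: vehicle at the origin, bird
    and non-bird symmetric about the first axis, so the declared pairwise
    distances are Euclidean by construction (symmetric, triangle
    inequality).
    """

    latent_dim: int = 2
    bn_onset_ms: float = 250.0
    bn_peak_ms: float = 350.0
    bn_max: float = 1.0
    cv_onset_ms: float = 120.0
    cv_peak_ms: float = 180.0
    cv_max: float = 1.0
    bn_in_superordinate: bool = False

    def __post_init__(self):
        if self.bn_max > 2 * self.cv_max:
            raise ValueError("bird-nonbird separation cannot exceed twice the vehicle separation")

    def d_bn(self, task: str, times_ms: np.ndarray) -> np.ndarray:
        r = _ramp(np.asarray(times_ms, float), self.bn_onset_ms, self.bn_peak_ms) * self.bn_max
        if task == "superordinate" and not self.bn_in_superordinate:
            return np.zeros_like(r)
        return r

    def d_cv(self, times_ms: np.ndarray) -> np.ndarray:
        return _ramp(np.asarray(times_ms, float), self.cv_onset_ms, self.cv_peak_ms) * self.cv_max

    def latent_means(self, task: str, times_ms: np.ndarray) -> dict:
        """dict category -> (latent_dim, T) latent mean time courses."""
        t = np.asarray(times_ms, float)
        h = self.d_bn(task, t) / 2.0
        d_cv = self.d_cv(t)
        x = np.sqrt(np.maximum(d_cv**2 - h**2, 0.0))
        zeros = np.zeros_like(t)
        means = {
            "vehicle": np.stack([zeros, zeros]),
            "bird": np.stack([x, h]),
            "nonbird_animal": np.stack([x, -h]),
        }
        if self.latent_dim > 2:
            pad = np.zeros((self.latent_dim - 2, t.size))
            means = {k: np.vstack([v, pad]) for k, v in means.items()}
        return means

    def pair_distance(self, task: str, pair: tuple[str, str], times_ms: np.ndarray) -> np.ndarray:
        m = self.latent_means(task, times_ms)
        return np.linalg.norm(m[pair[0]] - m[pair[1]], axis=0)


def zero_schedule() -> GeometrySchedule:
    """Null schedule: all category separations are 0 at every timepoint."""
    return GeometrySchedule(bn_max=0.0, cv_max=0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for synthetic epochs.

    sd_uv : per-channel noise SD in microvolts.
    spatial_scale : e-folding angular distance (radians) of the exponential
        spatial correlation over the ring channel layout; 0 = white.
    pink : apply 1/f temporal coloring (marginal variance kept at sd_uv^2).
    """

    sd_uv: float = 8.0
    spatial_scale: float = 0.5
    pink: bool = True
    pink_exponent: float = 1.0


PAIRS = (("bird", "nonbird_animal"), ("nonbird_animal", "vehicle"), ("bird", "vehicle"))


@dataclass
class GroundTruth:
    """Everything needed to recompute the planted quantities exactly."""

    mixing: np.ndarray  # channels x latent_dim, includes effect_uv scaling
    schedule: GeometrySchedule
    effect_uv: float
    noise: NoiseSpec
    times: np.ndarray
    latent_means: dict  # (task, category) -> (latent_dim, T)
    channel_sq_distances: dict  # (task, pair) -> (T,) squared channel-space separations
    ddm_params: dict | None
    artifact_trials: np.ndarray
    seed: int = 0


def generate_epochs(
    design: DesignSpec | None = None,
    schedule: GeometrySchedule | None = None,
    n_channels: int = 32,
    srate: float = 256.0,
    tmin_ms: float = -150.0,
    tmax_ms: float = 500.0,
    effect_uv: float = 20.0,
    noise: NoiseSpec | None = None,
    behavior: pd.DataFrame | None = None,
    ddm_params: dict | None = None,
    n_eye_artifacts: int = 0,
    participant: str = "0",
    simulate_responses: bool = True,
    mixing_seed: int | None = None,
    mixing: np.ndarray | None = None,
    seed: int = 0,
):
    """Generate a full epoched session plus its :class:`GroundTruth`.

    Each trial is ``effect_uv * M @ latent_mean(task, category, t)`` plus
    spatially correlated noise (independent across trials); ``M`` has
    orthonormal columns, so channel-space separations equal ``effect_uv``
    times the latent separations. Two extra vertical-EOG channels carry
    independent noise; ``n_eye_artifacts`` trials get a planted
    super-threshold EOG deflection. When no behavior table is supplied one
    is simulated from ``ddm_params`` and aligned trial-for-trial.
    """
    design = design or DesignSpec()
    schedule = schedule or GeometrySchedule()
    noise = noise or NoiseSpec()
    if behavior is None:
        if simulate_responses:
            ddm_params = ddm_params or default_ddm_params()
            behavior = generate_behavior(
                design, ddm_params, seed=child_seed(seed, "behavior"), participant=participant
            )
        else:
            behavior = design_labels(design, seed=child_seed(seed, "behavior"), participant=participant)
    n_trials = len(behavior)
    step = 1000.0 / srate
    times = tmin_ms + step * np.arange(int(np.floor((tmax_ms - tmin_ms) / step)) + 1)
    n_t = times.size
    rng = np.random.default_rng(child_seed(seed, "epochs"))

    # spatially correlated noise over a ring layout
    if noise.spatial_scale > 0:
        cov = np.exp(-ring_distance(n_channels) / noise.spatial_scale)
    else:
        cov = np.eye(n_channels)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_channels))

    # mixing: the planted separations are defined in noise-whitened
    # (discriminability) units, so the latent axes are mapped through
    # Sigma^(1/2) Q with Q orthonormal — after multivariate noise
    # normalization the measured separations equal the scheduled ones
    # regardless of direction, which keeps "equal across tasks" contrasts
    # genuinely null under correlated noise. A separate mixing_seed lets a
    # group of participants share one scalp projection (common anatomy,
    # independent noise); an explicit mixing matrix is used verbatim (after
    # orthonormalization) to plant signal in known, e.g. template, subspaces.
    if mixing is not None:
        mixing = np.asarray(mixing, dtype=float)
        if mixing.shape != (n_channels, schedule.latent_dim):
            raise ValueError(
                f"mixing must be {(n_channels, schedule.latent_dim)}, got {mixing.shape}"
            )
        q, _ = np.linalg.qr(mixing)
        mixing = q[:, : schedule.latent_dim]
    else:
        rng_mix = np.random.default_rng(
            child_seed(seed if mixing_seed is None else mixing_seed, "mixing")
        )
        g = rng_mix.standard_normal((n_channels, schedule.latent_dim))
        q, _ = np.linalg.qr(g)
        mixing = chol @ q[:, : schedule.latent_dim]

    latent = {
        (task, cat): schedule.latent_means(task, times)[cat]
        for task in TASKS
        for cat in CATEGORIES
    }
    signal = {key: effect_uv * mixing @ m for key, m in latent.items()}  # (C, T)

    def draw_noise(n, channels):
        white = rng.standard_normal((n, channels, n_t))
        if noise.pink:
            freqs = np.fft.rfftfreq(n_t, d=1.0 / srate)
            amp = np.ones_like(freqs)
            amp[1:] = freqs[1:] ** (-noise.pink_exponent / 2.0)
            amp[0] = amp[1]
            spec = np.fft.rfft(white, axis=2) * amp
            colored = np.fft.irfft(spec, n=n_t, axis=2)
            std = colored.std()  # restore unit marginal variance after coloring
            white = colored / std if std > 0 else colored
        return noise.sd_uv * white

    scalp_noise = np.einsum("cd,ndt->nct", chol, draw_noise(n_trials, n_channels))
    data = np.empty((n_trials, n_channels + 2, n_t))
    for i, (task, cat) in enumerate(zip(behavior["task"], behavior["category"])):
        data[i, :n_channels] = signal[(task, cat)] + scalp_noise[i]
    # vertical EOG pair: independent noise, plus planted blink artifacts
    data[:, n_channels:] = draw_noise(n_trials, 2) * 2.0
    artifact_trials = np.array([], dtype=int)
    if n_eye_artifacts > 0:
        artifact_trials = np.sort(
            rng.choice(n_trials, size=min(n_eye_artifacts, n_trials), replace=False)
        )
        blink = 400.0 * np.exp(-0.5 * ((times - 200.0) / 40.0) ** 2)
        data[artifact_trials, n_channels, :] += blink

    channels = [f"C{i + 1:02d}" for i in range(n_channels)] + ["VEOG_UP", "VEOG_LO"]
    labels = behavior[["task", "category", "correct", "rt_ms", "participant"]].copy()
    epochs = EpochSet(
        data=data,
        times=times,
        srate=srate,
        channels=channels,
        labels=labels,
        veog_pair=("VEOG_UP", "VEOG_LO"),
    )
    truth = GroundTruth(
        mixing=effect_uv * mixing,
        schedule=schedule,
        effect_uv=effect_uv,
        noise=noise,
        times=times,
        latent_means=latent,
        channel_sq_distances={
            (task, pair): np.sum(
                (signal[(task, pair[0])] - signal[(task, pair[1])]) ** 2, axis=0
            )
            for task in TASKS
            for pair in PAIRS
        },
        ddm_params=ddm_params,
        artifact_trials=artifact_trials,
        seed=seed,
    )
    return epochs, truth


def generate_dataset(
    n_participants: int,
    seed: int = 0,
    scalp_only: bool = False,
    shared_mixing: bool = True,
    **kwargs,
):
    """List of seeded (EpochSet, GroundTruth) pairs, one synthetic
    participant each — the units of analysis for group-level tests.

    With ``shared_mixing`` the whole group uses one scalp projection
    (common anatomy — required for group-level source analysis, where
    per-participant projections would cancel in the average). With
    ``shared_mixing=False`` each participant draws an independent
    projection, making any direction-dependent measurement residue
    exchangeable across participants.
    """
    if shared_mixing:
        kwargs.setdefault("mixing_seed", child_seed(seed, "group-mixing"))
    out = []
    for p in range(n_participants):
        ep, gt = generate_epochs(
            participant=str(p), seed=child_seed(seed, "participant", p), **kwargs
        )
        if scalp_only:
            keep = [i for i, ch in enumerate(ep.channels) if not ch.startswith("VEOG")]
            ep = EpochSet(
                data=ep.data[:, keep],
                times=ep.times,
                srate=ep.srate,
                channels=[ep.channels[i] for i in keep],
                labels=ep.labels,
            )
        out.append((ep, gt))
    return out


# ---------------------------------------------------------------------------
# posterior samples and source templates
# ---------------------------------------------------------------------------


def generate_posterior_samples(
    true_params: dict,
    spread: float | dict = 0.05,
    n_samples: int = 2000,
    seed: int = 0,
) -> dict:
    """Fabricate Gaussian 'posterior' sample chains centered on true values.

    ``true_params`` maps (task, category) -> DDMParams; ``spread`` is the
    posterior SD, either a scalar or a dict per parameter name. Returns
    {(task, category, param): samples} for params a, v, t.
    """
    if isinstance(spread, dict):
        sds = {k: float(v) for k, v in spread.items()}
    else:
        sds = {p: float(spread) for p in ("a", "v", "t")}
    if any(v <= 0 for v in sds.values()):
        raise ValueError("spread must be > 0")
    out = {}
    for (task, cat), params in true_params.items():
        for name in ("a", "v", "t"):
            rng = np.random.default_rng(child_seed(seed, "posterior", task, cat, name))
            out[(task, cat, name)] = getattr(params, name) + sds[name] * rng.standard_normal(n_samples)
    return out


def generate_templates(
    n_areas: int = 6,
    channels: int | list[str] = 32,
    smoothness: float = 0.35,
    seed: int = 0,
    max_tries: int = 50,
    max_abs_cos: float = 0.95,
):
    """Smooth, unit-norm, mutually distinguishable area topographies.

    Each area is a Gaussian bump of angular width ``smoothness`` (radians)
    at a random position on the ring layout, plus a little smooth
    variability. Rows are renormalized; generation retries until all
    pairwise |cosine| < ``max_abs_cos``.

    Returns (templates areas x channels, area names, channel names).
    """
    if n_areas < 2:
        raise ValueError("n_areas must be >= 2")
    if isinstance(channels, int):
        ch_names = [f"C{i + 1:02d}" for i in range(channels)]
    else:
        ch_names = list(channels)
    n_ch = len(ch_names)
    theta = 2 * np.pi * np.arange(n_ch) / n_ch
    for attempt in range(max_tries):
        rng = np.random.default_rng(child_seed(seed, "templates", attempt))
        centers = rng.uniform(0, 2 * np.pi, size=n_areas)
        rows = []
        for mu in centers:
            d = np.abs(theta - mu)
            d = np.minimum(d, 2 * np.pi - d)
            bump = np.exp(-0.5 * (d / smoothness) ** 2)
            k = min(5, n_ch)
            bump += 0.1 * np.convolve(rng.standard_normal(n_ch), np.ones(k) / k, mode="same")[:n_ch]
            rows.append(bump / np.linalg.norm(bump))
        t = np.array(rows)
        gram = np.abs(t @ t.T - np.eye(n_areas))
        if gram.max() < max_abs_cos:
            areas = [f"area{i + 1}" for i in range(n_areas)]
            return t, areas, ch_names
    raise RuntimeError(
        f"could not draw {n_areas} templates with pairwise |cos| < {max_abs_cos} in "
        f"{max_tries} tries; increase the number of channels or smoothness"
    )
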