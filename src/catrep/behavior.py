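"""Behavioral scoring: trial filters, corrected d-prime, paired comparisons,
and the Bayesian posterior-overlap probability used for DDM contrasts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import TARGETS


def filter_trials(table: pd.DataFrame, min_rt_ms: float = 200.0, include=("anticipatory", "no_response")):
    """Apply the standard behavioral exclusions.

    Removes anticipatory responses (RT below ``min_rt_ms``) and no-response
    trials (``response == 'none'``). Retained rows are unchanged. Returns
    (filtered table, counts removed per reason).
    """
    rt = table["rt_ms"].to_numpy(dtype=float)
    no_response = (table["response"] == "none").to_numpy()
    anticipatory = ~no_response & (rt < min_rt_ms)
    drop = np.zeros(len(table), dtype=bool)
    counts = {}
    if "no_response" in include:
        drop |= no_response
        counts["no_response"] = int(no_response.sum())
    if "anticipatory" in include:
        drop |= anticipatory
        counts["anticipatory"] = int(anticipatory.sum())
    return table.loc[~drop].reset_index(drop=True), counts


def dprime_corrected(hits: int, misses: int, false_alarms: int, correct_rejections: int) -> float:
    """Signal-detection d' with the log-linear correction for extreme rates.

    0.5 is added to every cell and 1 to every denominator before the rates
    are computed, so the statistic stays finite at 0% or 100% performance:
    d' = Phi^-1((hits+.5)/(hits+misses+1)) - Phi^-1((fa+.5)/(fa+cr+1)).
    """
    counts = (hits, misses, false_alarms, correct_rejections)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    n_signal = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need at least one signal trial and one noise trial")
    h = (hits + 0.5) / (n_signal + 1)
    fa = (false_alarms + 0.5) / (n_noise + 1)
    return float(stats.norm.ppf(h) - stats.norm.ppf(fa))


@dataclass
class ComparisonResult:
    """One paired contrast: estimates, t, Cohen's d, raw and corrected p."""

    label: str
    estimate_a: float
    estimate_b: float
    difference: float
    statistic: float
    df: int
    cohens_d: float
    p_raw: float
    p_corrected: float
    correction: str = "bonferroni"
    family_size: int = 1
    overlap_probability: float | None = None

    def __post_init__(self):
        assert self.p_corrected >= self.p_raw - 1e-15 and self.p_corrected <= 1.0


def paired_comparisons(values: pd.DataFrame, pairs: list[tuple[str, str]], family_size: int | None = None):
    """Two-sided paired t-tests with Bonferroni correction.

    ``values`` is participants x conditions (columns are condition names);
    ``pairs`` lists the (a, b) column contrasts. ``family_size`` defaults to
    the number of pairs (the study used a family of 3). Cohen's d is the
    paired-data version, mean(diff) / sd(diff).
    """
    if family_size is None:
        family_size = len(pairs)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 participants for a paired test")
    results = []
    tiny = np.finfo(float).tiny
    for a, b in pairs:
        da = values[a].to_numpy(dtype=float)
        db = values[b].to_numpy(dtype=float)
        diff = da - db
        sd = diff.std(ddof=1)
        if sd == 0.0:
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:  # constant nonzero difference: infinite t, p below machine floor
                t, p = np.inf * np.sign(diff.mean()), tiny
            d = np.inf * np.sign(diff.mean()) if diff.mean() != 0 else 0.0
        else:
            res = stats.ttest_rel(da, db)
            t, p = float(res.statistic), float(res.pvalue)
            d = float(diff.mean() / sd)
        results.append(
            ComparisonResult(
                label=f"{a} vs {b}",
                estimate_a=float(da.mean()),
                estimate_b=float(db.mean()),
                difference=float(diff.mean()),
                statistic=t,
                df=n - 1,
                cohens_d=d,
                p_raw=p,
                p_corrected=min(1.0, p * family_size),
                family_size=family_size,
            )
        )
    return results


def posterior_overlap_probability(samples_a, samples_b) -> float:
    """P(a > b) over posterior draws, the Bayesian overlap statistic.

    With equal-length chains the draws are compared index-paired (preserving
    MCMC dependence); otherwise the full cross-product is used. Ties count
    0.5. P = 0.5 means full overlap; P near 0 or 1 means separation.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("posterior sample arrays must be nonempty")
    if a.size == b.size:
        return float(np.mean(a > b) + 0.5 * np.mean(a == b))
    # cross-product via sorting: count of b-draws below each a-draw
    bs = np.sort(b)
    lower = np.searchsorted(bs, a, side="left")
    upper = np.searchsorted(bs, a, side="right")
    return float((lower.sum() + 0.5 * (upper - lower).sum()) / (a.size * b.size))


# ---------------------------------------------------------------------------
# session-level summaries
# ---------------------------------------------------------------------------


def task_signal_counts(table: pd.DataFrame, task: str) -> dict:
    """Hit/miss/false-alarm/correct-rejection counts for one task, with the
    task's target categories as 'signal' and yes-responses as detections."""
    sub = table[(table["task"] == task) & (table["response"] != "none")]
    is_target = sub["category"].isin(TARGETS[task]).to_numpy()
    said_yes = (sub["response"] == "yes").to_numpy()
    return {
        "hits": int(np.sum(is_target & said_yes)),
        "misses": int(np.sum(is_target & ~said_yes)),
        "false_alarms": int(np.sum(~is_target & said_yes)),
        "correct_rejections": int(np.sum(~is_target & ~said_yes)),
    }


def behavior_summary(table: pd.DataFrame, min_rt_ms: float = 200.0) -> pd.DataFrame:
    """Per task: corrected d' and mean/median RT of correct responses,
    after the standard exclusions. One row per task."""
    filtered, _ = filter_trials(table, min_rt_ms=min_rt_ms)
    rows = []
    for task in filtered["task"].unique():
        counts = task_signal_counts(filtered, task)
        correct_rt = filtered[
            (filtered["task"] == task) & (filtered["correct"] == True)  # noqa: E712
        ]["rt_ms"]
        rows.append(
            {
                "task": task,
                "dprime": dprime_corrected(**counts),
                "mean_rt_ms": float(correct_rt.mean()),
                "median_rt_ms": float(correct_rt.median()),
                **counts,
            }
        )
    return pd.DataFrame(rows)


def category_rates(table: pd.DataFrame, min_rt_ms: float = 200.0) -> pd.DataFrame:
    """Per task x category response rates.

    For target categories the 'hit rate' is the yes-rate; for distractor
    categories both readings reported in the literature are exposed: the
    yes-rate (false-alarm style) and the correct-rejection rate. Mean RT of
    correct responses is included.
    """
    filtered, _ = filter_trials(table, min_rt_ms=min_rt_ms)
    rows = []
    for (task, category), sub in filtered.groupby(["task", "category"], sort=True):
        yes_rate = float((sub["response"] == "yes").mean())
        is_target = category in TARGETS[task]
        correct_rt = sub[sub["correct"] == True]["rt_ms"]  # noqa: E712
        rows.append(
            {
                "task": task,
                "category": category,
                "is_target": is_target,
                "yes_rate": yes_rate,
                "hit_rate": yes_rate if is_target else np.nan,
                "correct_rejection_rate": np.nan if is_target else 1.0 - yes_rate,
                "accuracy": float((sub["correct"] == True).mean()),  # noqa: E712
                "mean_rt_correct_ms": float(correct_rt.mean()) if len(correct_rt) else np.nan,
            }
        )
    return pd.DataFrame(rows)
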