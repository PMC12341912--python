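"""Template-based functional source analysis of classifier weights.

Linear classifier weights are not directly interpretable as neural sources;
the forward-model (Haufe) transform converts them into activation patterns,
pattern = Σ_x w / var(w·x), which for LDA equal the ERP difference between
the two decoded conditions. Pattern topographies are then expressed, per
timepoint, as a simultaneous least-squares combination of per-area EEG
templates, giving each area a contribution time course. Significance is
assessed against a sign-flip bootstrap null (randomly flipping each
participant's pattern), summarized by a Gaussian z per area and timepoint,
converted to p = 2·(1 − Φ(|z|)), and thresholded at p < 0.005 sustained for
at least 15 consecutive milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import child_seed


@dataclass
class SourceTimecourses:
    """Per-area contributions with bootstrap null statistics."""

    areas: list[str]
    times: np.ndarray
    contributions: np.ndarray  # (A, T) observed coefficients
    null_mean: np.ndarray  # (A, T)
    null_sd: np.ndarray  # (A, T)
    z: np.ndarray  # (A, T)
    p: np.ndarray  # (A, T)
    mask: np.ndarray  # (A, T) significance after the consecutive-ms rule
    params: dict = field(default_factory=dict)


def weights_to_pattern(weights: np.ndarray, data) -> np.ndarray:
    """Haufe transform: classifier weights -> activation pattern.

    ``weights`` is (T, C) (or (C,) for a single timepoint) and ``data`` an
    EpochSet or (n, C, T) array of the trials the classifiers saw. Per
    timepoint, pattern = Σ_x w / var(w·x) with Σ_x the empirical data
    covariance, normalizing so the pattern is in data units per unit
    decision value. Returns (C, T) (or (C,)).
    """
    x = data.data if hasattr(data, "channels") else np.asarray(data, dtype=float)
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    single = np.asarray(weights).ndim == 1
    if single:
        if x.ndim == 2:
            x = x[:, :, None]
    n, c, t = x.shape
    if w.shape != (t, c):
        raise ValueError(f"weights shape {w.shape} does not match data (T={t}, C={c})")
    centered = x - x.mean(axis=0, keepdims=True)
    # s_t = Sigma_x(t) @ w_t, computed without forming Sigma explicitly
    proj = np.einsum("tc,nct->nt", w, centered, optimize=True)  # decision values
    s = np.einsum("nct,nt->ct", centered, proj, optimize=True) / (n - 1)
    var = np.einsum("nt,nt->t", proj, proj) / (n - 1)
    if np.any(var <= 0):
        raise ValueError("decision-value variance is zero at some timepoint")
    pattern = s / var
    return pattern[:, 0] if single else pattern


def localize_templates(patterns: np.ndarray, templates: np.ndarray):
    """Simultaneous least-squares fit of pattern topographies to area templates.

    ``patterns`` is (C, T) (or (C,)); ``templates`` is (A, C). Per timepoint
    the pattern is modeled as templates.T @ coeffs; returns
    (coefficients (A, T), residual_fraction (T,)), the latter being the
    fraction of squared pattern norm unexplained by the fit.
    """
    templates = np.asarray(templates, dtype=float)
    p = np.asarray(patterns, dtype=float)
    single = p.ndim == 1
    p = p[:, None] if single else p
    a, c = templates.shape
    if p.shape[0] != c:
        raise ValueError(f"pattern has {p.shape[0]} channels, templates have {c}")
    rank = np.linalg.matrix_rank(templates)
    if rank < a:
        gram = templates @ templates.T
        norms = np.sqrt(np.diag(gram))
        cos = gram / np.outer(norms, norms)
        pairs = [
            (i, j)
            for i in range(a)
            for j in range(i + 1, a)
            if abs(cos[i, j]) > 0.999
        ]
        raise ValueError(f"template matrix is rank deficient (rank {rank} < {a}); collinear area pairs: {pairs}")
    coeffs, _, _, _ = np.linalg.lstsq(templates.T, p, rcond=None)
    fitted = templates.T @ coeffs
    denom = np.sum(p**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        residual_fraction = np.where(denom > 0, np.sum((p - fitted) ** 2, axis=0) / denom, 0.0)
    if single:
        return coeffs[:, 0], float(residual_fraction[0])
    return coeffs, residual_fraction


def group_pattern(patterns: np.ndarray, normalize: bool = True, signs=None) -> np.ndarray:
    """Group-mean pattern over participants (P, C, T), optionally after
    normalizing each participant to unit Frobenius norm so none dominates."""
    p = np.asarray(patterns, dtype=float)
    if normalize:
        norms = np.sqrt(np.sum(p**2, axis=(1, 2), keepdims=True))
        norms = np.where(norms > 0, norms, 1.0)
        p = p / norms
    if signs is not None:
        p = p * np.asarray(signs, dtype=float)[:, None, None]
    return p.mean(axis=0)


def signflip_bootstrap_null(
    patterns: np.ndarray,
    templates: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    normalize: bool = True,
) -> np.ndarray:
    """Bootstrap null of area coefficients under random participant sign flips.

    Each draw flips the sign of each participant's whole pattern with
    probability 0.5 (the flip unit is the participant, keeping temporal
    structure intact), recomputes the group-mean pattern and its template
    coefficients. Because localization is linear, per-participant
    coefficients are computed once and recombined. Returns
    (n_boot, A, T) null coefficients.
    """
    p = np.asarray(patterns, dtype=float)
    if p.ndim != 3 or p.shape[0] < 2:
        raise ValueError("patterns must be (participants >= 2, channels, times)")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is low; null tails will be coarse")
    if normalize:
        norms = np.sqrt(np.sum(p**2, axis=(1, 2), keepdims=True))
        p = p / np.where(norms > 0, norms, 1.0)
    per_participant = np.stack([localize_templates(pi, templates)[0] for pi in p])  # (P, A, T)
    rng = np.random.default_rng(child_seed(seed, "signflip"))
    signs = rng.choice((-1.0, 1.0), size=(n_boot, p.shape[0]))
    return np.einsum("bp,pat->bat", signs, per_participant, optimize=True) / p.shape[0]


def gaussian_z_pvalue(observed, null_samples):
    """Gaussian-fit z and two-sided p of an observed value against its null.

    z = (observed − null mean) / null SD; p = 2·(1 − Φ(|z|)), floored at the
    smallest positive float so p ∈ (0, 1]. Broadcasts over trailing axes
    when ``null_samples`` is (n_boot, ...) and ``observed`` matches the
    trailing shape.
    """
    null = np.asarray(null_samples, dtype=float)
    if null.shape[0] < 2:
        raise ValueError("need at least 2 null samples")
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("null distribution has zero variance")
    z = (np.asarray(observed, dtype=float) - mu) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.maximum(p, np.finfo(float).tiny)
    return z, p


def consecutive_significance(
    p: np.ndarray,
    p_threshold: float = 0.005,
    min_duration_ms: float = 15.0,
    srate: float = 1000.0,
) -> np.ndarray:
    """Mask of maximal sub-threshold runs lasting at least ``min_duration_ms``.

    A run of k consecutive samples spans k·(1000/srate) ms; shorter runs are
    rejected entirely.
    """
    if srate <= 0:
        raise ValueError("srate must be positive")
    p = np.asarray(p, dtype=float)
    below = p < p_threshold
    mask = np.zeros_like(below)
    dt_ms = 1000.0 / srate
    i = 0
    n = below.size
    flat_below = below.ravel() if below.ndim == 1 else None
    if flat_below is None:  # apply row-wise for (A, T) input
        return np.stack(
            [consecutive_significance(row, p_threshold, min_duration_ms, srate) for row in p]
        )
    flat_mask = mask.ravel()
    while i < n:
        if flat_below[i]:
            j = i
            while j < n and flat_below[j]:
                j += 1
            if (j - i) * dt_ms >= min_duration_ms:
                flat_mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def source_analysis(
    patterns: np.ndarray,
    templates: np.ndarray,
    areas: list[str],
    times: np.ndarray,
    srate: float,
    n_boot: int = 1000,
    p_threshold: float = 0.005,
    min_duration_ms: float = 15.0,
    seed: int = 0,
    normalize: bool = True,
) -> SourceTimecourses:
    """Full source stage: observed contributions, bootstrap null, z/p, mask."""
    observed, _ = localize_templates(group_pattern(patterns, normalize=normalize), templates)
    null = signflip_bootstrap_null(patterns, templates, n_boot=n_boot, seed=seed, normalize=normalize)
    z, p = gaussian_z_pvalue(observed, null)
    mask = consecutive_significance(p, p_threshold, min_duration_ms, srate)
    return SourceTimecourses(
        areas=list(areas),
        times=np.asarray(times, dtype=float),
        contributions=observed,
        null_mean=null.mean(axis=0),
        null_sd=null.std(axis=0, ddof=1),
        z=z,
        p=p,
        mask=mask,
        params=dict(
            n_boot=n_boot, p_threshold=p_threshold, min_duration_ms=min_duration_ms,
            seed=seed, normalize=normalize,
        ),
    )
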