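"""Shared numerical helpers: seed derivation, shrinkage covariance, ring layouts."""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(master: int, *tags) -> int:
    """Derive a deterministic child seed from a master seed and string/int tags.

    Hash-based so that adding a new consumer never shifts another consumer's
    stream. Result is always in [0, 2**31) and safe for numpy Generators.
    """
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def ring_positions(n: int) -> np.ndarray:
    """Angles (radians) of n sensors equally spaced on a ring."""
    return 2.0 * np.pi * np.arange(n) / n


def ring_distance(n: int) -> np.ndarray:
    """n x n matrix of angular distances (radians) on the ring layout."""
    theta = ring_positions(n)
    d = np.abs(theta[:, None] - theta[None, :])
    return np.minimum(d, 2.0 * np.pi - d)


def shrinkage_covariance(z: np.ndarray, shrinkage: float | str = "auto"):
    """Shrinkage covariance toward the scaled identity, batched over time.

    Parameters
    ----------
    z : array, shape (n, C) or (n, C, T)
        Centered observations (residuals). The caller is responsible for
        removing the relevant means (e.g. per-condition, per-timepoint).
    shrinkage : 'auto' or float in [0, 1]
        'auto' uses the analytic (Ledoit–Wolf) intensity computed per
        timepoint; a float applies that fixed intensity.

    Returns
    -------
    sigma : array, (C, C) or (T, C, C)
    intensity : array, scalar or (T,)
    """
    single = z.ndim == 2
    if single:
        z = z[:, :, None]
    n, c, t = z.shape
    if n < 2:
        raise ValueError("need at least 2 observations to estimate a covariance")
    # empirical covariance per timepoint: S_t = Z_t' Z_t / n
    s = np.einsum("ict,idt->tcd", z, z, optimize=True) / n
    mu = np.trace(s, axis1=1, axis2=2) / c  # (T,)
    eye = np.eye(c)
    if shrinkage == "auto":
        # Ledoit & Wolf (2004) optimal intensity toward mu*I, vectorized over T.
        d2 = np.sum((s - mu[:, None, None] * eye) ** 2, axis=(1, 2)) / c
        sq_norms = np.sum(z**2, axis=1)  # (n, T): ||z_i||^2
        b2 = (np.sum(sq_norms**2, axis=0) / n**2) / c - np.sum(s**2, axis=(1, 2)) / (n * c)
        b2 = np.clip(b2, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            lam = np.where(d2 > 0, np.minimum(b2 / np.where(d2 > 0, d2, 1.0), 1.0), 1.0)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage intensity must lie in [0, 1]")
        lam = np.full(t, lam)
    sigma = (1.0 - lam)[:, None, None] * s + (lam * mu)[:, None, None] * eye
    if single:
        return sigma[0], lam[0]
    return sigma, lam


def inv_sqrtm_psd(sigma: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Inverse matrix square root of a symmetric PSD matrix (batched over axis 0
    when 3-D). Eigenvalues below rcond * max are treated as singular."""
    single = sigma.ndim == 2
    if single:
        sigma = sigma[None]
    w, v = np.linalg.eigh(sigma)
    wmax = np.max(w, axis=1, keepdims=True)
    bad = w <= rcond * np.maximum(wmax, 0.0)
    if np.any(wmax <= 0):
        raise np.linalg.LinAlgError("covariance is not positive definite")
    inv_sqrt_w = np.where(bad, 0.0, 1.0 / np.sqrt(np.where(bad, 1.0, w)))
    out = np.einsum("tij,tj,tkj->tik", v, inv_sqrt_w, v, optimize=True)
    return out[0] if single else out
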