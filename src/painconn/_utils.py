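"""Small shared helpers (integer apportionment, PSD repair, seeding)."""

from __future__ import annotations

import numpy as np


def largest_remainder(total: int, proportions) -> np.ndarray:
    """Apportion ``total`` integer units across categories by largest remainder.

    Quotas ``total * p_i`` are floored, then the leftover units go to the
    categories with the largest fractional remainders (ties broken by index,
    deterministically).
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("proportions must be a non-empty 1-D sequence")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {p.sum()!r})")
    quotas = total * p
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def apportion(total: int, quotas) -> np.ndarray:
    """Largest-remainder apportionment for arbitrary nonnegative real quotas
    summing (approximately) to ``total``."""
    q = np.asarray(quotas, dtype=float)
    counts = np.floor(q).astype(int)
    remainder = total - counts.sum()
    if remainder < 0:
        raise ValueError("quotas exceed total")
    order = np.argsort(-(q - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def nearest_psd_correlation(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive semi-definite matrix
    (eigenvalue clipping) and renormalize to unit diagonal.

    Raises if the result is still not PSD (cannot happen for finite input, but
    the contract is checked explicitly).
    """
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    if w.min() >= 0:
        out = sym
    else:
        w = np.clip(w, eps, None)
        out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    if np.any(d <= 0):
        raise ValueError("covariance repair failed: non-positive diagonal")
    out = out / np.outer(d, d)
    out = 0.5 * (out + out.T)
    if np.linalg.eigvalsh(out).min() < -1e-10:
        raise ValueError("covariance repair failed: matrix remains non-PSD")
    return out


def spawn_rngs(seed: int, names) -> dict:
    """Split one master seed into named independent Generator streams.

    The mapping from name to stream depends only on the position in ``names``,
    so adding streams at the end never perturbs earlier ones.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def sym_to_vec(mat: np.ndarray) -> np.ndarray:
    """Upper triangle (diagonal excluded) of a square matrix, row-major."""
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.asarray(mat)[iu]


def vec_to_sym(vec: np.ndarray, n_regions: int, diag_value: float = 0.0) -> np.ndarray:
    """Fold an upper-triangle vector back into a symmetric matrix."""
    iu = np.triu_indices(n_regions, k=1)
    if vec.shape[-1] != iu[0].size:
        raise ValueError(
            f"vector length {vec.shape[-1]} does not match {n_regions} regions "
            f"(expected {iu[0].size})"
        )
    out = np.full((n_regions, n_regions), float(diag_value))
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out
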