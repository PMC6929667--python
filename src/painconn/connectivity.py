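"""Pairwise functional-connectivity measures: correlation and DTW.

Two measures are supported:

* Pearson correlation (a similarity, in [-1, 1]);
* dynamic time warping distance (a dissimilarity, >= 0), computed either by
  the exact O(nm) dynamic program or by the FastDTW multiresolution
  approximation with a refinement ``radius``.

No sign flip is applied to reconcile the two orientations: both kinds of
matrix are globally z-scored downstream and the classifiers learn the
orientation, so a small DTW distance and a large correlation both simply mean
"strongly connected" in feature space — users comparing raw matrices should
keep the opposite orientations in mind.

The local cost defaults to the absolute difference (``cost='abs'``;
``'squared'`` is available).  FastDTW always returns the cost of a valid
warping path, hence ``dtw_fast >= dtw_exact``, with equality guaranteed when
``max(len(x), len(y)) <= radius + 2`` (the base case runs the full DP).

Matrix-level z-scoring uses the population standard deviation over *all*
cells, diagonal included.  It is applied per subject; a cohort-level variant
(one mean/sd shared by a whole stack of matrices) is available via
``zscore_matrices_cohort``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

MEASURES = ("correlation", "dtw")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N connectivity matrix plus provenance tags."""

    values: np.ndarray
    measure: str
    normalized: bool = False
    subject_id: str = ""
    parcellation_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be square")
        if np.abs(v - v.T).max(initial=0.0) > 1e-10:
            raise ValueError("connectivity values must be symmetric within 1e-10")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        self.values = v


# ---------------------------------------------------------------------------
# DTW kernels


@njit(cache=True)
def _band_dp(x, y, lo, hi, squared):
    """Dynamic program restricted to a per-row band [lo[i], hi[i]] over y.

    Steps are (1,0), (0,1), (1,1); cells outside the band stay infinite.
    Returns the accumulated-cost matrix.
    """
    n = x.shape[0]
    m = y.shape[0]
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        j0 = lo[i - 1] + 1
        j1 = hi[i - 1] + 1
        for j in range(j0, j1 + 1):
            d = x[i - 1] - y[j - 1]
            c = d * d if squared else abs(d)
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            if best < np.inf:
                acc[i, j] = c + best
    return acc


@njit(cache=True)
def _backtrack(acc):
    """Recover one optimal warping path from the accumulated-cost matrix."""
    i = acc.shape[0] - 1
    j = acc.shape[1] - 1
    path = np.empty((i + j + 1, 2), dtype=np.int64)
    k = 0
    while i > 1 or j > 1:
        path[k, 0] = i - 1
        path[k, 1] = j - 1
        k += 1
        diag = acc[i - 1, j - 1] if (i > 1 and j > 1) else np.inf
        up = acc[i - 1, j] if i > 1 else np.inf
        left = acc[i, j - 1] if j > 1 else np.inf
        if diag <= up and diag <= left:
            i -= 1
            j -= 1
        elif up <= left:
            i -= 1
        else:
            j -= 1
    path[k, 0] = 0
    path[k, 1] = 0
    k += 1
    return path[:k][::-1]


def _full_band(n: int, m: int):
    lo = np.zeros(n, dtype=np.int64)
    hi = np.full(n, m - 1, dtype=np.int64)
    return lo, hi


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("DTW requires non-empty series")
    return arr


def dtw_exact(x, y, cost: str = "abs") -> float:
    """Exact DTW distance by the full dynamic program."""
    x, y = _as_series(x), _as_series(y)
    lo, hi = _full_band(len(x), len(y))
    acc = _band_dp(x, y, lo, hi, cost == "squared")
    return float(acc[len(x), len(y)])


def _halve(x: np.ndarray) -> np.ndarray:
    """Coarsen a series by averaging adjacent pairs (odd tail kept as-is)."""
    n = len(x)
    half = x[: n - n % 2].reshape(-1, 2).mean(axis=1)
    if n % 2:
        half = np.concatenate([half, x[-1:]])
    return half


def _expand_window(path: np.ndarray, n: int, m: int, radius: int):
    """Project a coarse path to fine resolution and dilate it by ``radius``.

    Returns contiguous per-row bounds (lo, hi) over the fine grid; the band is
    made monotone and connected so the DP always has a feasible path from
    (0, 0) to (n-1, m-1).
    """
    lo = np.full(n, m, dtype=np.int64)
    hi = np.full(n, -1, dtype=np.int64)
    # dilate by `radius` in coarse cells, then project each cell to a 2x2 block
    for ci, cj in path:
        for i in range(2 * (ci - radius), 2 * (ci + radius) + 2):
            if 0 <= i < n:
                jl = max(0, 2 * (cj - radius))
                jh = min(m - 1, 2 * (cj + radius) + 1)
                if jl < lo[i]:
                    lo[i] = jl
                if jh > hi[i]:
                    hi[i] = jh
    # fill any empty rows and enforce monotone, connected bounds
    for i in range(n):
        if hi[i] < lo[i]:
            lo[i], hi[i] = (0, m - 1)
    lo[0] = 0
    hi[-1] = m - 1
    for i in range(1, n):
        if lo[i] < lo[i - 1]:
            lo[i] = lo[i - 1]
        if hi[i] < hi[i - 1]:  # keep rows overlapping so steps stay feasible
            hi[i] = hi[i - 1]
    return lo, hi


def _fastdtw(x: np.ndarray, y: np.ndarray, radius: int, squared: bool):
    n, m = len(x), len(y)
    if max(n, m) <= radius + 2:
        lo, hi = _full_band(n, m)
    else:
        coarse_path = _fastdtw(_halve(x), _halve(y), radius, squared)[1]
        lo, hi = _expand_window(coarse_path, n, m, radius)
    acc = _band_dp(x, y, lo, hi, squared)
    return float(acc[n, m]), _backtrack(acc)


def dtw_fast(x, y, radius: int = 1, cost: str = "abs") -> float:
    """FastDTW: coarsen, solve recursively, refine within ``radius``.

    The returned value is the cost of a valid warping path, so it is an upper
    bound on :func:`dtw_exact`; the two coincide whenever
    ``max(len(x), len(y)) <= radius + 2``.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    x, y = _as_series(x), _as_series(y)
    return _fastdtw(x, y, radius, cost == "squared")[0]


# ---------------------------------------------------------------------------
# Matrix construction


def correlation_matrix(signals: np.ndarray, subject_id: str = "",
                       parcellation_id: str = "") -> ConnectivityMatrix:
    """Pairwise Pearson correlation; diagonal 1.

    Zero-variance regions get zero rows/columns (with a logged warning)
    instead of NaNs; their diagonal entries stay 1.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("signals must be regions x timepoints with >= 3 timepoints")
    sd = x.std(axis=1)
    dead = sd < 1e-14
    vals = np.eye(x.shape[0])
    live = ~dead
    if live.sum() >= 1:
        sub = np.corrcoef(x[live])
        if live.sum() == 1:
            sub = np.atleast_2d(sub)
        vals[np.ix_(live, live)] = sub
    if dead.any():
        logger.warning("zero-variance regions in correlation set to 0: %s",
                       np.flatnonzero(dead).tolist())
        for r in np.flatnonzero(dead):
            vals[r, :] = 0.0
            vals[:, r] = 0.0
            vals[r, r] = 1.0
    vals = 0.5 * (vals + vals.T)
    return ConnectivityMatrix(vals, "correlation", False, subject_id, parcellation_id)


def connectivity_matrix(signals: np.ndarray, measure: str, radius: int = 1,
                        cost: str = "abs", subject_id: str = "",
                        parcellation_id: str = "") -> ConnectivityMatrix:
    """Symmetric connectivity matrix for the chosen measure.

    Only the upper triangle is computed and mirrored.  DTW uses
    :func:`dtw_fast` with the given radius and has a zero diagonal.
    """
    if measure == "correlation":
        return correlation_matrix(signals, subject_id, parcellation_id)
    if measure != "dtw":
        raise ValueError(f"unknown measure {measure!r}")
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("signals must be regions x timepoints")
    n = x.shape[0]
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_fast(x[i], x[j], radius=radius, cost=cost)
            vals[i, j] = vals[j, i] = d
    return ConnectivityMatrix(vals, "dtw", False, subject_id, parcellation_id)


def zscore_matrix(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Z-score every cell against all cells of the same matrix.

    Population standard deviation, diagonal included.  A constant matrix has
    no defined z-score and raises.
    """
    v = m.values
    mu = v.mean()
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant connectivity matrix")
    return replace(m, values=(v - mu) / sd, normalized=True)


def zscore_matrices_cohort(matrices) -> list:
    """Cohort-level alternative: one mean/sd pooled over all matrices' cells."""
    stack = np.stack([m.values for m in matrices])
    mu, sd = stack.mean(), stack.std()
    if sd == 0:
        raise ValueError("cannot z-score constant matrices")
    return [replace(m, values=(m.values - mu) / sd, normalized=True)
            for m in matrices]


# ---------------------------------------------------------------------------
# External interface: tab-delimited matrix + JSON sidecar


def write_matrix(m: ConnectivityMatrix, path) -> None:
    path = Path(path)
    np.savetxt(path, m.values, delimiter="\t")
    meta = {"subject_id": m.subject_id, "measure": m.measure,
            "parcellation_id": m.parcellation_id, "normalized": m.normalized}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    vals = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if np.abs(vals - vals.T).max(initial=0.0) > 1e-10:
        raise ValueError(f"matrix at {path} is not symmetric")
    return ConnectivityMatrix(vals, meta["measure"], meta["normalized"],
                              meta["subject_id"], meta["parcellation_id"])
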