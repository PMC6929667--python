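"""Parcel signal extraction and time-series cleaning.

Voxel data are turned into region (parcel) time-series by solving, per
timepoint, the least-squares problem ``voxel_data ~ atlas_weights @ signals``
— the natural inverse of the probabilistic-atlas mixing model.  Cleaning then
follows a fixed order: (1) remove a per-region linear trend, (2) project each
region's series onto the orthogonal complement of the confound column space,
(3) standardize each region to mean 0, sd 1.

Confound columns are themselves detrended (mean and linear trend removed)
before the projector is built.  This makes the three steps mutually
idempotent — the cleaned output is orthogonal to {constant, linear trend,
confounds} simultaneously, so cleaning a cleaned series is a no-op — without
changing the span being projected out (the trend is removed from the signal
in step 1 either way).

A volume-level artifact detector (global-intensity z-score plus frame-to-frame
motion difference) and the subject-exclusion rule (more than
``max_bad_volumes`` flagged volumes) complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .cohort import ParcellationMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds and switches for artifact flagging and series cleaning."""

    detrend: bool = True
    standardize: bool = True
    confound_projection: bool = True
    intensity_z_threshold: float = 3.0
    motion_threshold: float = 1.0
    max_bad_volumes: int = 3

    def validate(self) -> None:
        if self.intensity_z_threshold <= 0 or self.motion_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_bad_volumes < 0:
            raise ValueError("max_bad_volumes must be >= 0")


def flag_artifact_volumes(voxel_data: np.ndarray, motion_params: np.ndarray,
                          cfg: CleaningConfig | None = None) -> frozenset:
    """Flag outlier volumes by global intensity and motion jumps.

    A volume is flagged iff the z-score of its global mean intensity (against
    all volumes, population sd) exceeds ``intensity_z_threshold`` in absolute
    value, OR any motion channel moves by more than ``motion_threshold``
    between the previous volume and this one.  Constant data produce no
    intensity flags.
    """
    cfg = cfg or CleaningConfig()
    cfg.validate()
    voxel_data = np.asarray(voxel_data, dtype=float)
    if voxel_data.ndim != 2 or voxel_data.shape[1] < 2:
        raise ValueError("voxel_data must be voxels x timepoints with >= 2 timepoints")
    flags: set[int] = set()

    g = voxel_data.mean(axis=0)
    sd = g.std()
    if sd > 0:
        z = (g - g.mean()) / sd
        flags.update(np.flatnonzero(np.abs(z) > cfg.intensity_z_threshold).tolist())

    motion = np.asarray(motion_params, dtype=float)
    if motion.size:
        if motion.ndim == 1:
            motion = motion[:, None]
        if motion.shape[0] != voxel_data.shape[1]:
            raise ValueError("motion_params must have one row per volume")
        jumps = np.abs(np.diff(motion, axis=0))  # row t-1 -> volume t
        bad = np.flatnonzero((jumps > cfg.motion_threshold).any(axis=1)) + 1
        flags.update(bad.tolist())
    return frozenset(int(t) for t in flags)


def exclude_subject(flags, cfg: CleaningConfig | None = None) -> bool:
    """True iff the subject has more than ``max_bad_volumes`` flagged volumes."""
    cfg = cfg or CleaningConfig()
    cfg.validate()
    return len(flags) > cfg.max_bad_volumes


def _dependent_columns(weights: np.ndarray) -> list[int]:
    """Indices of columns outside the independent set chosen by pivoted QR."""
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(weights)
    _, _, piv = qr(weights, mode="economic", pivoting=True)
    return sorted(int(c) for c in piv[rank:])


def extract_region_signals(voxel_data: np.ndarray,
                           atlas: ParcellationMap) -> np.ndarray:
    """Per-timepoint least-squares inversion of the atlas mixing model.

    Returns the regions x timepoints matrix ``S`` minimizing
    ``||voxel_data - W @ S||`` columnwise; recovery is exact when the voxel
    data lie in the atlas column space.
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    weights = np.asarray(atlas.weights, dtype=float)
    if voxel_data.shape[0] != weights.shape[0]:
        raise ValueError(
            f"voxel_data has {voxel_data.shape[0]} voxels, atlas has {weights.shape[0]}"
        )
    if np.linalg.matrix_rank(weights) < weights.shape[1]:
        bad = _dependent_columns(weights)
        names = [atlas.region_names[c] for c in bad]
        raise ValueError(f"atlas is rank-deficient; offending columns: {names}")
    signals, *_ = np.linalg.lstsq(weights, voxel_data)
    return signals


def clean_timeseries(signals: np.ndarray, confounds: np.ndarray,
                     cfg: CleaningConfig | None = None) -> np.ndarray:
    """Detrend, project out confounds, standardize (in that order).

    After the projection step every region's series has zero inner product
    with every (detrended) confound column.  Regions left with zero variance
    are returned as all-zeros with a logged warning.
    """
    cfg = cfg or CleaningConfig()
    cfg.validate()
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("signals must be regions x timepoints")
    n_t = x.shape[1]
    conf = np.asarray(confounds, dtype=float)
    if conf.size == 0:
        conf = np.empty((n_t, 0))
    if conf.shape[0] != n_t:
        raise ValueError("confounds must have one row per timepoint")
    if n_t < conf.shape[1] + 2:
        raise ValueError("need timepoints >= n_confounds + 2")

    out = x.copy()
    if cfg.detrend:
        out = _linear_detrend(out, axis=1, type="linear")
    if cfg.confound_projection and conf.shape[1]:
        c = _linear_detrend(conf, axis=0, type="linear")
        # pseudoinverse-based projector: rank-safe for collinear confounds
        out = out - (out @ c) @ np.linalg.pinv(c)
    if cfg.standardize:
        mu = out.mean(axis=1, keepdims=True)
        sd = out.std(axis=1, keepdims=True)
        dead = sd[:, 0] < 1e-12 * max(1.0, float(np.abs(out).max(initial=0.0)))
        sd[dead] = 1.0
        out = (out - mu) / sd
        if dead.any():
            out[dead] = 0.0
            logger.warning("zero-variance regions after cleaning set to 0: %s",
                           np.flatnonzero(dead).tolist())
    return out


def apply_exclusion(records, cfg: CleaningConfig | None = None):
    """Drop subjects whose artifact flags exceed the allowed count.

    Returns ``(kept_records, report)`` where ``report`` is a list of
    ``(subject_id, n_flags, excluded)`` rows.
    """
    cfg = cfg or CleaningConfig()
    kept, report = [], []
    for rec in records:
        excluded = exclude_subject(rec.artifact_flags, cfg)
        report.append((rec.subject_id, len(rec.artifact_flags), excluded))
        if not excluded:
            kept.append(rec)
    return kept, report


def clean_cohort(records, cfg: CleaningConfig | None = None):
    """Clean every subject's series against its own confounds."""
    cfg = cfg or CleaningConfig()
    out = []
    for rec in records:
        cleaned = clean_timeseries(rec.timeseries, rec.confounds, cfg)
        out.append(cleaned)
    return out
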