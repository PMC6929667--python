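"""Synthetic resting-state cohort generator.

The study this pipeline implements was run on a private clinical dataset
(pain-free controls vs. chronic-pain patients).  This module generates a
synthetic multi-subject cohort with the statistical structure the downstream
analysis assumes, so the whole pipeline can be exercised and validated
end-to-end:

* two groups whose latent region signals are drawn from group-specific
  correlation matrices, with the group difference concentrated on a designated
  subset of edges (``affected_edges``);
* an optional inter-regional time lag in the patient group on those same
  edges, implemented as a circular shift of one member of each affected pair.
  The shift preserves the marginal variance of the series, so it attenuates
  instantaneous correlation while leaving a warping-based distance with a
  different (measure-specific) signature — correlation and DTW dissociate;
* temporally autocorrelated signals (AR(1) innovations, emulating the
  hemodynamic smoothness of BOLD) rather than white noise;
* nuisance confounds (linear drift, a slow sinusoid, a white "motion"
  channel) mixed into the observed series with small random loadings;
* occasional artifact volumes (a whole volume scaled by a spike factor),
  recorded as ground-truth flags;
* a sex label assigned from its own random stream, statistically independent
  of the group-conditional signal parameters unless a sex-linked edge effect
  is explicitly planted (used only for the sex-label control analysis).

The master seed is split into independent named streams (group, sex, signal,
confound, artifact) so that toggling one component never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.linalg import toeplitz

from ._utils import apportion, largest_remainder, nearest_psd_correlation, spawn_rngs

logger = logging.getLogger(__name__)

GROUPS = ("control", "chronic_pain")
SEXES = ("female", "male")

# Final cohort of 140 participants keeps the original 98:60 control:patient
# ratio of the recruited sample; 124:34 female:male likewise.
DEFAULT_GROUP_PROPORTIONS = (98 / 158, 60 / 158)
DEFAULT_SEX_PROPORTIONS = (124 / 158, 34 / 158)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``n_timepoints`` defaults to 235: a 240-volume echo-planar series with the
    first five volumes discarded.  ``corr_effect`` is the additive difference
    in latent correlation on affected edges for the patient group;
    ``base_coupling`` is the shared (both-group) latent correlation on those
    edges, on top of which the effect and/or lag act.  ``lag_effect`` is an
    integer circular shift (in volumes) applied to one member of each affected
    pair, patients only.
    """

    n_subjects: int = 140
    group_proportions: tuple[float, float] = DEFAULT_GROUP_PROPORTIONS
    n_regions: int = 16
    n_timepoints: int = 235
    affected_edges: frozenset = frozenset()
    base_coupling: float = 0.4
    corr_effect: float = 0.0
    lag_effect: int = 0
    ar_coefficient: float = 0.9
    toeplitz_rho: float = 0.3
    n_confounds: int = 3
    confound_amplitude: float = 0.1
    artifact_rate: float = 0.01
    artifact_scale: float = 5.0
    sex_proportions: tuple[float, float] = DEFAULT_SEX_PROPORTIONS
    sex_effect_edges: frozenset = frozenset()
    sex_effect: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, props in (("group_proportions", self.group_proportions),
                            ("sex_proportions", self.sex_proportions)):
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
            if any(p < 0 for p in props):
                raise ValueError(f"{name} must be nonnegative")
        if self.n_subjects < 1 or self.n_regions < 2 or self.n_timepoints < 2:
            raise ValueError("n_subjects, n_regions, n_timepoints too small")
        if not 0 <= self.lag_effect < self.n_timepoints:
            raise ValueError(
                f"lag_effect must satisfy 0 <= lag < n_timepoints "
                f"(got {self.lag_effect} with {self.n_timepoints} timepoints)"
            )
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in (-1, 1)")
        if not -2 <= self.corr_effect <= 2:
            raise ValueError("corr_effect must be in [-2, 2]")
        if self.n_confounds < 0 or not 0 <= self.artifact_rate <= 1:
            raise ValueError("invalid n_confounds or artifact_rate")
        for i, j in set(self.affected_edges) | set(self.sex_effect_edges):
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions and i != j):
                raise ValueError(f"edge ({i}, {j}) out of range for {self.n_regions} regions")


@dataclass
class SubjectRecord:
    """One participant: region time-series plus metadata."""

    subject_id: str
    group: str
    sex: str
    timeseries: np.ndarray  # regions x timepoints
    confounds: np.ndarray  # timepoints x n_confounds
    artifact_flags: frozenset = field(default_factory=frozenset)


@dataclass
class ParcellationMap:
    """Probabilistic parcellation: nonnegative voxel x region weights."""

    weights: np.ndarray  # voxels x regions
    region_names: list
    atlas_id: str = "toy"

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[1]


def choose_affected_edges(n_regions: int, fraction: float, seed: int) -> frozenset:
    """Sample ``fraction`` of all region pairs, without replacement."""
    pairs = list(combinations(range(n_regions), 2))
    n_pick = int(round(fraction * len(pairs)))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.choice(len(pairs), size=n_pick, replace=False)
    return frozenset(pairs[i] for i in sorted(idx))


@lru_cache(maxsize=32)
def _lag_calibration(n_timepoints: int, phi: float, lag: int) -> tuple:
    """Finite-sample calibration of the lag construction.

    Returns ``(align, alpha)`` where ``align`` is the Monte-Carlo expectation
    of the sample correlation between an AR(1) series and its circular
    ``lag``-shift at this series length (the asymptotic value ``phi**lag``
    carries a substantial negative finite-sample bias for persistent
    series), and ``alpha`` is the control-group mixing coefficient solved so
    that ``corr(f, alpha*f + sqrt(1-alpha^2)*g)`` has the same finite-sample
    expectation.  Both groups then match in measured correlation at the
    actual series length, not just asymptotically.

    The internal Monte Carlo uses a fixed seed: the calibration is a
    deterministic function of (length, phi, lag).
    """
    rng = np.random.default_rng(np.random.SeedSequence(987654321))
    n_mc = 400
    f = _ar1_series(rng, n_mc, n_timepoints, phi)
    g = _ar1_series(rng, n_mc, n_timepoints, phi)
    fz = (f - f.mean(axis=1, keepdims=True)) / f.std(axis=1, keepdims=True)

    def mean_corr(h):
        hz = (h - h.mean(axis=1, keepdims=True)) / h.std(axis=1, keepdims=True)
        return float((fz * hz).mean(axis=1).mean())

    return mean_corr(np.roll(f, lag, axis=1))


@lru_cache(maxsize=256)
def _composite_alpha(n_timepoints: int, phi: float, lag: int,
                     s2: float, c0: float) -> float:
    """Control mixing coefficient for one pair, calibrated on the composite.

    Simulates the full pair construction — background components with
    baseline correlation ``c0``, factor loading ``sqrt(s2)`` — *including the
    downstream cleaning* (detrending and projection of the slow nuisance
    regressors, which attenuates lagged coupling but not instantaneous
    mixing), and solves (secant) for the alpha whose control-group mean
    sample correlation equals the patient group's (circularly shifted
    factor).  Fixed internal seed: deterministic in its arguments.
    """
    rng = np.random.default_rng(np.random.SeedSequence(192837465))
    n_mc = 1500
    z1 = _ar1_series(rng, n_mc, n_timepoints, phi)
    w = _ar1_series(rng, n_mc, n_timepoints, phi)
    f = _ar1_series(rng, n_mc, n_timepoints, phi)
    g = _ar1_series(rng, n_mc, n_timepoints, phi)
    z2 = c0 * z1 + np.sqrt(max(1.0 - c0 * c0, 0.0)) * w
    s = np.sqrt(s2)

    # the deterministic part of the cleaning design: intercept, linear
    # trend and the slow sinusoid nuisance regressor
    t = np.arange(n_timepoints)
    design = np.column_stack([np.ones(n_timepoints), t - t.mean(),
                              np.sin(2 * np.pi * t / 100.0)])
    resid_proj = np.eye(n_timepoints) - design @ np.linalg.pinv(design)

    def mean_corr(y):
        x = (z1 + s * f) @ resid_proj.T
        y = y @ resid_proj.T
        xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        yz = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, keepdims=True)
        return float((xz * yz).mean(axis=1).mean())

    target = mean_corr(z2 + s * np.roll(f, lag, axis=1))
    a0 = phi ** lag
    a1 = min(0.999, a0 + 0.05)
    e0 = mean_corr(z2 + s * (a0 * f + np.sqrt(1 - a0 * a0) * g)) - target
    for _ in range(20):
        e1 = mean_corr(z2 + s * (a1 * f + np.sqrt(1 - a1 * a1) * g)) - target
        if abs(e1) < 5e-4 or e1 == e0:
            break
        a0, a1, e0 = a1, float(np.clip(a1 - e1 * (a1 - a0) / (e1 - e0),
                                       0.0, 0.999)), e1
    return a1


def choose_disjoint_pairs(n_regions: int, n_pairs: int, seed: int) -> frozenset:
    """Sample a matching: region pairs with no region shared between pairs.

    Disjoint pairs keep the lagged-coupling construction exactly on target
    (no region carries more than one shared factor), which is the cleanest
    condition for studying measure-specific (lag-only) group differences.
    """
    if 2 * n_pairs > n_regions:
        raise ValueError("not enough regions for that many disjoint pairs")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    regions = rng.permutation(n_regions)[: 2 * n_pairs]
    return frozenset(tuple(sorted((int(regions[2 * k]), int(regions[2 * k + 1]))))
                     for k in range(n_pairs))


def _group_correlation(cfg: CohortConfig, group: str, sex: str) -> np.ndarray:
    """Latent correlation matrix for one (group, sex) cell, PSD-repaired.

    When ``lag_effect`` is nonzero the affected-edge coupling is carried by
    per-pair shared factors instead (see :func:`_pair_loadings`), so this
    matrix then holds only the Toeplitz baseline plus any sex-linked effect.
    """
    base = toeplitz(cfg.toeplitz_rho ** np.arange(cfg.n_regions))
    c = base.copy()
    if not cfg.lag_effect:
        for i, j in cfg.affected_edges:
            c[i, j] = c[j, i] = cfg.base_coupling
        if group == "chronic_pain":
            for i, j in cfg.affected_edges:
                v = np.clip(c[i, j] + cfg.corr_effect, -0.99, 0.99)
                c[i, j] = c[j, i] = v
    if sex == "female" and cfg.sex_effect:
        for i, j in cfg.sex_effect_edges:
            v = np.clip(c[i, j] + cfg.sex_effect, -0.99, 0.99)
            c[i, j] = c[j, i] = v
    return nearest_psd_correlation(c)


def _pair_loadings(cfg: CohortConfig, group: str) -> tuple:
    """Shared-factor loadings realizing the affected-edge structure under lag.

    With a nonzero ``lag_effect`` each affected pair (i, j) shares a fresh
    AR(1) factor: region i receives the factor as-is.  In the patient group
    region j receives the *same* factor circularly shifted by the lag; in the
    control group it receives a partially decorrelated copy (mixing
    coefficient ``phi**lag``, matching the lag's autocorrelation attenuation
    exactly).  Both groups therefore share the same factor variance budget
    and the same instantaneous correlation on every edge — the groups differ
    only in whether the shared component is genuinely time-shifted (and thus
    re-alignable by a warping distance) or irrecoverably decorrelated.
    Correlation is blind to this difference by construction; DTW is not.

    Loadings are solved by fixed point so that the measured correlation hits
    ``base_coupling`` (+ ``corr_effect`` for patients) after per-region
    variance normalization, also when pairs share regions.
    """
    pairs = sorted(tuple(sorted(e)) for e in cfg.affected_edges)
    if not pairs or not cfg.lag_effect:
        return pairs, np.zeros(len(pairs)), np.ones(cfg.n_regions), np.ones(len(pairs))
    align = _lag_calibration(cfg.n_timepoints, cfg.ar_coefficient,
                             cfg.lag_effect)
    target = cfg.base_coupling + (cfg.corr_effect if group == "chronic_pain" else 0.0)
    target = float(np.clip(target, -0.95, 0.95))
    base = cfg.toeplitz_rho ** np.abs(np.subtract.outer(np.arange(cfg.n_regions),
                                                        np.arange(cfg.n_regions)))
    # damped fixed point; the cap keeps overloaded regions (many pairs on one
    # region) finite — their achieved coupling then undershoots the target
    s2 = np.full(len(pairs), max(target, 0.0) / max(1.0 - abs(target), 0.05))
    for _ in range(200):
        norm2 = np.ones(cfg.n_regions)
        for (i, j), v in zip(pairs, s2):
            norm2[i] += v
            norm2[j] += v
        new = np.array([
            max(target * np.sqrt(norm2[i] * norm2[j]) - base[i, j], 0.0) / align
            for (i, j) in pairs
        ])
        new = np.clip(0.5 * s2 + 0.5 * new, 0.0, 9.0)
        if np.allclose(new, s2, atol=1e-12):
            s2 = new
            break
        s2 = new
    norm2 = np.ones(cfg.n_regions)
    for (i, j), v in zip(pairs, s2):
        norm2[i] += v
        norm2[j] += v
    alphas = np.array([
        _composite_alpha(cfg.n_timepoints, cfg.ar_coefficient, cfg.lag_effect,
                         round(float(v), 3), round(float(base[i, j]), 3))
        for (i, j), v in zip(pairs, s2)
    ])
    return pairs, np.sqrt(s2), np.sqrt(norm2), alphas


def _ar1_series(rng: np.random.Generator, n_regions: int, n_timepoints: int,
                phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) rows from iid innovations."""
    e = rng.standard_normal((n_regions, n_timepoints))
    x = np.empty_like(e)
    x[:, 0] = e[:, 0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_timepoints):
        x[:, t] = phi * x[:, t - 1] + scale * e[:, t]
    return x


def _confound_matrix(rng: np.random.Generator, n_timepoints: int,
                     n_confounds: int) -> np.ndarray:
    """Drift + slow sinusoid + white motion channel (+ extra white channels)."""
    t = np.arange(n_timepoints)
    cols = []
    if n_confounds >= 1:
        cols.append(np.linspace(-1.0, 1.0, n_timepoints))
    if n_confounds >= 2:
        cols.append(np.sin(2 * np.pi * t / 100.0))
    while len(cols) < n_confounds:
        cols.append(rng.standard_normal(n_timepoints))
    if not cols:
        return np.empty((n_timepoints, 0))
    return np.column_stack(cols)


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw a full cohort of :class:`SubjectRecord` from ``config``.

    Deterministic given (config, seed): the same configuration always yields a
    bitwise-identical cohort.
    """
    config.validate()
    rngs = spawn_rngs(config.seed, ["group", "sex", "signal", "confound", "artifact"])

    group_counts = largest_remainder(config.n_subjects, config.group_proportions)
    groups = np.repeat(GROUPS, group_counts)
    rngs["group"].shuffle(groups)
    sex_counts = largest_remainder(config.n_subjects, config.sex_proportions)
    sexes = np.repeat(SEXES, sex_counts)
    rngs["sex"].shuffle(sexes)

    chols = {}
    loadings = {}
    for g in GROUPS:
        for s in SEXES:
            corr = _group_correlation(config, g, s)
            # jitter the floor slightly for numerical Cholesky safety
            chols[g, s] = np.linalg.cholesky(corr + 1e-10 * np.eye(config.n_regions))
        loadings[g] = _pair_loadings(config, g)

    records = []
    for k in range(config.n_subjects):
        g, s = str(groups[k]), str(sexes[k])
        latent = chols[g, s] @ _ar1_series(
            rngs["signal"], config.n_regions, config.n_timepoints, config.ar_coefficient
        )
        if config.lag_effect and config.affected_edges:
            # shared pair factors: the second member gets the factor either
            # truly time-shifted (patients) or decorrelated by the same
            # amount (controls); both variants are drawn for every subject so
            # the stream stays aligned across groups
            pairs, s_load, norm, alphas = loadings[g]
            factors = _ar1_series(rngs["signal"], len(pairs),
                                  config.n_timepoints, config.ar_coefficient)
            fresh = _ar1_series(rngs["signal"], len(pairs),
                                config.n_timepoints, config.ar_coefficient)
            for p, (i, j) in enumerate(pairs):
                latent[i] += s_load[p] * factors[p]
                if g == "chronic_pain":
                    fj = np.roll(factors[p], config.lag_effect)
                else:
                    a = alphas[p]
                    fj = a * factors[p] + np.sqrt(1 - a * a) * fresh[p]
                latent[j] += s_load[p] * fj
            latent /= norm[:, None]
        confounds = _confound_matrix(rngs["confound"], config.n_timepoints,
                                     config.n_confounds)
        conf_load = rngs["confound"].standard_normal((config.n_regions, config.n_confounds))
        observed = latent + config.confound_amplitude * conf_load @ confounds.T

        flags = np.flatnonzero(
            rngs["artifact"].random(config.n_timepoints) < config.artifact_rate
        )
        observed[:, flags] *= config.artifact_scale

        records.append(SubjectRecord(
            subject_id=f"sub-{k:03d}",
            group=g,
            sex=s,
            timeseries=observed,
            confounds=confounds,
            artifact_flags=frozenset(int(f) for f in flags),
        ))
    return records


def generate_toy_atlas(n_voxels: int, n_regions: int, overlap: float,
                       seed: int) -> ParcellationMap:
    """Random probabilistic toy atlas: every voxel has a dominant home region;
    with probability ``overlap`` it also loads on a second region.

    ``overlap=0`` yields a binary one-hot partition.  The weight matrix is
    guaranteed full column rank (regenerated with fresh jitter up to 10 times,
    then an error is raised).
    """
    if not (n_voxels >= n_regions >= 1):
        raise ValueError("need n_voxels >= n_regions >= 1")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for _attempt in range(10):
        weights = np.zeros((n_voxels, n_regions))
        home = np.concatenate([
            np.arange(n_regions),  # every region owns at least one voxel
            rng.integers(0, n_regions, size=n_voxels - n_regions),
        ])
        rng.shuffle(home)
        weights[np.arange(n_voxels), home] = 1.0
        if overlap > 0:
            mixed = rng.random(n_voxels) < overlap
            for v in np.flatnonzero(mixed):
                other = int(rng.integers(0, n_regions - 1))
                if other >= home[v]:
                    other += 1
                weights[v, other] = rng.uniform(0.2, 0.6)
        if np.linalg.matrix_rank(weights) == n_regions:
            names = [f"region_{r:03d}" for r in range(n_regions)]
            return ParcellationMap(weights=weights, region_names=names,
                                   atlas_id=f"toy{n_regions}")
    raise RuntimeError("failed to generate a full-rank atlas in 10 attempts")


def generate_voxel_volume(record: SubjectRecord, atlas: ParcellationMap,
                          noise_sd: float, seed: int) -> np.ndarray:
    """Voxel time-series implied by the linear mixing model:
    ``voxels = atlas_weights @ region_signals + N(0, noise_sd)``."""
    if atlas.n_regions != record.timeseries.shape[0]:
        raise ValueError(
            f"atlas has {atlas.n_regions} regions but record has "
            f"{record.timeseries.shape[0]}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    data = atlas.weights @ record.timeseries
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return data


def null_config(config: CohortConfig) -> CohortConfig:
    """The matched no-effect configuration (exchangeable groups)."""
    return replace(config, corr_effect=0.0, lag_effect=0, sex_effect=0.0)


# ---------------------------------------------------------------------------
# NIfTI adapters (optional external interface)

def voxel_series_to_nifti(voxel_data: np.ndarray, grid_shape: tuple):
    """Pack a voxels x timepoints matrix into a 4-D NIfTI image."""
    import nibabel as nib

    nx, ny, nz = grid_shape
    if nx * ny * nz != voxel_data.shape[0]:
        raise ValueError("grid_shape does not match voxel count")
    vol = voxel_data.reshape(nx, ny, nz, voxel_data.shape[1])
    return nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))


def atlas_to_nifti(atlas: ParcellationMap, grid_shape: tuple):
    """Pack a probabilistic atlas into a 4-D NIfTI (one volume per region)."""
    import nibabel as nib

    nx, ny, nz = grid_shape
    if nx * ny * nz != atlas.n_voxels:
        raise ValueError("grid_shape does not match voxel count")
    vol = atlas.weights.reshape(nx, ny, nz, atlas.n_regions)
    return nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))


def nifti_to_voxel_series(img) -> np.ndarray:
    """Flatten a 4-D NIfTI back into a voxels x timepoints matrix."""
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D image")
    return data.reshape(-1, data.shape[3])
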