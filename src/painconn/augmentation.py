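"""Local Synthetic Instances (LSI): nearest-neighbor convex interpolation.

Small-n neuroimaging studies cannot feed a CNN directly; the training set is
expanded by sampling a real instance ``a``, one of its ``k`` nearest
neighbors ``b`` *of the same class* (Euclidean distance in feature space),
and a mixing weight ``alpha ~ U(0, 1)``, and emitting::

    s = alpha * a + (1 - alpha) * b        (label = class of a)

This is the SMOTE-family reconstruction of the "local synthetic instances"
idea: every synthetic point lies on a segment between two same-class parents,
hence inside the class-conditional convex hull.  The scheme here is a
reconstruction from that principle (neighbor count, mixing law and class
balancing are configurable), not a line-for-line reproduction of any one
reference implementation.

Training and validation sets are always augmented separately
(:func:`augment_split`): synthetic training instances derive only from
training parents and synthetic validation instances only from validation
parents, and the parent indices of every synthetic instance are recorded so
the absence of leakage can be audited after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._utils import largest_remainder


@dataclass(frozen=True)
class AugmentationConfig:
    n_synthetic: int = 5000
    k_neighbors: int = 5
    mix_distribution: str = "uniform01"
    balance_classes: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_synthetic < 0:
            raise ValueError("n_synthetic must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.mix_distribution != "uniform01":
            raise ValueError(f"unknown mix_distribution {self.mix_distribution!r}")


@dataclass
class SyntheticSet:
    """Synthetic instances plus full provenance (parent indices, alphas)."""

    features: np.ndarray  # n_synthetic x dims
    labels: np.ndarray  # n_synthetic
    parent_a: np.ndarray  # index of instance a (in the caller's index space)
    parent_b: np.ndarray  # index of neighbor b
    alphas: np.ndarray

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parent_a": self.parent_a,
            "parent_b": self.parent_b,
            "alpha": self.alphas,
            "label": self.labels,
        })


def local_synthetic_instances(features, labels, cfg: AugmentationConfig,
                              index=None, rng=None) -> SyntheticSet:
    """Draw ``cfg.n_synthetic`` synthetic instances from real parents.

    ``index`` optionally maps row positions to external instance ids so that
    recorded provenance lives in the caller's index space.  With
    ``balance_classes`` the per-class synthetic counts differ by at most one;
    otherwise they are proportional to the class sizes.
    """
    cfg.validate()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("features must be instances x dims")
    if len(y) != x.shape[0]:
        raise ValueError("labels length must match features")
    index = np.arange(len(y)) if index is None else np.asarray(index)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 instances")

    if cfg.balance_classes:
        per_class = largest_remainder(cfg.n_synthetic,
                                      np.full(len(classes), 1.0 / len(classes)))
    else:
        per_class = largest_remainder(cfg.n_synthetic, counts / counts.sum())

    feats, labs, pas, pbs, als = [], [], [], [], []
    for cls, n_cls in zip(classes, per_class):
        rows = np.flatnonzero(y == cls)
        xc = x[rows]
        k = min(cfg.k_neighbors, len(rows) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(xc)
        neigh = nn.kneighbors(xc, return_distance=False)[:, 1:]  # drop self
        a_pos = rng.integers(0, len(rows), size=n_cls)
        b_pos = neigh[a_pos, rng.integers(0, k, size=n_cls)]
        alpha = rng.random(n_cls)
        feats.append(alpha[:, None] * xc[a_pos] + (1 - alpha[:, None]) * xc[b_pos])
        labs.append(np.full(n_cls, cls, dtype=y.dtype))
        pas.append(index[rows[a_pos]])
        pbs.append(index[rows[b_pos]])
        als.append(alpha)

    return SyntheticSet(
        features=np.concatenate(feats) if feats else np.empty((0, x.shape[1])),
        labels=np.concatenate(labs) if labs else np.empty(0, dtype=y.dtype),
        parent_a=np.concatenate(pas) if pas else np.empty(0, dtype=int),
        parent_b=np.concatenate(pbs) if pbs else np.empty(0, dtype=int),
        alphas=np.concatenate(als) if als else np.empty(0),
    )


@dataclass
class AugmentedSplit:
    train: SyntheticSet
    validation: SyntheticSet


def augment_split(train_features, train_labels, val_features, val_labels,
                  cfg: AugmentationConfig, train_index=None,
                  val_index=None) -> AugmentedSplit:
    """Augment training and validation sets separately (no cross-leakage).

    The two sets get independent child streams of ``cfg.seed``; each
    synthetic set's provenance refers only to its own side's parents.  If
    index arrays are supplied they must be disjoint.
    """
    cfg.validate()
    train_index = (np.arange(len(train_labels)) if train_index is None
                   else np.asarray(train_index))
    val_index = (np.arange(len(train_labels), len(train_labels) + len(val_labels))
                 if val_index is None else np.asarray(val_index))
    if np.intersect1d(train_index, val_index).size:
        raise ValueError("train and validation index sets overlap")

    ss_train, ss_val = np.random.SeedSequence(cfg.seed).spawn(2)
    train_syn = local_synthetic_instances(
        train_features, train_labels, cfg, index=train_index,
        rng=np.random.default_rng(ss_train))
    val_syn = local_synthetic_instances(
        val_features, val_labels, cfg, index=val_index,
        rng=np.random.default_rng(ss_val))
    return AugmentedSplit(train=train_syn, validation=val_syn)


def audit_provenance(synthetic: SyntheticSet, allowed_index) -> None:
    """Raise unless every recorded parent belongs to ``allowed_index``."""
    allowed = np.asarray(allowed_index)
    parents = np.concatenate([synthetic.parent_a, synthetic.parent_b])
    bad = np.setdiff1d(parents, allowed)
    if bad.size:
        raise RuntimeError(
            f"provenance violation: synthetic parents {bad.tolist()} are outside "
            "the allowed instance set"
        )
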