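"""Experiment protocol: splits, metrics, the grid, and the runners.

The evaluation protocol is strict about leakage: an independent test fold is
carved out by a stratified split *before* anything else happens; all
augmentation, training and model search see only training-fold subjects, and
every synthetic instance carries parent provenance so the separation can be
audited mechanically (:func:`painconn.augmentation.audit_provenance`).  All
reported scores are computed on the independent fold only.

Metrics follow their textbook definitions exactly as used downstream:

* balanced accuracy — mean per-class recall;
* log loss — negative mean log-likelihood with probabilities clamped to
  ``[clip_eps, 1 - clip_eps]`` (natural log);
* AUC — Mann-Whitney form, ties counted 1/2.

The full hyper-parameter grid is the Cartesian product of parcellations (4)
x connectivity measures (2) x architectures (3) x learning rates (3) x
dropout (4) x L1 (3) x L2 (3) = 2592 experiments; the classical-pipeline
search adds 3 optimization metrics x 8 matrix sets = 24 more, 2616 in all.

The classical baseline is a seeded evolutionary search (population 50,
10 generations by default) over an explicit scikit-learn pipeline space
(scaler on/off x univariate feature selector on/off x classifier family),
selected by stratified within-training cross-validation only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._utils import apportion, sym_to_vec, vec_to_sym
from .augmentation import AugmentationConfig, audit_provenance, augment_split
from .connectivity import connectivity_matrix, zscore_matrix
from .extraction import CleaningConfig, clean_timeseries
from .models import (ArchitectureSpec, TrainConfig, build_architecture,
                     predict_proba, train_model)

DEFAULT_PARCELLATIONS = ("biobank21", "biobank55", "msdl39", "willard499")
DEFAULT_MEASURES = ("correlation", "dtw")
DEFAULT_ARCHITECTURES = ("ann4brains", "ann4brains_batch", "conv1d_net")
DEFAULT_LEARNING_RATES = (0.1, 0.01, 0.001)
DEFAULT_DROPOUTS = (0.0, 0.3, 0.5, 0.8)
DEFAULT_LAMBDAS = (0.0, 0.1, 0.01)
BASELINE_METRICS = ("balanced_accuracy", "auc", "log_loss")


# ---------------------------------------------------------------------------
# Metrics


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recall; requires both classes in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if len(classes) < 2:
        raise ValueError("balanced accuracy needs both classes in y_true")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def log_loss(y_true, p_class1, clip_eps: float = 1e-15) -> float:
    """Negative mean log-likelihood of binary labels, clipped probabilities."""
    y = np.asarray(y_true, dtype=float)
    p = np.clip(np.asarray(p_class1, dtype=float), clip_eps, 1.0 - clip_eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def auc(y_true, p_class1) -> float:
    """Probability a random positive outranks a random negative; ties 1/2."""
    from scipy.stats import rankdata

    y = np.asarray(y_true)
    p = np.asarray(p_class1, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes in y_true")
    ranks = rankdata(p)  # average ranks implement the tie = 1/2 convention
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Split protocol


def stratified_split(labels, train_fraction: float, seed: int):
    """Per-class largest-remainder stratified split into (train, test) ids.

    The total training size is ``round(train_fraction * n)``; per-class
    training counts are the largest-remainder apportionment of the per-class
    quotas, so a 140-subject cohort at fraction 0.70 always yields 98/42.
    """
    y = np.asarray(labels)
    n = len(y)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 records in each of >= 2 classes")
    total_train = int(round(train_fraction * n))
    per_class = apportion(total_train, train_fraction * counts)
    if np.any(per_class >= counts):
        raise ValueError("a class would receive 0 test members")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    train_ids, test_ids = [], []
    for cls, n_train in zip(classes, per_class):
        rows = np.flatnonzero(y == cls)
        rng.shuffle(rows)
        train_ids.extend(rows[:n_train].tolist())
        test_ids.extend(rows[n_train:].tolist())
    return np.array(sorted(train_ids)), np.array(sorted(test_ids))


# ---------------------------------------------------------------------------
# Grid enumeration


@dataclass(frozen=True)
class ExperimentSpec:
    """One grid cell of the classification experiment."""

    parcellation_id: str
    measure: str
    architecture: str
    learning_rate: float
    dropout: float
    l1_lambda: float
    l2_lambda: float
    seed: int = 0


@dataclass(frozen=True)
class GridConfig:
    parcellations: tuple = DEFAULT_PARCELLATIONS
    measures: tuple = DEFAULT_MEASURES
    architectures: tuple = DEFAULT_ARCHITECTURES
    learning_rates: tuple = DEFAULT_LEARNING_RATES
    dropouts: tuple = DEFAULT_DROPOUTS
    l1_lambdas: tuple = DEFAULT_LAMBDAS
    l2_lambdas: tuple = DEFAULT_LAMBDAS
    seed: int = 0


def enumerate_grid(grid: GridConfig | None = None) -> list:
    """Deterministic Cartesian product of all grid factors (no duplicates)."""
    grid = grid or GridConfig()
    factors = (grid.parcellations, grid.measures, grid.architectures,
               grid.learning_rates, grid.dropouts, grid.l1_lambdas,
               grid.l2_lambdas)
    names = ("parcellations", "measures", "architectures", "learning_rates",
             "dropouts", "l1_lambdas", "l2_lambdas")
    for name, f in zip(names, factors):
        if len(f) == 0:
            raise ValueError(f"grid factor {name} is empty")
        if len(set(f)) != len(f):
            raise ValueError(f"grid factor {name} has duplicates")
    return [
        ExperimentSpec(p, m, a, lr, do, l1, l2, seed=grid.seed)
        for p, m, a, lr, do, l1, l2 in itertools.product(*factors)
    ]


@dataclass(frozen=True)
class BaselineSpec:
    """One automated-search experiment: an optimization metric x matrix set."""

    matrix_set: str  # "<parcellation>_<measure>"
    metric: str


def enumerate_baseline_grid(parcellations=DEFAULT_PARCELLATIONS,
                            measures=DEFAULT_MEASURES,
                            metrics=BASELINE_METRICS) -> list:
    if not parcellations or not measures or not metrics:
        raise ValueError("baseline grid factors must be non-empty")
    return [BaselineSpec(f"{p}_{m}", metric)
            for metric in metrics
            for p in parcellations for m in measures]


# ---------------------------------------------------------------------------
# Feature assembly (cohort records -> per-measure z-scored features)


@dataclass
class FeatureSet:
    """Vectorized z-scored connectivity features for one (parcellation, measure)."""

    vectors: np.ndarray  # subjects x n_edges (upper triangle, diagonal excluded)
    group_labels: np.ndarray  # 1 = chronic pain
    sex_labels: np.ndarray  # 1 = female
    subject_ids: list
    n_regions: int
    parcellation_id: str
    measure: str

    def matrices(self) -> np.ndarray:
        return np.stack([vec_to_sym(v, self.n_regions) for v in self.vectors])

    def labels(self, target: str) -> np.ndarray:
        if target == "group":
            return self.group_labels
        if target == "sex":
            return self.sex_labels
        raise ValueError(f"unknown target {target!r}")


def cohort_features(records, measure: str, radius: int = 1,
                    cleaning: CleaningConfig | None = None,
                    parcellation_id: str = "toy") -> FeatureSet:
    """Clean each subject, build one connectivity matrix, z-score, vectorize."""
    cleaning = cleaning or CleaningConfig()
    vecs, groups, sexes, ids = [], [], [], []
    n_regions = records[0].timeseries.shape[0]
    for rec in records:
        cleaned = clean_timeseries(rec.timeseries, rec.confounds, cleaning)
        mat = connectivity_matrix(cleaned, measure, radius=radius,
                                  subject_id=rec.subject_id,
                                  parcellation_id=parcellation_id)
        vecs.append(sym_to_vec(zscore_matrix(mat).values))
        groups.append(1 if rec.group == "chronic_pain" else 0)
        sexes.append(1 if rec.sex == "female" else 0)
        ids.append(rec.subject_id)
    return FeatureSet(np.stack(vecs), np.array(groups), np.array(sexes), ids,
                      n_regions, parcellation_id, measure)


# ---------------------------------------------------------------------------
# Experiment runner


@dataclass
class EvaluationResult:
    spec: ExperimentSpec
    balanced_accuracy: float
    log_loss: float
    auc: float
    predictions: pd.DataFrame

    def row(self) -> dict:
        d = {k: getattr(self.spec, k) for k in
             ("parcellation_id", "measure", "architecture", "learning_rate",
              "dropout", "l1_lambda", "l2_lambda", "seed")}
        d.update(balanced_accuracy=self.balanced_accuracy,
                 log_loss=self.log_loss, auc=self.auc)
        return d


def run_experiment(spec: ExperimentSpec, features: FeatureSet, split,
                   aug_cfg: AugmentationConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   arch_overrides: dict | None = None,
                   target: str = "group") -> EvaluationResult:
    """Train one grid cell and score it on the independent fold.

    The training fold is sub-split (stratified, 3:1) into train/validation;
    both sub-sets are augmented separately and the model is trained on the
    synthetic instances only.  A provenance audit asserts that no synthetic
    instance has a parent outside its own sub-set — in particular none from
    the independent fold.
    """
    aug_cfg = aug_cfg or AugmentationConfig()
    train_idx, test_idx = (np.asarray(split[0]), np.asarray(split[1]))
    if np.intersect1d(train_idx, test_idx).size:
        raise RuntimeError("provenance violation: train and test folds overlap")
    y = features.labels(target)
    x = features.vectors

    sub_train, sub_val = stratified_split(y[train_idx], 0.75, seed=spec.seed)
    inner_train, inner_val = train_idx[sub_train], train_idx[sub_val]
    aug = augment_split(x[inner_train], y[inner_train],
                        x[inner_val], y[inner_val],
                        replace(aug_cfg, seed=aug_cfg.seed + spec.seed),
                        train_index=inner_train, val_index=inner_val)
    audit_provenance(aug.train, inner_train)
    audit_provenance(aug.validation, inner_val)
    for syn in (aug.train, aug.validation):
        if np.intersect1d(np.concatenate([syn.parent_a, syn.parent_b]),
                          test_idx).size:
            raise RuntimeError("provenance violation: test-fold parent detected")

    n = features.n_regions
    fold = lambda v: np.stack([vec_to_sym(row, n) for row in v])  # noqa: E731
    arch = ArchitectureSpec(
        name=spec.architecture, n_regions=n, dropout=spec.dropout,
        l1_lambda=spec.l1_lambda, l2_lambda=spec.l2_lambda,
        learning_rate=spec.learning_rate,
        batch_norm=spec.architecture == "ann4brains_batch",
        **(arch_overrides or {}))
    net = build_architecture(arch, seed=spec.seed)
    trained = train_model(net, fold(aug.train.features), aug.train.labels,
                          fold(aug.validation.features), aug.validation.labels,
                          arch, train_cfg, seed=spec.seed)

    probs = predict_proba(trained, fold(x[test_idx]))[:, 1]
    y_test = y[test_idx]
    preds = pd.DataFrame({
        "subject_id": [features.subject_ids[i] for i in test_idx],
        "y_true": y_test,
        "p_class1": probs,
        "y_pred": (probs >= 0.5).astype(int),
    })
    return EvaluationResult(
        spec=spec,
        balanced_accuracy=balanced_accuracy(y_test, preds["y_pred"].to_numpy()),
        log_loss=log_loss(y_test, probs),
        auc=auc(y_test, probs),
        predictions=preds,
    )


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results])


# ---------------------------------------------------------------------------
# Classical-pipeline evolutionary search


def default_search_space() -> dict:
    """The bounded pipeline space: scaler x selector x classifier family.

    Classifier entries are (family, ((param, value), ...)) so genomes stay
    hashable for fitness caching.
    """
    return {
        "scaler": [False, True],
        "select_k": [0, 10, 25, 50],  # 0 = no selection
        "classifier": [
            ("logreg", (("C", 0.1),)), ("logreg", (("C", 1.0),)),
            ("logreg", (("C", 10.0),)),
            ("svc", (("C", 0.1),)), ("svc", (("C", 1.0),)),
            ("svc", (("C", 10.0),)),
            ("rf", (("n_estimators", 100), ("max_depth", None))),
            ("rf", (("n_estimators", 100), ("max_depth", 5))),
            ("knn", (("n_neighbors", 3),)), ("knn", (("n_neighbors", 5),)),
            ("knn", (("n_neighbors", 7),)),
        ],
    }


def _build_pipeline(genome: tuple, n_features: int, seed: int) -> Pipeline:
    scaler, select_k, (family, kw_items) = genome
    kw = dict(kw_items)
    steps = []
    if scaler:
        steps.append(("scale", StandardScaler()))
    if select_k:
        steps.append(("select", SelectKBest(f_classif, k=min(select_k, n_features))))
    if family == "logreg":
        clf = LogisticRegression(max_iter=2000, random_state=seed, **kw)
    elif family == "svc":
        # Platt-style calibration gives the margin classifier probabilities
        clf = CalibratedClassifierCV(SVC(kernel="linear", random_state=seed, **kw),
                                     ensemble=False, cv=3)
    elif family == "rf":
        clf = RandomForestClassifier(random_state=seed, **kw)
    elif family == "knn":
        clf = KNeighborsClassifier(**kw)
    else:  # pragma: no cover - space is fixed above
        raise ValueError(f"unknown classifier family {family!r}")
    steps.append(("clf", clf))
    return Pipeline(steps)


def _cv_score(genome: tuple, x: np.ndarray, y: np.ndarray, metric: str,
              folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(x, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("fold stratification impossible: single-class fold")
        pipe = _build_pipeline(genome, x.shape[1], seed)
        pipe.fit(x[tr], y[tr])
        p = pipe.predict_proba(x[te])[:, 1]
        if metric == "balanced_accuracy":
            scores.append(balanced_accuracy(y[te], (p >= 0.5).astype(int)))
        elif metric == "auc":
            scores.append(auc(y[te], p))
        elif metric == "log_loss":
            scores.append(-log_loss(y[te], p))  # maximized
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return float(np.mean(scores))


@dataclass
class BaselineSearchResult:
    genome: tuple
    pipeline: Pipeline
    cv_score: float  # on the metric's natural scale (log loss: lower = better)
    metric: str
    evaluations: int


def classical_baseline_search(x, y, metric: str = "balanced_accuracy",
                              folds: int = 5, population: int = 50,
                              generations: int = 10, seed: int = 0,
                              space: dict | None = None) -> BaselineSearchResult:
    """Seeded evolutionary search over the classical-pipeline space.

    Selection uses only stratified cross-validation inside the supplied
    (training) data; the winning genome is refit on all of it.  Fitness
    evaluations are cached per genome, so the effective cost is bounded by
    the size of the space rather than population x generations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    space = space or default_search_space()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    keys = ("scaler", "select_k", "classifier")

    def random_genome() -> tuple:
        return tuple(space[k][rng.integers(len(space[k]))] for k in keys)

    cache: dict = {}

    def fitness(genome: tuple) -> float:
        if genome not in cache:
            cache[genome] = _cv_score(genome, x, y, metric, folds, seed)
        return cache[genome]

    n_genomes = int(np.prod([len(space[k]) for k in keys]))
    if n_genomes == 1:
        best = tuple(space[k][0] for k in keys)
        score = fitness(best)
    else:
        pop = [random_genome() for _ in range(population)]
        for _gen in range(generations):
            scored = sorted(pop, key=fitness, reverse=True)
            elite = scored[: max(2, population // 4)]
            children = list(elite)
            while len(children) < population:
                a, b = (elite[rng.integers(len(elite))] for _ in range(2))
                child = tuple(a[i] if rng.random() < 0.5 else b[i]
                              for i in range(len(keys)))
                if rng.random() < 0.3:  # point mutation
                    i = int(rng.integers(len(keys)))
                    child = (child[:i]
                             + (space[keys[i]][rng.integers(len(space[keys[i]]))],)
                             + child[i + 1:])
                children.append(child)
            pop = children
        best = max(set(pop) | set(cache), key=fitness)
        score = fitness(best)

    pipeline = _build_pipeline(best, x.shape[1], seed)
    pipeline.fit(x, y)
    cv = -score if metric == "log_loss" else score
    return BaselineSearchResult(genome=best, pipeline=pipeline, cv_score=cv,
                                metric=metric, evaluations=len(cache))


# ---------------------------------------------------------------------------
# Sex-label control analysis


def sex_control_analysis(specs, features: FeatureSet, split,
                         aug_cfg: AugmentationConfig | None = None,
                         train_cfg: TrainConfig | None = None,
                         arch_overrides: dict | None = None) -> pd.DataFrame:
    """Re-run the identical pipeline with sex as the target variable.

    Returns one table with the pain-target and sex-target scores per spec,
    so control and primary results sit side by side.
    """
    for name, idx in (("train", split[0]), ("test", split[1])):
        if len(np.unique(features.sex_labels[np.asarray(idx)])) < 2:
            raise ValueError(f"single-sex {name} fold: control analysis undefined")
    rows = []
    for spec in specs:
        for target in ("group", "sex"):
            res = run_experiment(spec, features, split, aug_cfg, train_cfg,
                                 arch_overrides, target=target)
            row = res.row()
            row["target"] = target
            rows.append(row)
    return pd.DataFrame(rows)
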