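"""End-to-end study conditions: power, null, lag-dissociation, sex control.

These functions bundle the full pipeline — cohort generation, cleaning,
connectivity, augmentation, training, independent-fold scoring — under the
fixed study conditions used throughout the project:

* **power study** — 140 subjects, 16 regions, a correlation effect of 0.4 on
  20% of edges; 12 grid cells sampled from the full hyper-parameter grid.
* **null study** — the matched no-effect cohort; the AUC distribution over
  20 specs should center on chance.
* **lag-dissociation study** — cohorts whose group difference is purely a
  timing difference (circular lag on disjoint coupled pairs, instantaneous
  correlation matched between groups): the best DTW-based spec is compared
  with the best correlation-based spec over replicate cohorts.
* **sex-control study** — the pipeline re-targeted at the sex label, with
  sex either independent of connectivity or planted on one edge.

Problem sizes are reduced relative to the clinical protocol (16 or 12
regions instead of hundreds, a few hundred synthetic instances instead of
five thousand, filter banks a quarter of the default width) so a full study
runs in minutes on one CPU; the reductions are documented in the methods
note and exposed as arguments.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from .augmentation import AugmentationConfig
from .cohort import (CohortConfig, choose_affected_edges, choose_disjoint_pairs,
                     generate_cohort)
from .experiments import (ExperimentSpec, GridConfig, cohort_features,
                          enumerate_grid, run_experiment, stratified_split)
from .models import TrainConfig

# quarter-width filter banks: same architectures, desk-scale runtimes
REDUCED_ARCH = dict(e2e_filters=8, e2n_filters=16, n2g_units=32,
                    fc_sizes=(32, 16, 2), conv1d_filters=(32, 32), conv1d_fc=32)

TRAIN_FRACTION = 0.70


def _seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


def effect_cohort_config(seed: int, n_subjects: int = 140, n_regions: int = 16,
                         corr_effect: float = 0.4,
                         affected_fraction: float = 0.2) -> CohortConfig:
    """The canonical effect-bearing cohort: correlation effect on 20% of edges."""
    edge_seed, cohort_seed = _seeds(seed, 2)
    edges = choose_affected_edges(n_regions, affected_fraction, edge_seed)
    return CohortConfig(n_subjects=n_subjects, n_regions=n_regions,
                        affected_edges=edges, base_coupling=0.4,
                        corr_effect=corr_effect, artifact_rate=0.0,
                        seed=cohort_seed)


def sample_grid_cells(n_cells: int, seed: int, parcellation: str = "toy16",
                      measures=("correlation", "dtw")) -> list:
    """Deterministically sample distinct cells from the full grid."""
    grid = enumerate_grid(GridConfig(parcellations=(parcellation,),
                                     measures=tuple(measures)))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.choice(len(grid), size=n_cells, replace=False)
    return [dc_replace(grid[i], seed=k) for k, i in enumerate(sorted(idx))]


def _run_cells(specs, feature_sets, split, n_synthetic, epochs,
               target: str = "group") -> pd.DataFrame:
    """Run each spec; ``split`` is one (train, test) pair or one per spec.

    Chance-level summaries (null and independent-sex studies) pass one split
    per spec so that fold-composition noise averages out across specs.
    """
    splits = split if isinstance(split, list) else [split] * len(specs)
    rows = []
    for spec, split in zip(specs, splits):
        fs = feature_sets[spec.measure]
        try:
            res = run_experiment(
                spec, fs, split,
                aug_cfg=AugmentationConfig(n_synthetic=n_synthetic, seed=spec.seed),
                train_cfg=TrainConfig(epochs=epochs, patience=6),
                arch_overrides=REDUCED_ARCH, target=target)
            row = res.row()
        except RuntimeError:  # divergent cells (large LR) count as failures
            row = {**{k: getattr(spec, k) for k in
                      ("parcellation_id", "measure", "architecture",
                       "learning_rate", "dropout", "l1_lambda", "l2_lambda",
                       "seed")},
                   "balanced_accuracy": np.nan, "log_loss": np.nan,
                   "auc": np.nan}
        rows.append(row)
    return pd.DataFrame(rows)


def power_study(seed: int, n_cells: int = 12, n_synthetic: int = 500,
                epochs: int = 60) -> pd.DataFrame:
    """Best-of-12-grid-cells on the canonical effect cohort (98/42 split)."""
    records = generate_cohort(effect_cohort_config(seed))
    feature_sets = {m: cohort_features(records, m, parcellation_id="toy16")
                    for m in ("correlation", "dtw")}
    y = feature_sets["correlation"].group_labels
    split = stratified_split(y, TRAIN_FRACTION, seed)
    specs = sample_grid_cells(n_cells, seed)
    return _run_cells(specs, feature_sets, split, n_synthetic, epochs)


def null_study(seed: int, n_specs: int = 20, n_synthetic: int = 300,
               epochs: int = 15) -> pd.DataFrame:
    """AUC distribution over specs on the matched no-effect cohort."""
    records = generate_cohort(effect_cohort_config(seed, corr_effect=0.0))
    fs = cohort_features(records, "correlation", parcellation_id="toy16")
    archs = ("ann4brains", "ann4brains_batch", "conv1d_net")
    specs = [ExperimentSpec("toy16", "correlation", archs[k % 3], 0.01,
                            (0.0, 0.3, 0.5)[k % 3], 0.0, (0.0, 0.01)[k % 2],
                            seed=k)
             for k in range(n_specs)]
    splits = [stratified_split(fs.group_labels, TRAIN_FRACTION, seed + k)
              for k in range(n_specs)]
    return _run_cells(specs, {"correlation": fs}, splits, n_synthetic, epochs)


def lag_cohort_config(seed: int, n_regions: int = 12, n_timepoints: int = 200,
                      n_pairs: int = 6, lag: int = 5) -> CohortConfig:
    """Lag-only cohort: group difference purely in timing on disjoint pairs."""
    edge_seed, cohort_seed = _seeds(seed, 2)
    edges = choose_disjoint_pairs(n_regions, n_pairs, edge_seed)
    return CohortConfig(n_subjects=140, n_regions=n_regions,
                        n_timepoints=n_timepoints, affected_edges=edges,
                        base_coupling=0.4, corr_effect=0.0, lag_effect=lag,
                        artifact_rate=0.0, seed=cohort_seed)


def lag_dissociation_study(seed: int, n_replicates: int = 10,
                           n_synthetic: int = 300,
                           epochs: int = 20) -> pd.DataFrame:
    """Best DTW spec vs best correlation spec on lag-only replicate cohorts."""
    rows = []
    for rep, rep_seed in enumerate(_seeds(seed, n_replicates)):
        records = generate_cohort(lag_cohort_config(rep_seed))
        feature_sets = {m: cohort_features(records, m, parcellation_id="toy12")
                        for m in ("correlation", "dtw")}
        y = feature_sets["correlation"].group_labels
        split = stratified_split(y, TRAIN_FRACTION, rep_seed)
        best = {}
        for measure in ("correlation", "dtw"):
            specs = [ExperimentSpec("toy12", measure, arch, 0.01, 0.3, 0.0,
                                    0.01, seed=rep_seed % 1000 + k)
                     for k, arch in enumerate(("ann4brains", "conv1d_net"))]
            table = _run_cells(specs, feature_sets, split, n_synthetic, epochs)
            best[measure] = float(np.nanmax(table["balanced_accuracy"]))
        rows.append({"replicate": rep,
                     "best_correlation": best["correlation"],
                     "best_dtw": best["dtw"],
                     "dtw_wins": best["dtw"] > best["correlation"]})
    return pd.DataFrame(rows)


def sex_control_study(seed: int, n_specs: int = 10, n_synthetic: int = 300,
                      epochs: int = 15) -> dict:
    """Sex-target control: chance when independent, strong when planted."""
    edge_seed, ind_seed, planted_seed = _seeds(seed, 3)

    def run(cfg, n):
        records = generate_cohort(cfg)
        fs = cohort_features(records, "correlation", parcellation_id="toy16")
        archs = ("ann4brains", "ann4brains_batch", "conv1d_net")
        specs = [ExperimentSpec("toy16", "correlation", archs[k % 3], 0.01,
                                (0.0, 0.3, 0.5)[k % 3], 0.0, 0.0, seed=k)
                 for k in range(n)]
        splits = [stratified_split(fs.sex_labels, TRAIN_FRACTION, cfg.seed + k)
                  for k in range(n)]
        return _run_cells(specs, {"correlation": fs}, splits, n_synthetic,
                          epochs, target="sex")

    independent = run(CohortConfig(n_subjects=140, n_regions=16,
                                   artifact_rate=0.0, seed=ind_seed), n_specs)
    planted_edges = choose_disjoint_pairs(16, 1, edge_seed)
    planted = run(CohortConfig(n_subjects=140, n_regions=16,
                               sex_effect_edges=planted_edges, sex_effect=0.6,
                               artifact_rate=0.0, seed=planted_seed),
                  max(3, n_specs // 3))
    return {
        "independent_mean_auc": float(np.nanmean(independent["auc"])),
        "planted_best_auc": float(np.nanmax(planted["auc"])),
        "independent": independent,
        "planted": planted,
    }
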