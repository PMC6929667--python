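"""Classical-pipeline evolutionary search on the effect cohort.

Searches scaler x feature-selector x classifier-family pipelines by seeded
evolution (within-training cross-validation only), then scores the winner
once on the independent fold.  Writes results/baseline_search.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import painconn as pc
from painconn import studies

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--population", type=int, default=50)
parser.add_argument("--generations", type=int, default=10)
args = parser.parse_args()
results = Path("results"); results.mkdir(exist_ok=True)

records = pc.generate_cohort(studies.effect_cohort_config(args.seed))
rows = []
for measure in ("correlation", "dtw"):
    fs = pc.cohort_features(records, measure, parcellation_id="toy16")
    train, test = pc.stratified_split(fs.group_labels, studies.TRAIN_FRACTION,
                                      args.seed)
    for metric in ("balanced_accuracy", "auc", "log_loss"):
        res = pc.classical_baseline_search(
            fs.vectors[train], fs.group_labels[train], metric=metric,
            folds=5, population=args.population,
            generations=args.generations, seed=args.seed)
        p = res.pipeline.predict_proba(fs.vectors[test])[:, 1]
        y = fs.group_labels[test]
        rows.append({
            "measure": measure, "search_metric": metric,
            "genome": str(res.genome), "cv_score": res.cv_score,
            "pipelines_evaluated": res.evaluations,
            "test_balanced_accuracy": pc.balanced_accuracy(y, (p >= 0.5).astype(int)),
            "test_auc": pc.auc(y, p),
            "test_log_loss": pc.log_loss(y, p),
        })
        print(f"{measure}/{metric}: winner {res.genome} "
              f"(cv {res.cv_score:.3f}) -> test BA "
              f"{rows[-1]['test_balanced_accuracy']:.3f}, "
              f"AUC {rows[-1]['test_auc']:.3f}")

pd.DataFrame(rows).to_csv(results / "baseline_search.csv", index=False)
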