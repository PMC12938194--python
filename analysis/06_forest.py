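"""Random-forest stage: build the 11-feature table from the selected
model's posterior means, train the classification (trial accuracy) and
regression (log RT, correct trials) forests, evaluate by OOB and grouped
5-fold CV, and rank features by 50-repeat OOB permutation importance;
finally compare the full-feature model against the Top-8 refit.
"""

import argparse
import pickle
from pathlib import Path

from ruleddm import design, features, forest

parser = argparse.ArgumentParser()
parser.add_argument("--results", default="results")
parser.add_argument("--model", type=int, default=4)
parser.add_argument("--trees", type=int, default=300)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()
out = Path(args.results)

trials = design.read_trials_csv(out / "trials_clean.csv")
with open(out / "fits.pkl", "rb") as fh:
    fits = pickle.load(fh)

ft = features.build_features(trials, fits[args.model])
ft.to_csv(out / "features.csv", index=False)
print(f"Feature table: {len(ft)} trials x {len(features.FEATURE_COLUMNS)} "
      f"features (z excluded for collinearity; Z0 retained).")

for task, target in (("classification", "Accuracy"), ("regression", "log_rt")):
    sub = ft if task == "classification" else ft[ft["Accuracy"] == 1]
    y = sub[target].to_numpy()
    cfg = forest.ForestConfig(task=task, n_trees=args.trees, seed=args.seed)
    fr = forest.train_forest(sub, y, cfg)
    oob = forest.evaluate(fr, scheme="oob")
    cv = forest.evaluate(fr, sub[forest.FEATURE_COLUMNS], y, scheme="group_cv",
                         groups=sub["participant_id"].to_numpy(), seed=args.seed)
    imp = forest.permutation_importance(fr, repeats=50, seed=args.seed)
    imp.table.sort_values("normalized", ascending=False) \
        .to_csv(out / f"importance_{task}.csv", index=False)
    topk = forest.topk_refit(sub[forest.FEATURE_COLUMNS], y, cfg, imp, k=8,
                             groups=sub["participant_id"].to_numpy(),
                             seed=args.seed)
    topk.to_csv(out / f"topk_{task}.csv", index=False)
    cv_clean = {k: round(v, 3) for k, v in cv.items() if k != "per_fold"}
    print(f"\n{task}: OOB { {k: round(v,3) for k,v in oob.items()} }, "
          f"grouped 5-fold CV {cv_clean}")
    print(f"  importance ranking: {imp.ranking()}")
    print(f"  top-8 vs full:\n{topk.round(3).to_string(index=False)}")
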