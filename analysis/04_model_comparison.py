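"""Compare the four fitted models: AIC, BIC, PSIS-LOO ELPD and the
pairwise delta-ELPD > 2 se rule; report the selected model and the
drift-rate interaction contrast of the cell-wise model.
"""

import argparse
import pickle
from pathlib import Path

from ruleddm import compare as mc, design, sampler

parser = argparse.ArgumentParser()
parser.add_argument("--results", default="results")
args = parser.parse_args()
out = Path(args.results)

trials = design.read_trials_csv(out / "trials_clean.csv")
with open(out / "fits.pkl", "rb") as fh:
    fits = pickle.load(fh)

table = mc.compare(fits, trials)
table.per_model.to_csv(out / "comparison.csv", index=False)
table.pairwise.to_csv(out / "comparison_pairwise.csv", index=False)
print(table)

mean, (lo, hi), _ = sampler.interaction_contrast(fits[4], "v")
print(f"\nDrift-rate hierarchy x block interaction contrast (cell-wise "
      f"model): {mean:.3f}, 95% HDI [{lo:.3f}, {hi:.3f}] "
      f"({'excludes' if lo > 0 or hi < 0 else 'includes'} 0)")
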