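"""Behavioural stage: participant exclusions, RT trimming, and the
3 x 5 repeated-measures ANOVA on accuracy and correct-trial RT.

Reads results/trials.csv + results/screening.csv (from 01_simulate.py);
writes the cleaned table and ANOVA/pairwise CSVs under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from ruleddm import behavior, design

parser = argparse.ArgumentParser()
parser.add_argument("--results", default="results")
args = parser.parse_args()
out = Path(args.results)

trials = design.read_trials_csv(out / "trials.csv")
fixture = pd.read_csv(out / "screening.csv")
clean = behavior.preprocess(trials, fixture)
design.write_trials_csv(clean.trials, out / "trials_clean.csv")
clean.exclusion_log.to_csv(out / "exclusions.csv", index=False)
clean.outlier_log.to_csv(out / "rt_outliers.csv", index=False)
print(f"{clean.n_participants} participants retained "
      f"({len(clean.exclusion_log)} excluded: "
      f"{dict(clean.exclusion_log['reason'].value_counts())}); "
      f"{len(clean.outlier_log)} outlier trials trimmed.")

for dv in ("accuracy", "rt"):
    res = behavior.rm_anova(clean, dv=dv)
    res.table.to_csv(out / f"anova_{dv}.csv", index=False)
    print(f"\n{res}")
    for factor in ("hierarchy", "block"):
        pw = behavior.pairwise(clean, factor=factor, dv=dv)
        pw.to_csv(out / f"pairwise_{dv}_{factor}.csv", index=False)
        sig = pw[pw["significant"]]
        print(f"  {factor} pairwise: {len(sig)}/{len(pw)} pairs significant "
              f"(Bonferroni)")
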