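"""Posterior predictive check of the selected model: simulate replicate
data at the posterior means and compare per-cell accuracy and RT
quantiles (.1/.3/.5/.7/.9) against the observations.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from ruleddm import design, ppc

parser = argparse.ArgumentParser()
parser.add_argument("--results", default="results")
parser.add_argument("--model", type=int, default=4)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()
out = Path(args.results)

trials = design.read_trials_csv(out / "trials_clean.csv")
with open(out / "fits.pkl", "rb") as fh:
    fits = pickle.load(fh)

report = ppc.posterior_predictive_check(fits[args.model], trials, seed=args.seed)
report.table.to_csv(out / f"ppc_m{args.model}.csv", index=False)
print(report)
worst = report.table.sort_values("max_abs_rt_q_diff").iloc[-1]
print(f"Worst cell: block {int(worst['block'])}, hierarchy "
      f"{int(worst['hierarchy'])} (observed median RT "
      f"{worst['obs_rt_q50']:.2f}s vs simulated {worst['sim_rt_q50']:.2f}s)")
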