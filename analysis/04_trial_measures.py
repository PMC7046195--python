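#!/usr/bin/env python
"""Trial-level feedback-processing measures at the fitted parameters.

For each participant, runs the change-point observer at that
participant's posterior-median parameters over their own probabilistic
block and writes per-trial surprisal, belief-update KL divergence,
predictive entropy and predictive target probability -- the table that
trial-level regressions of feedback processing consume -- together with
the behavioral table (accuracy, disambiguating trials, perseverative
errors).
"""

import argparse
from pathlib import Path

import pandas as pd

from revlearn.association import behavior_metrics
from revlearn.bcp import BCPParams, bcp_measures_table
from revlearn.io import read_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--condition", default="probabilistic")
    args = ap.parse_args()

    ds = read_dataset(args.results / "dataset")
    med = pd.read_csv(
        args.results / "fits" / f"medians_BCP_{args.condition}.csv",
        index_col="participant_id",
    )

    meas, behav = [], []
    for p in ds.participants:
        row = med.loc[p.id]
        params = BCPParams(h=row["h"], gamma=row["gamma"], epsilon=row["epsilon"])
        meas.append(bcp_measures_table(params, p.blocks[args.condition], p.id))
        tab = behavior_metrics(p.blocks[args.condition], p.responses[args.condition])
        tab.insert(0, "participant_id", p.id)
        behav.append(tab)

    measures = pd.concat(meas, ignore_index=True)
    behavior = pd.concat(behav, ignore_index=True)
    measures.to_csv(args.results / "measures.csv", index=False)
    behavior.to_csv(args.results / "behavior.csv", index=False)

    by_valid = measures.groupby("valid")["surprisal"].mean()
    print(f"wrote {len(measures)} measure rows, {len(behavior)} behavior rows")
    print(f"mean surprisal: valid trials {by_valid.get(True, float('nan')):.3f}, "
          f"invalid trials {by_valid.get(False, float('nan')):.3f}")
    print(f"mean accuracy {behavior['accuracy'].mean():.3f}; "
          f"{behavior['is_perseverative_error'].sum()} perseverative errors")


if __name__ == "__main__":
    main()
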