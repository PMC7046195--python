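#!/usr/bin/env python
"""Symptom-parameter associations with permutation tests.

Correlates the fitted posterior medians (transition uncertainty,
observation uncertainty, lapse rate) with the OCI-R total and the
DASS-21 subscales per condition, using permutation tests, plus the
partial correlation of OCI-R controlling for depressive symptoms.
Participants flagged by the exclusion screen are dropped first.
"""

import argparse
from pathlib import Path

import pandas as pd

from revlearn.association import headline_analysis
from revlearn.io import read_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=4)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--n-perm", type=int, default=10_000)
    args = ap.parse_args()

    ds = read_dataset(args.results / "dataset")
    medians = {}
    for f in sorted((args.results / "fits").glob("medians_BCP_*.csv")):
        cond = f.stem.split("_", 2)[2]
        medians[cond] = pd.read_csv(f, index_col="participant_id")

    excluded = []
    excl_file = args.results / "exclusions.csv"
    if excl_file.exists():
        flags = pd.read_csv(excl_file, index_col=0)
        excluded = list(flags.index[flags["excluded"]])
        if excluded:
            print(f"excluding {len(excluded)} chance-level participant(s)")

    report = headline_analysis(
        ds, medians, excluded=excluded, n_perm=args.n_perm, seed=args.seed
    )
    report.to_csv(args.results / "associations.csv", index=False)

    key = report[
        (report["parameter"] == "transition_uncertainty")
        & (report["scale"] == "ocir")
    ]
    for _, row in key.iterrows():
        print(f"OCI-R ~ transition uncertainty ({row['condition']}): "
              f"r = {row['r']:.3f}, permutation p = {row['p']:.4f} "
              f"(n = {row['n']}, {row['n_perm']} permutations)")


if __name__ == "__main__":
    main()
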