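#!/usr/bin/env python
"""Compare the fitted models: WAIC, PSIS-LOO, weights, absolute fit.

Reads the posteriors written by 02_fit_models.py, tabulates relative fit
per condition with Akaike weights (WAIC) and pseudo-BMA weights
(PSIS-LOO), computes per-participant posterior-predictive absolute fit,
and applies the chance-level exclusion screen (near-chance absolute fit
in every condition together with a high fitted lapse rate).
"""

import argparse
from pathlib import Path

import pandas as pd

from revlearn.compare import absolute_fit_table, comparison_table
from revlearn.hierfit import exclusion_screen
from revlearn.io import read_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--n-draws-absfit", type=int, default=100)
    args = ap.parse_args()

    ds = read_dataset(args.results / "dataset")
    fits_dir = args.results / "fits"
    draws_files = sorted(fits_dir.glob("draws_*.pkl"))
    by_cond: dict[str, dict] = {}
    for f in draws_files:
        _, model, cond = f.stem.split("_", 2)
        by_cond.setdefault(cond, {})[model] = pd.read_pickle(f)

    comp_rows, abs_rows = [], []
    for cond, fits in by_cond.items():
        comp = comparison_table(fits)
        comp_rows.append(comp)
        abs_rows.append(
            absolute_fit_table(fits, ds, n_draws=args.n_draws_absfit, seed=args.seed)
        )
        best = comp.sort_values("waic").iloc[0]
        print(f"{cond}: best model by WAIC is {best['model']} "
              f"(WAIC {best['waic']:.1f}, Akaike weight {best['akaike_weight']:.2f})")

    comparison = pd.concat(comp_rows, ignore_index=True)
    absfit = pd.concat(abs_rows, ignore_index=True)
    comparison.to_csv(args.results / "comparison.csv", index=False)
    absfit.to_csv(args.results / "absolute_fit.csv", index=False)

    primary = "BCP"
    wide = absfit[absfit["model"] == primary].pivot(
        index="participant_id", columns="condition", values="absolute_fit"
    )
    eps = pd.DataFrame({
        cond: pd.read_csv(
            args.results / "fits" / f"medians_{primary}_{cond}.csv",
            index_col="participant_id",
        )["epsilon"]
        for cond in by_cond
    })
    flags = exclusion_screen(wide, eps)
    flags.to_csv(args.results / "exclusions.csv")
    n_flagged = int(flags["excluded"].sum())
    print(f"mean absolute fit ({primary}): "
          + ", ".join(f"{c}={wide[c].mean():.3f}" for c in wide.columns))
    print(f"{n_flagged} participant(s) flagged as chance-level responders")


if __name__ == "__main__":
    main()
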