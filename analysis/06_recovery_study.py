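#!/usr/bin/env python
"""Parameter-recovery study: can the fitted values be trusted?

Simulates cohorts at known ground truth, refits them, and tabulates
true-vs-recovered rank correlations, bias, and posterior interval widths
per parameter and condition. This underwrites the interpretability of
the fitted transition-uncertainty values used in the association
analysis.
"""

import argparse
from pathlib import Path

from revlearn.pipeline import run_recovery_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=5)
    ap.add_argument("--n-participants", type=int, default=30)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = {
        "seed": args.seed,
        "simulate": {"n_participants": args.n_participants},
        "fit": {
            "models": ["BCP"],
            "conditions": ["deterministic", "probabilistic"],
            "chains": 2,
            "iterations": 750,
            "warmup": 250,
            "max_escalations": 1,
        },
    }
    table = run_recovery_study(cfg, args.results / "recovery")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    h = table[table["parameter"] == "h"]
    print("\ntransition uncertainty recovers with Spearman "
          + ", ".join(f"{r.condition}={r.spearman:.2f}" for r in h.itertuples()))


if __name__ == "__main__":
    main()
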