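#!/usr/bin/env python
"""Residual heterosis of the F4 crosses over their mid-parent values.

Ranks crosses per environment for 100-grain weight (higher is better) and
NS_max (negative heterosis = fewer Striga than the mid-parent, desirable).
"""

import argparse
from pathlib import Path

import pandas as pd

from strigascreen import heterosis, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    joined = pd.read_csv(args.outdir / "plot_summary.csv", na_values=["NA"])
    crosses = io.read_cross_registry(args.datadir / "crosses.csv")
    desirability = {"HGW": "higher_better", "NS_max": "lower_better"}

    for env in ("field", "pot"):
        records = joined[joined["environment"] == env]
        table, exclusions = heterosis.heterosis_table(
            records, crosses, list(desirability), env
        )
        for trait, direction in desirability.items():
            ranked = heterosis.rank_crosses(table, trait, direction)
            ranked.to_csv(
                args.outdir / f"heterosis_{trait}_{env}.csv", index=False
            )
            best = ranked.iloc[0]
            print(
                f"[{env}] {trait}: best cross {best['cross_id']} "
                f"({best['residual_heterosis_pct']:+.2f}% vs mid-parent); "
                f"{(ranked['residual_heterosis_pct'] < 0).sum()}/{len(ranked)} "
                f"crosses below mid-parent"
            )
        if exclusions:
            print(f"[{env}] excluded: {len(exclusions)} cross-trait records")


if __name__ == "__main__":
    main()
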