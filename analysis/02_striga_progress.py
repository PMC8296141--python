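#!/usr/bin/env python
"""Per-plot Striga progress statistics (ASNPC, NS_max, first emergence).

Reads the count series written by 01_simulate_study.py, computes the
progress statistics, joins them onto the plot trait table and reports the
most resistant and most susceptible genotypes per environment by mean ASNPC.
"""

import argparse
from pathlib import Path

from strigascreen import io, striga


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    traits = io.read_trait_table(args.datadir / "traits.csv")
    series = io.read_striga_counts(args.datadir / "striga_counts.csv")
    joined = striga.join_with_traits(traits, series)
    joined.to_csv(args.outdir / "plot_summary.csv", index=False, na_rep="NA")
    summary = striga.summarize_plots(series)
    summary.to_csv(args.outdir / "striga_summary.csv", index=False, na_rep="NA")

    for env in ("field", "pot"):
        sub = joined[joined["environment"] == env]
        means = sub.groupby("genotype_id")["ASNPC"].mean().sort_values()
        print(f"[{env}] mean ASNPC {means.mean():.0f} (count-days)")
        print(f"  most resistant:   {', '.join(f'{g} ({v:.0f})' for g, v in means.head(3).items())}")
        print(f"  most susceptible: {', '.join(f'{g} ({v:.0f})' for g, v in means.tail(3).items())}")


if __name__ == "__main__":
    main()
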