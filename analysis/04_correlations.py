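#!/usr/bin/env python
"""Within-trial and field-vs-pot trait correlations on genotype means."""

import argparse
from pathlib import Path

import pandas as pd

from strigascreen import correlation, pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    joined = pd.read_csv(args.outdir / "plot_summary.csv", na_values=["NA"])
    traits = [t for t in list(pipeline.RunConfig().traits) + ["ASNPC", "NS_max"]
              if t in joined.columns]
    field = joined[joined["environment"] == "field"]
    pot = joined[joined["environment"] == "pot"]

    for env, sub in (("field", field), ("pot", pot)):
        r, p, _ = correlation.trait_correlation_matrix(sub, traits, env)
        r.to_csv(args.outdir / f"correlation_r_{env}.csv")
        p.to_csv(args.outdir / f"correlation_p_{env}.csv")
        n_sig = int(((p < 0.05).to_numpy().sum() - len(traits)) // 2)
        print(f"[{env}] significant trait pairs (P<0.05): {n_sig}")
        print(
            f"  ASNPC~NS_max r = {r.loc['ASNPC', 'NS_max']:.2f}, "
            f"ASNPC~NSFC r = {r.loc['ASNPC', 'NSFC']:.2f}, "
            f"HGW~ASNPC r = {r.loc['HGW', 'ASNPC']:.2f}"
        )

    across = correlation.cross_trial_table(field, pot, traits)
    across.to_csv(args.outdir / "cross_trial_correlation.csv", index=False)
    print("field vs pot correlation of genotype means:")
    for _, row in across.iterrows():
        print(f"  {row['trait']:7s} r = {row['r']:+.2f} {row['stars']}")


if __name__ == "__main__":
    main()
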