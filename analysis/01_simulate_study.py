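#!/usr/bin/env python
"""Generate the synthetic two-environment screening study.

Writes the complete study — plot trait tables for the field and pot trials,
per-plot Striga count series, the cross registry and the parent/progeny SNP
matrix — as delimited text under results/data/, ready for the downstream
analysis scripts.
"""

import argparse
from pathlib import Path

import pandas as pd

from strigascreen import io
from strigascreen.simulate import simulate_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    bundle = simulate_study(seed=args.seed)
    traits = pd.concat([bundle.field_traits, bundle.pot_traits], ignore_index=True)
    io.write_trait_table(traits, args.outdir / "traits.csv")
    io.write_striga_counts(
        bundle.field_counts + bundle.pot_counts, args.outdir / "striga_counts.csv"
    )
    io.write_cross_registry(bundle.crosses, args.outdir / "crosses.csv")
    io.write_cross_registry(bundle.snp_crosses, args.outdir / "snp_crosses.csv")
    io.write_snp_matrix(bundle.snps, args.outdir / "snps.csv")

    classes = pd.Series(
        [g.material_class.value for g in bundle.genotypes]
    ).value_counts()
    print(f"simulated study (seed {args.seed}) written to {args.outdir}/")
    print(f"  genotypes: {len(bundle.genotypes)} ({classes.to_dict()})")
    print(f"  plots: {len(traits)} across 2 environments x 3 replicates")
    print(
        f"  SNP matrix: {bundle.snps.n_samples} samples x {bundle.snps.n_markers} markers"
    )
    print(f"  genotyped crosses: {bundle.snp_crosses['cross_id'].nunique()}")


if __name__ == "__main__":
    main()
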