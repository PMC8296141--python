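#!/usr/bin/env python
"""SNP filtering, ABH hybridity confirmation and NJ diversity tree.

Filters the SNP matrix on call rate and minor-allele frequency, confirms
hybridity of the genotyped F4 progenies via ABH heterozygosity at
informative markers, and builds the identity-by-state neighbor-joining
dendrogram of the non-progeny panel.
"""

import argparse
from pathlib import Path

from strigascreen import genotyping, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    snps = io.read_snp_matrix(args.datadir / "snps.csv")
    crosses = io.read_cross_registry(args.datadir / "snp_crosses.csv")

    filtered, report = genotyping.filter_snps(snps)
    print(
        f"SNP filtering: {report['n_markers_in']} -> {report['n_markers_out']} markers "
        f"(call rate >= {report['min_call_rate']}, MAF >= {report['min_maf']})"
    )

    hybridity, exclusions = genotyping.hybridity_table(filtered, crosses)
    hybridity.to_csv(args.outdir / "hybridity.csv", index=False)
    print(f"hybridity confirmed for {len(hybridity)} crosses:")
    for _, row in hybridity.head(5).iterrows():
        print(
            f"  {row['cross_id']}: {row['n_progeny_tested']} progeny, "
            f"{row['n_biallelic_markers']} biallelic markers, "
            f"het {row['het_pct_min']:.1f}-{row['het_pct_max']:.1f}%"
        )
    if len(hybridity) > 5:
        print(f"  ... and {len(hybridity) - 5} more (see hybridity.csv)")
    if exclusions:
        print(f"excluded crosses: {exclusions}")

    progeny_ids = set(crosses["id"])
    panel = filtered.subset(
        sample_ids=[s for s in filtered.sample_ids if s not in progeny_ids]
    )
    dm = genotyping.ibs_distance(panel)
    tree = genotyping.neighbor_joining(dm)
    dm.to_data_frame().to_csv(args.outdir / "ibs_distance.csv")
    io.write_newick(tree, args.outdir / "nj_tree.nwk")
    print(
        f"NJ dendrogram over {panel.n_samples} panel accessions "
        f"written to nj_tree.nwk (mean IBS distance "
        f"{dm.condensed_form().mean():.3f})"
    )


if __name__ == "__main__":
    main()
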