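#!/usr/bin/env python
"""Lattice ANOVA, variance components, heritability and Fisher's LSD.

Fits the fixed-effects incomplete-block ANOVA per trait and environment,
partitions the genotype sum of squares into parents vs progenies, pools the
two environments, derives sigma2_g/sigma2_e/GCV/PCV/H2 and prints the
heritability classification per trait.
"""

import argparse
from pathlib import Path

import pandas as pd

from strigascreen import anova, correlation, io, pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    joined = pd.read_csv(args.outdir / "plot_summary.csv", na_values=["NA"])
    crosses = io.read_cross_registry(args.datadir / "crosses.csv")
    progenies = set(crosses["id"])
    traits = [t for t in list(pipeline.RunConfig().traits) + ["ASNPC", "NS_max"]
              if t in joined.columns]

    anova_rows, vc_rows = [], []
    for env in ("field", "pot"):
        sub = joined[joined["environment"] == env]
        parents = sorted(set(sub["genotype_id"]) - progenies)
        progeny_list = sorted(set(sub["genotype_id"]) & progenies)
        for trait in traits:
            table = anova.fit_anova(sub, trait, "lattice")
            part = anova.partition_genotype_ss(sub, trait, parents, progeny_list)
            full = pd.concat(
                [table.reset_index(), part.drop(index="Residual").reset_index()]
            ).assign(trait=trait, environment=env)
            anova_rows.append(full)
            vc_rows.append(vars(anova.variance_component_summary(sub, trait, env)))

    pd.concat(anova_rows, ignore_index=True).to_csv(
        args.outdir / "anova_tables.csv", index=False, na_rep="NA"
    )
    vc = pd.DataFrame(vc_rows)
    vc.to_csv(args.outdir / "variance_components.csv", index=False)

    combined = []
    field = joined[joined["environment"] == "field"]
    pot = joined[joined["environment"] == "pot"]
    for trait in traits:
        tab = anova.combined_environment_anova(field, pot, trait)
        combined.append(tab.reset_index().assign(trait=trait))
    pd.concat(combined, ignore_index=True).to_csv(
        args.outdir / "anova_combined.csv", index=False, na_rep="NA"
    )

    print("broad-sense heritability by trait (field / pot):")
    for trait in traits:
        sel = vc[vc["trait"] == trait].set_index("environment")
        f, p = sel.loc["field"], sel.loc["pot"]
        print(
            f"  {trait:7s} H2 = {f['h2_pct']:5.1f}% ({f['h2_class']}) / "
            f"{p['h2_pct']:5.1f}% ({p['h2_class']})   "
            f"GCV {f['gcv_pct']:.1f}%, PCV {f['pcv_pct']:.1f}% in field"
        )
    # Fisher's protected LSD for the headline yield component
    sub = field
    table = anova.fit_anova(sub, "HGW")
    lsd = anova.fisher_lsd(
        correlation.genotype_means(sub, "HGW"),
        table.loc["Residual", "mean_sq"],
        int(table.loc["Residual", "df"]),
        int(sub["replicate"].nunique()),
        f_p_value=float(table.loc["Genotype", "p"]),
    )
    print(f"field HGW: LSD(5%) = {lsd.lsd:.3f} g, protected = {lsd.protected}")


if __name__ == "__main__":
    main()
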