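"""End-to-end orchestration of the trial analyses.

The three pipelines mirror the study's results structure: the phenotypic
pipeline produces per-environment Striga summaries, ANOVA tables with the
parents/progenies partition, variance components with GCV/PCV and
broad-sense heritability, LSD groupings, correlation tables, top/bottom-10
rankings and the combined-environment ANOVA; the genotypic pipeline produces
the SNP filtering report, the per-cross hybridity table, the IBS matrix and
the neighbor-joining tree; the heterosis pipeline produces the ranked
residual-heterosis tables for HGW (higher is better) and NS_max (lower is
better).  Runs are deterministic given the configuration and seed, and every
run writes a ``manifest.json`` with the config hash, seed and table list.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, anova, correlation, genotyping, heterosis, io, striga
from .model import MaterialClass, TRAIT_COLUMNS
from .simulate import StudyBundle, simulate_study

logger = logging.getLogger(__name__)

#: Striga progress statistics appended to the trait list by the pipeline.
STRIGA_TRAITS = ("ASNPC", "NS_max")

DEFAULT_DESIRABILITY = {"HGW": "higher_better", "NS_max": "lower_better"}


@dataclass
class RunConfig:
    """Configuration of a pipeline run (inputs or simulation, and options)."""

    # input paths; when None, the study is simulated from `seed`
    traits_path: Optional[str] = None
    counts_path: Optional[str] = None
    snps_path: Optional[str] = None
    crosses_path: Optional[str] = None
    snp_crosses_path: Optional[str] = None
    traits: list = field(default_factory=lambda: list(TRAIT_COLUMNS))
    model: str = "lattice"
    alpha: float = 0.05
    min_call_rate: float = 0.80
    min_maf: float = 0.05
    desirability: dict = field(default_factory=lambda: dict(DEFAULT_DESIRABILITY))
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_or_simulate(config: RunConfig) -> StudyBundle:
    if config.traits_path is None:
        return simulate_study(seed=config.seed)
    traits = io.read_trait_table(config.traits_path)
    counts = io.read_striga_counts(config.counts_path) if config.counts_path else []
    crosses = (
        io.read_cross_registry(config.crosses_path)
        if config.crosses_path
        else pd.DataFrame(columns=["id", "female", "male", "cross_id"])
    )
    snps = io.read_snp_matrix(config.snps_path) if config.snps_path else None
    snp_crosses = (
        io.read_cross_registry(config.snp_crosses_path)
        if config.snp_crosses_path
        else crosses
    )
    return StudyBundle(
        genotypes=[],
        crosses=crosses,
        field_traits=traits[traits["environment"] == "field"],
        pot_traits=traits[traits["environment"] == "pot"],
        field_counts=[s for s in counts if s.environment == "field"],
        pot_counts=[s for s in counts if s.environment == "pot"],
        snps=snps,
        snp_crosses=snp_crosses,
    )


def _parent_progeny_ids(bundle: StudyBundle, records: pd.DataFrame):
    if bundle.genotypes:
        progenies = {g.id for g in bundle.genotypes if g.material_class is MaterialClass.F4}
    elif len(bundle.crosses):
        progenies = set(bundle.crosses["id"])
    else:
        return None, None
    observed = set(records["genotype_id"].astype(str))
    return sorted(observed - progenies), sorted(observed & progenies)


def run_phenotypic_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Striga summaries, ANOVA, variance components, LSD, correlations, ranks."""
    bundle = _load_or_simulate(config)
    tables: dict[str, pd.DataFrame] = {}
    joined = {}
    for env, records, counts in (
        ("field", bundle.field_traits, bundle.field_counts),
        ("pot", bundle.pot_traits, bundle.pot_counts),
    ):
        df = striga.join_with_traits(records, counts) if counts else records.copy()
        joined[env] = df
        tables[f"striga_summary_{env}"] = striga.summarize_plots(counts) if counts else pd.DataFrame()

        traits = [t for t in list(config.traits) + list(STRIGA_TRAITS) if t in df.columns]
        anova_rows, vc_rows, lsd_rows, rank_frames = [], [], [], []
        parents, progenies = _parent_progeny_ids(bundle, df)
        for trait in traits:
            try:
                table = anova.fit_anova(df, trait, config.model)
            except ValueError as exc:
                logger.warning("phenotype[%s] ANOVA %s skipped: %s", env, trait, exc)
                continue
            tab = table.reset_index().assign(trait=trait)
            if parents and progenies:
                part = anova.partition_genotype_ss(
                    df, trait, parents, progenies, config.model
                )
                tab = pd.concat(
                    [tab, part.drop(index="Residual").reset_index().assign(trait=trait)]
                )
            anova_rows.append(tab)

            vc = anova.variance_component_summary(df, trait, env, config.model)
            vc_rows.append(vars(vc))

            means = correlation.genotype_means(df[df[trait].notna()], trait)
            lsd = anova.fisher_lsd(
                means,
                table.loc["Residual", "mean_sq"],
                int(table.loc["Residual", "df"]),
                int(df["replicate"].nunique()),
                alpha=config.alpha,
                f_p_value=float(table.loc["Genotype", "p"]),
            )
            lsd_rows.append(
                {"trait": trait, "lsd": lsd.lsd, "protected": lsd.protected}
            )
            if trait in config.desirability:
                asc = config.desirability[trait] == "lower_better"
                ranked = means.sort_values(ascending=asc)
                rank_frames.append(
                    pd.DataFrame(
                        {
                            "trait": trait,
                            "genotype_id": list(ranked.index[:10]) + list(ranked.index[-10:]),
                            "mean": list(ranked.iloc[:10]) + list(ranked.iloc[-10:]),
                            "group": ["top10"] * min(10, len(ranked))
                            + ["bottom10"] * min(10, len(ranked)),
                        }
                    )
                )
        tables[f"anova_{env}"] = pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()
        tables[f"variance_components_{env}"] = pd.DataFrame(vc_rows)
        tables[f"lsd_{env}"] = pd.DataFrame(lsd_rows)
        if rank_frames:
            tables[f"rankings_{env}"] = pd.concat(rank_frames, ignore_index=True)

        r, p, n = correlation.trait_correlation_matrix(df, traits, env)
        tables[f"correlation_r_{env}"] = r
        tables[f"correlation_p_{env}"] = p

    # across-trial correlations and combined ANOVA
    shared_traits = [
        t
        for t in list(config.traits) + list(STRIGA_TRAITS)
        if t in joined["field"].columns and t in joined["pot"].columns
    ]
    tables["cross_trial_correlation"] = correlation.cross_trial_table(
        joined["field"], joined["pot"], shared_traits
    )
    combined_rows = []
    for trait in shared_traits:
        try:
            tab = anova.combined_environment_anova(
                joined["field"], joined["pot"], trait, config.model
            )
        except ValueError as exc:
            logger.warning("combined ANOVA %s skipped: %s", trait, exc)
            continue
        combined_rows.append(tab.reset_index().assign(trait=trait))
    tables["anova_combined"] = (
        pd.concat(combined_rows, ignore_index=True) if combined_rows else pd.DataFrame()
    )
    tables["_joined_field"] = joined["field"]
    tables["_joined_pot"] = joined["pot"]
    return tables


def run_heterosis_pipeline(
    config: RunConfig, phenotype_tables: Optional[dict] = None
) -> dict[str, pd.DataFrame]:
    """Per-environment ranked residual-heterosis tables for HGW and NS_max."""
    if phenotype_tables is None:
        phenotype_tables = run_phenotypic_pipeline(config)
    bundle = _load_or_simulate(config)
    tables: dict[str, pd.DataFrame] = {}
    traits = [t for t in config.desirability]
    for env in ("field", "pot"):
        records = phenotype_tables[f"_joined_{env}"]
        het, exclusions = heterosis.heterosis_table(
            records, bundle.crosses, traits, env
        )
        tables[f"heterosis_{env}"] = het
        for trait in traits:
            if trait in het["trait"].values:
                tables[f"heterosis_rank_{trait}_{env}"] = heterosis.rank_crosses(
                    het, trait, config.desirability[trait]
                )
        if exclusions:
            tables[f"heterosis_exclusions_{env}"] = pd.DataFrame(
                {"reason": exclusions}
            )
    return tables


def run_genotypic_pipeline(config: RunConfig) -> dict:
    """SNP filtering report, hybridity table, IBS matrix and NJ tree."""
    bundle = _load_or_simulate(config)
    if bundle.snps is None:
        raise ValueError("genotypic pipeline requires SNP input or simulation")
    filtered, report = genotyping.filter_snps(
        bundle.snps, config.min_call_rate, config.min_maf
    )
    hybridity, exclusions = genotyping.hybridity_table(filtered, bundle.snp_crosses)
    # diversity tree over the non-progeny panel (parents, wild, landraces)
    progeny_ids = set(bundle.snp_crosses["id"])
    panel_ids = [s for s in filtered.sample_ids if s not in progeny_ids]
    panel = filtered.subset(sample_ids=panel_ids)
    dm = genotyping.ibs_distance(panel)
    tree = genotyping.neighbor_joining(dm)
    out = {
        "filter_report": pd.DataFrame([report]),
        "hybridity": hybridity,
        "ibs_distance": dm.to_data_frame(),
        "tree": tree,
    }
    if exclusions:
        out["hybridity_exclusions"] = pd.DataFrame({"reason": exclusions})
    return out


def write_tables(tables: dict, config: RunConfig) -> Path:
    """Write every table (and tree) to the output directory with a manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in tables.items():
        if name.startswith("_"):
            continue
        if hasattr(obj, "write"):  # TreeNode
            path = outdir / f"{name}.nwk"
            io.write_newick(obj, path)
        else:
            path = outdir / f"{name}.csv"
            index = name.startswith(("correlation_", "ibs_"))
            obj.to_csv(path, index=index, na_rep="NA")
        written.append(path.name)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "tables": sorted(written),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def run_all(config: RunConfig) -> dict:
    """Run the phenotypic, heterosis and genotypic pipelines."""
    tables = run_phenotypic_pipeline(config)
    tables.update(run_heterosis_pipeline(config, tables))
    tables.update(run_genotypic_pipeline(config))
    return tables
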