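"""Synthetic study generator with known ground truth.

Emulates the screening trial's structure so every downstream stage is
testable by parameter recovery: a resolvable square-lattice layout (64
genotypes, 3 replicates, blocks of 8) in two environments, an additive
Gaussian trait model with chosen genotypic and error variances,
genotype-dependent *Striga* emergence-count curves over the biweekly
assessment dates, fully homozygous inbred parent SNP panels, and selfed
progeny advanced to a chosen filial generation (F1 -> F4) from homozygous
parents.  Every simulator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenotypeEntry, MaterialClass, SNPMatrix, StrigaCountSeries

# Default trait means, loosely calibrated to the field-trial scale of the
# study system (days, grams, centimeters, t/ha, 1-9 scores, counts).
DEFAULT_TRAIT_MEANS = {
    "DTF": 75.0,
    "DPW": 55.0,
    "PH": 180.0,
    "YLD": 2.5,
    "HGW": 2.6,
    "ODS": 4.0,
    "OPS": 4.0,
    "NSFC": 12.0,
}

# Genotypic / error variances giving moderate-to-high heritabilities of the
# kind the trial reports for yield components.
DEFAULT_SIGMA2_G = {
    "DTF": 100.0,
    "DPW": 150.0,
    "PH": 2000.0,
    "YLD": 1.2,
    "HGW": 0.55,
    "ODS": 1.0,
    "OPS": 1.0,
    "NSFC": 40.0,
}
DEFAULT_SIGMA2_E = {
    "DTF": 50.0,
    "DPW": 100.0,
    "PH": 400.0,
    "YLD": 0.8,
    "HGW": 0.75,
    "ODS": 0.6,
    "OPS": 0.6,
    "NSFC": 30.0,
}

#: Biweekly Striga assessment schedule (days after sowing) and the expected
#: emerged-count curve of a fully susceptible field plot: emergence builds
#: after first attachment and plateaus toward crop maturity.
DEFAULT_ASSESSMENT_DAYS = (49, 63, 77, 91)
DEFAULT_BASELINE_CURVE = (8.0, 25.0, 45.0, 55.0)


@dataclass
class TrialSimParams:
    """Layout and additive trait model of one simulated trial."""

    n_genotypes: int = 64
    n_reps: int = 3
    block_size: int = 8
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    sigma2_g: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA2_G))
    sigma2_e: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA2_E))
    # replicate and block-within-replicate effect variances, as a fraction
    # of sigma2_e (the design is specified by the study; the generative
    # nuisance scale is a modeling choice)
    rep_block_var_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes % self.block_size != 0:
            raise ValueError(
                f"{self.n_genotypes} genotypes not divisible into blocks of "
                f"{self.block_size}"
            )
        for name, d in (("sigma2_g", self.sigma2_g), ("sigma2_e", self.sigma2_e)):
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name} must be non-negative")


@dataclass
class StrigaSimParams:
    """Emergence-curve model for the per-plot Striga count series."""

    assessment_days: tuple = DEFAULT_ASSESSMENT_DAYS
    baseline_curve: tuple = DEFAULT_BASELINE_CURVE
    genotype_susceptibility: dict = field(default_factory=dict)
    # negative-binomial dispersion k (variance = mu + mu^2 / k);
    # None = Poisson limit
    overdispersion: Optional[float] = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.assessment_days) != len(self.baseline_curve):
            raise ValueError("assessment_days and baseline_curve lengths differ")
        if any(b < 0 for b in self.baseline_curve):
            raise ValueError("baseline_curve must be non-negative")
        if any(s < 0 for s in self.genotype_susceptibility.values()):
            raise ValueError("susceptibility multipliers must be >= 0")


def make_study_genotypes(
    n_wild: int = 17,
    n_landrace: int = 8,
    n_improved: int = 13,
    n_f4: int = 26,
    seed: int = 0,
) -> list[GenotypeEntry]:
    """Entry list mirroring the trial's germplasm composition.

    Parents of the F4 crosses are drawn from the improved varieties and
    landraces, as in the study's crossing scheme.
    """
    rng = np.random.default_rng(seed)
    entries = [
        GenotypeEntry(f"WILD{i + 1:02d}", MaterialClass.WILD) for i in range(n_wild)
    ]
    entries += [
        GenotypeEntry(f"LR{i + 1:02d}", MaterialClass.LANDRACE) for i in range(n_landrace)
    ]
    entries += [
        GenotypeEntry(f"IMP{i + 1:02d}", MaterialClass.IMPROVED) for i in range(n_improved)
    ]
    parent_pool = [e.id for e in entries if e.material_class is not MaterialClass.WILD]
    seen = set()
    f4 = []
    while len(f4) < n_f4:
        female, male = rng.choice(parent_pool, size=2, replace=False)
        if (female, male) in seen:
            continue
        seen.add((female, male))
        f4.append(
            GenotypeEntry(
                f"F4-{len(f4) + 1:02d}",
                MaterialClass.F4,
                female_parent=str(female),
                male_parent=str(male),
            )
        )
    return entries + f4


def cross_registry_frame(genotypes: Sequence[GenotypeEntry]) -> pd.DataFrame:
    """Cross registry (id, female, male, cross_id) for the F4 entries."""
    rows = [
        {
            "id": g.id,
            "female": g.female_parent,
            "male": g.male_parent,
            "cross_id": g.cross_id,
        }
        for g in genotypes
        if g.material_class is MaterialClass.F4
    ]
    return pd.DataFrame(rows, columns=["id", "female", "male", "cross_id"])


def simulate_trial(
    params: TrialSimParams,
    genotype_ids: Optional[Sequence[str]] = None,
    environment: str = "field",
    genotype_effects: Optional[dict] = None,
) -> pd.DataFrame:
    """Simulate one trial's plot trait table under the additive model.

    value = trait mean + genotype effect (drawn once per genotype,
    variance sigma2_g) + replicate effect + block-within-replicate effect
    + plot error (variance sigma2_e).  Each replicate is a complete
    permutation of the genotypes partitioned into incomplete blocks of
    ``block_size`` (a resolvable lattice layout).

    ``genotype_effects`` may pin chosen effects, e.g.
    ``{"HGW": {"F4-01": 1.2}}``, overriding the random draw for those
    genotypes — used to inject known heterosis or null effects.
    """
    rng = np.random.default_rng(params.seed)
    if genotype_ids is None:
        genotype_ids = [f"G{i + 1:03d}" for i in range(params.n_genotypes)]
    genotype_ids = list(genotype_ids)
    if len(genotype_ids) != params.n_genotypes:
        raise ValueError("genotype_ids length must equal n_genotypes")
    traits = list(params.trait_means)
    n_blocks = params.n_genotypes // params.block_size

    effects = {}
    for t in traits:
        draw = rng.normal(0.0, np.sqrt(params.sigma2_g[t]), size=params.n_genotypes)
        eff = dict(zip(genotype_ids, draw))
        if genotype_effects and t in genotype_effects:
            eff.update(genotype_effects[t])
        effects[t] = eff

    nuisance_sd = {
        t: np.sqrt(params.rep_block_var_fraction * params.sigma2_e[t]) for t in traits
    }
    rep_eff = {t: rng.normal(0.0, nuisance_sd[t], size=params.n_reps) for t in traits}
    block_eff = {
        t: rng.normal(0.0, nuisance_sd[t], size=(params.n_reps, n_blocks))
        for t in traits
    }

    rows = []
    for rep in range(params.n_reps):
        order = rng.permutation(params.n_genotypes)
        for pos, gi in enumerate(order):
            block = pos // params.block_size
            row = {
                "plot_id": f"{environment[0].upper()}R{rep + 1}P{pos + 1:03d}",
                "environment": environment,
                "genotype_id": genotype_ids[gi],
                "replicate": rep + 1,
                "block": block + 1,
            }
            for t in traits:
                value = (
                    params.trait_means[t]
                    + effects[t][genotype_ids[gi]]
                    + rep_eff[t][rep]
                    + block_eff[t][rep, block]
                    + rng.normal(0.0, np.sqrt(params.sigma2_e[t]))
                )
                if t in ("ODS", "OPS"):
                    value = float(np.clip(value, 1.0, 9.0))
                elif t in ("DPW", "PH", "YLD", "HGW", "NSFC", "DTF"):
                    value = max(value, 0.0)
                row[t] = value
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_striga_series(
    trial: pd.DataFrame, params: StrigaSimParams
) -> list[StrigaCountSeries]:
    """Simulate the per-plot Striga count series over the trial layout.

    Counts at day t are negative-binomial with mean
    baseline_curve(t) x susceptibility(genotype) and dispersion k
    (Poisson when ``overdispersion`` is None); susceptibility 0 yields an
    all-zero series.
    """
    missing = set(trial["genotype_id"]) - set(params.genotype_susceptibility)
    if missing:
        raise ValueError(f"susceptibility undefined for genotypes {sorted(missing)[:5]}")
    rng = np.random.default_rng(params.seed)
    series = []
    for _, plot in trial.iterrows():
        s = params.genotype_susceptibility[plot["genotype_id"]]
        mu = np.asarray(params.baseline_curve) * s
        counts = _nb_draw(rng, mu, params.overdispersion)
        series.append(
            StrigaCountSeries(
                plot_id=plot["plot_id"],
                environment=plot["environment"],
                assessment_days=tuple(params.assessment_days),
                counts=tuple(int(c) for c in counts),
            )
        )
    return series


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, k: Optional[float]
) -> np.ndarray:
    out = np.zeros(len(mu), dtype=int)
    pos = mu > 0
    if not pos.any():
        return out
    if k is None:  # Poisson limit
        out[pos] = rng.poisson(mu[pos])
    else:
        p = k / (k + mu[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def draw_susceptibilities(
    genotype_ids: Sequence[str], seed: int = 0, sd_log: float = 1.0
) -> dict:
    """Lognormal per-genotype susceptibility multipliers (median 1)."""
    rng = np.random.default_rng(seed)
    return {g: float(v) for g, v in zip(genotype_ids, rng.lognormal(0.0, sd_log, len(genotype_ids)))}


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths and its tip metric.

    Returns (tree, DistanceMatrix of tip-tip path lengths); the matrix is
    additive by construction, so distance-exact methods must recover the
    generating topology from it.
    """
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent = TreeNode(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    for node in nodes:
        if node.length is None:
            node.length = float(rng.uniform(0.05, 1.0))
    tree = TreeNode(children=nodes)
    return tree, tree.tip_tip_distances()


# ---------------------------------------------------------------------------
# SNP simulation


def simulate_parent_panel(
    n_parents: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
    sample_ids: Optional[Sequence[str]] = None,
) -> SNPMatrix:
    """Fully homozygous inbred parents (calls 0 or 2).

    Per-marker alternate-allele frequencies are drawn uniformly from
    ``maf_range``; each parent is homozygous alternate with that
    probability.  Missing entries occur at ``missing_rate``.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=n_markers)
    calls = np.where(rng.random((n_parents, n_markers)) < freqs, 2.0, 0.0)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    if sample_ids is None:
        sample_ids = [f"P{i + 1:02d}" for i in range(n_parents)]
    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    return SNPMatrix(list(sample_ids), marker_ids, calls)


def simulate_selfed_progeny(
    panel: SNPMatrix,
    female_id: str,
    male_id: str,
    generation: int = 4,
    n_progeny: int = 6,
    seed: int = 0,
    prefix: Optional[str] = None,
) -> SNPMatrix:
    """Selfed progeny of a biparental cross at filial generation g.

    At loci where the homozygous parents differ, an F_g individual is
    heterozygous with probability 0.5^(g-1) (F1: 1, F4: 0.125) and otherwise
    homozygous for either parental allele with equal probability; loci where
    the parents agree are fixed.  Markers with a heterozygous or missing
    parent call are skipped with a warning.
    """
    import logging

    if generation < 1:
        raise ValueError("generation must be >= 1")
    rng = np.random.default_rng(seed)
    f = panel.sample(female_id)
    m = panel.sample(male_id)
    usable = (
        np.isfinite(f) & np.isfinite(m) & np.isin(f, (0.0, 2.0)) & np.isin(m, (0.0, 2.0))
    )
    n_skipped = int((~usable).sum())
    if n_skipped:
        logging.getLogger(__name__).warning(
            "cross %s x %s: skipped %d marker(s) with heterozygous/missing parent",
            female_id,
            male_id,
            n_skipped,
        )
    markers = [mid for mid, u in zip(panel.marker_ids, usable) if u]
    f_u, m_u = f[usable], m[usable]
    informative = f_u != m_u
    p_het = 0.5 ** (generation - 1)
    calls = np.empty((n_progeny, len(markers)))
    for i in range(n_progeny):
        row = np.where(informative, np.nan, f_u)  # fixed loci
        u = rng.random(informative.sum())
        seg = np.where(
            u < p_het, 1.0, np.where(rng.random(informative.sum()) < 0.5, f_u[informative], m_u[informative])
        )
        row[informative] = seg
        calls[i] = row
    prefix = prefix or f"{female_id}x{male_id}"
    ids = [f"{prefix}-{i + 1:02d}" for i in range(n_progeny)]
    return SNPMatrix(ids, markers, calls)


def stack_snp_matrices(matrices: Sequence[SNPMatrix]) -> SNPMatrix:
    """Row-stack matrices over the intersection of their marker sets."""
    common = [m for m in matrices[0].marker_ids if all(m in x.marker_ids for x in matrices[1:])]
    subs = [x.subset(marker_ids=common) for x in matrices]
    return SNPMatrix(
        sample_ids=[s for x in subs for s in x.sample_ids],
        marker_ids=common,
        calls=np.vstack([x.calls for x in subs]),
    )


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyBundle:
    """A complete simulated study: everything the pipelines consume."""

    genotypes: list[GenotypeEntry]
    crosses: pd.DataFrame
    field_traits: pd.DataFrame
    pot_traits: pd.DataFrame
    field_counts: list[StrigaCountSeries]
    pot_counts: list[StrigaCountSeries]
    snps: SNPMatrix
    snp_crosses: pd.DataFrame  # progeny sample id -> parents


def simulate_study(
    seed: int = 0,
    n_markers: int = 1000,
    n_progeny_per_cross: int = 6,
    n_genotyped_crosses: int = 16,
    trial_params: Optional[TrialSimParams] = None,
) -> StudyBundle:
    """Simulate the full two-environment study with SNP data.

    Field and pot trials share the genotype panel but draw independent
    effects and errors; the pot environment gets lower Striga pressure and
    higher yield-component means, mirroring the study's contrast between
    the infested field and inoculated Striga-free pot soil.
    """
    rng = np.random.default_rng(seed)
    genotypes = make_study_genotypes(seed=int(rng.integers(2**31)))
    ids = [g.id for g in genotypes]
    crosses = cross_registry_frame(genotypes)

    base = trial_params or TrialSimParams()
    field_params = TrialSimParams(
        n_genotypes=base.n_genotypes,
        n_reps=base.n_reps,
        block_size=base.block_size,
        trait_means=dict(base.trait_means),
        sigma2_g=dict(base.sigma2_g),
        sigma2_e=dict(base.sigma2_e),
        rep_block_var_fraction=base.rep_block_var_fraction,
        seed=int(rng.integers(2**31)),
    )
    pot_means = dict(base.trait_means)
    pot_means.update({"YLD": pot_means["YLD"] * 1.6, "HGW": pot_means["HGW"] * 1.25,
                      "NSFC": pot_means["NSFC"] * 0.4})
    pot_params = TrialSimParams(
        n_genotypes=base.n_genotypes,
        n_reps=base.n_reps,
        block_size=base.block_size,
        trait_means=pot_means,
        sigma2_g=dict(base.sigma2_g),
        sigma2_e=dict(base.sigma2_e),
        rep_block_var_fraction=base.rep_block_var_fraction,
        seed=int(rng.integers(2**31)),
    )
    field_traits = simulate_trial(field_params, ids, "field")
    pot_traits = simulate_trial(pot_params, ids, "pot")

    susceptibility = draw_susceptibilities(ids, seed=int(rng.integers(2**31)))
    field_counts = simulate_striga_series(
        field_traits,
        StrigaSimParams(
            genotype_susceptibility=susceptibility, seed=int(rng.integers(2**31))
        ),
    )
    pot_counts = simulate_striga_series(
        pot_traits,
        StrigaSimParams(
            baseline_curve=tuple(0.3 * b for b in DEFAULT_BASELINE_CURVE),
            genotype_susceptibility=susceptibility,
            seed=int(rng.integers(2**31)),
        ),
    )

    # all non-F4 entries are genotyped; cross parents are a subset of these
    panel_ids = [g.id for g in genotypes if g.material_class is not MaterialClass.F4]
    panel = simulate_parent_panel(
        n_parents=len(panel_ids),
        n_markers=n_markers,
        missing_rate=0.02,
        seed=int(rng.integers(2**31)),
        sample_ids=panel_ids,
    )
    matrices = [panel]
    snp_rows = []
    for _, cross in crosses.head(n_genotyped_crosses).iterrows():
        progeny = simulate_selfed_progeny(
            panel,
            cross["female"],
            cross["male"],
            generation=4,
            n_progeny=n_progeny_per_cross,
            seed=int(rng.integers(2**31)),
            prefix=cross["id"],
        )
        matrices.append(progeny)
        snp_rows += [
            {"id": pid, "female": cross["female"], "male": cross["male"],
             "cross_id": cross["cross_id"]}
            for pid in progeny.sample_ids
        ]
    snps = stack_snp_matrices(matrices)
    snp_crosses = pd.DataFrame(snp_rows, columns=["id", "female", "male", "cross_id"])
    return StudyBundle(
        genotypes=genotypes,
        crosses=crosses,
        field_traits=field_traits,
        pot_traits=pot_traits,
        field_counts=field_counts,
        pot_counts=pot_counts,
        snps=snps,
        snp_crosses=snp_crosses,
    )
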