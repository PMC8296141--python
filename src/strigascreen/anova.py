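"""Fixed-effects trial ANOVA, variance components, heritability and LSD.

The lattice analysis is an ordinary-least-squares fixed-effects decomposition
with sequential (type-I) sums of squares in the order replicate -> block
within replicate (lattice only) -> genotype -> residual.  This yields the
genotype and error mean squares (MS_g, MS_e) that the classical
variance-component formulas consume:

    sigma2_g = (MS_g - MS_e) / r        sigma2_p = sigma2_g + sigma2_e
    GCV% = 100 sqrt(sigma2_g) / mean    PCV% = 100 sqrt(sigma2_p) / mean
    H2%  = 100 sigma2_g / sigma2_p

with r the number of replications and sigma2_e identified with the residual
mean square.  Negative sigma2_g estimates are clamped to zero and flagged.
Recovery of inter-block information (REML) is deliberately not attempted;
the intra-block fixed-effects analysis is reproducible from first principles
and provides the mean squares the downstream formulas need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import VarianceComponents

__all__ = [
    "fit_anova",
    "partition_genotype_ss",
    "combined_environment_anova",
    "variance_components",
    "gcv_pcv",
    "heritability",
    "classify_heritability",
    "fisher_lsd",
    "variance_component_summary",
    "significance_stars",
    "LsdResult",
]


def significance_stars(p: float) -> str:
    """Star codes at the 0.05 / 0.01 / 0.001 levels ('ns' otherwise)."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# sequential least-squares machinery


def _dummies(values: Sequence) -> np.ndarray:
    return pd.get_dummies(pd.Series(values).astype(str)).to_numpy(dtype=float)


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def sequential_ss(
    y: np.ndarray, terms: list[tuple[str, np.ndarray]]
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA decomposition over ordered model terms.

    Each term's sum of squares is the drop in residual sum of squares when
    its columns are appended to the design; degrees of freedom are the rank
    increase, so rank-deficient (confounded) columns are handled exactly.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    rss_prev, rank_prev = _rss_rank(X, y)
    rows = []
    for name, cols in terms:
        X = np.column_stack([X, cols])
        rss, rank = _rss_rank(X, y)
        rows.append(
            {"source": name, "df": rank - rank_prev, "sum_sq": max(rss_prev - rss, 0.0)}
        )
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    rows.append({"source": "Residual", "df": df_resid, "sum_sq": rss_prev})
    table = pd.DataFrame(rows).set_index("source")
    return _finish_table(table)


def _finish_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add mean squares, F statistics against the residual row, and p."""
    with np.errstate(invalid="ignore", divide="ignore"):
        table["mean_sq"] = table["sum_sq"] / table["df"].replace(0, np.nan)
    ms_e = table.loc["Residual", "mean_sq"]
    df_e = table.loc["Residual", "df"]
    f = table["mean_sq"] / ms_e
    p = pd.Series(
        [
            stats.f.sf(fv, dfv, df_e) if np.isfinite(fv) and dfv > 0 else np.nan
            for fv, dfv in zip(f, table["df"])
        ],
        index=table.index,
    )
    table["F"] = f
    table["p"] = p
    table.loc["Residual", ["F", "p"]] = np.nan
    table["stars"] = [significance_stars(pv) if np.isfinite(pv) else "" for pv in table["p"]]
    return table


def _prepare(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    if trait not in records.columns:
        raise ValueError(f"trait {trait!r} not in records")
    df = records.dropna(subset=[trait]).copy()
    if df.empty:
        raise ValueError(f"no non-missing observations for trait {trait!r}")
    if df["replicate"].nunique() < 2:
        raise ValueError("need at least 2 replicates for an ANOVA")
    return df


def _base_terms(df: pd.DataFrame, model: str) -> list[tuple[str, np.ndarray]]:
    terms: list[tuple[str, np.ndarray]] = [("Reps", _dummies(df["replicate"]))]
    if model == "lattice":
        if "block" not in df.columns:
            raise ValueError("lattice model requires a 'block' column")
        nested = df["replicate"].astype(str) + "/" + df["block"].astype(str)
        terms.append(("Blocks(Reps)", _dummies(nested)))
    elif model != "rcbd":
        raise ValueError(f"unknown model {model!r}; use 'rcbd' or 'lattice'")
    return terms


def fit_anova(records: pd.DataFrame, trait: str, model: str = "lattice") -> pd.DataFrame:
    """Fit the single-environment trial ANOVA for one trait.

    ``model='lattice'`` fits replicate -> block-within-replicate -> genotype;
    ``model='rcbd'`` omits the block term.  Returns the ANOVA table with
    sources as index and columns df, sum_sq, mean_sq, F, p, stars.
    """
    df = _prepare(records, trait)
    terms = _base_terms(df, model) + [("Genotype", _dummies(df["genotype_id"]))]
    table = sequential_ss(df[trait].to_numpy(), terms)
    if table.loc["Genotype", "df"] == 0:
        raise ValueError("singular design: Genotype fully confounded with Reps/Blocks")
    if table.loc["Residual", "df"] == 0:
        raise ValueError("zero residual degrees of freedom; model is saturated")
    return table


def partition_genotype_ss(
    records: pd.DataFrame,
    trait: str,
    parent_ids: Sequence[str],
    progeny_ids: Sequence[str],
    model: str = "lattice",
) -> pd.DataFrame:
    """Split the genotype sum of squares into Parents, Progenies and contrast.

    The 1-df parents-vs-progenies group contrast is fitted first, then the
    among-parents and among-progenies terms; the three sequential components
    sum to the genotype sum of squares by construction.  Groups with fewer
    than two members contribute a zero-df row flagged in ``table.attrs``.
    """
    parents, progenies = set(map(str, parent_ids)), set(map(str, progeny_ids))
    overlap = parents & progenies
    if overlap:
        raise ValueError(f"parent/progeny id sets overlap: {sorted(overlap)}")
    df = _prepare(records, trait)
    observed = set(df["genotype_id"].astype(str))
    uncovered = observed - parents - progenies
    if uncovered:
        raise ValueError(f"genotypes not assigned to either group: {sorted(uncovered)}")

    geno = df["genotype_id"].astype(str)
    is_progeny = geno.isin(progenies)
    within_parents = geno.where(~is_progeny, "__PROGENY__")
    within_progenies = geno  # full genotype factor completes the decomposition
    terms = _base_terms(df, model) + [
        ("Par vs Pro", is_progeny.to_numpy(dtype=float).reshape(-1, 1)),
        ("Parents (Par)", _dummies(within_parents)),
        ("Progenies (Pro)", _dummies(within_progenies)),
    ]
    table = sequential_ss(df[trait].to_numpy(), terms)
    table = table.loc[["Parents (Par)", "Progenies (Pro)", "Par vs Pro", "Residual"]]
    flags = [
        src
        for src in ("Parents (Par)", "Progenies (Pro)", "Par vs Pro")
        if table.loc[src, "df"] == 0
    ]
    table.attrs["zero_df_components"] = flags
    return table


def combined_environment_anova(
    field_records: pd.DataFrame,
    pot_records: pd.DataFrame,
    trait: str,
    model: str = "lattice",
) -> pd.DataFrame:
    """Pooled two-environment ANOVA with a fixed 1-df Environment source.

    The environment contrast is fitted first; each trial then contributes its
    own replicate/block/genotype decomposition nested within environment, so
    the per-trial rows equal the single-environment tables and the pooled
    residual df is the sum of the per-trial residual dfs.
    """
    f_geno = set(field_records["genotype_id"].astype(str))
    p_geno = set(pot_records["genotype_id"].astype(str))
    if not (f_geno & p_geno):
        raise ValueError("field and pot genotype sets are disjoint")
    f_df = _prepare(field_records, trait)
    p_df = _prepare(pot_records, trait)
    y = np.concatenate([f_df[trait].to_numpy(float), p_df[trait].to_numpy(float)])
    n_f, n_p = len(f_df), len(p_df)
    grand = y.mean()
    env_means = (f_df[trait].mean(), p_df[trait].mean())
    env_ss = n_f * (env_means[0] - grand) ** 2 + n_p * (env_means[1] - grand) ** 2

    f_tab = fit_anova(f_df, trait, model)
    p_tab = fit_anova(p_df, trait, model)
    rows = [{"source": "Environment", "df": 1, "sum_sq": env_ss}]
    for label, tab in (("Field", f_tab), ("Pot", p_tab)):
        for src in tab.index:
            if src == "Residual":
                continue
            rows.append(
                {
                    "source": f"{label}:{src}",
                    "df": tab.loc[src, "df"],
                    "sum_sq": tab.loc[src, "sum_sq"],
                }
            )
    rows.append(
        {
            "source": "Residual",
            "df": f_tab.loc["Residual", "df"] + p_tab.loc["Residual", "df"],
            "sum_sq": f_tab.loc["Residual", "sum_sq"] + p_tab.loc["Residual", "sum_sq"],
        }
    )
    table = pd.DataFrame(rows).set_index("source")
    return _finish_table(table)


# ---------------------------------------------------------------------------
# variance components and derived genetic parameters


def variance_components(
    ms_g: float, ms_e: float, r: int
) -> tuple[float, float, float, bool]:
    """(sigma2_g, sigma2_e, sigma2_p, clamped_flag) from the mean squares."""
    if r < 2:
        raise ValueError("need r >= 2 replications")
    s2g = (ms_g - ms_e) / r
    clamped = s2g < 0
    if clamped:
        s2g = 0.0
    s2e = ms_e
    return s2g, s2e, s2g + s2e, clamped


def gcv_pcv(sigma2_g: float, sigma2_p: float, grand_mean: float) -> tuple[float, float]:
    """Genotypic and phenotypic coefficients of variation, in percent."""
    if grand_mean <= 0:
        raise ValueError("GCV/PCV require a positive grand mean")
    return (
        100.0 * np.sqrt(sigma2_g) / grand_mean,
        100.0 * np.sqrt(sigma2_p) / grand_mean,
    )


def classify_heritability(h2_pct: float) -> str:
    """0-30% low, 30-60% moderate, >60% high."""
    if h2_pct <= 30.0:
        return "low"
    if h2_pct <= 60.0:
        return "moderate"
    return "high"


def heritability(sigma2_g: float, sigma2_p: float) -> tuple[float, str]:
    """Broad-sense heritability H2 = 100 sigma2_g / sigma2_p and its class."""
    if sigma2_p <= 0:
        raise ValueError("heritability undefined for sigma2_p <= 0")
    h2 = 100.0 * sigma2_g / sigma2_p
    h2 = float(np.clip(h2, 0.0, 100.0))
    return h2, classify_heritability(h2)


def variance_component_summary(
    records: pd.DataFrame,
    trait: str,
    environment: str,
    model: str = "lattice",
) -> VarianceComponents:
    """Fit the trial ANOVA and derive the full variance-component record."""
    df = _prepare(records, trait)
    table = fit_anova(df, trait, model)
    r = int(df["replicate"].nunique())
    s2g, s2e, s2p, clamped = variance_components(
        table.loc["Genotype", "mean_sq"], table.loc["Residual", "mean_sq"], r
    )
    mean = float(df[trait].mean())
    gcv, pcv = gcv_pcv(s2g, s2p, mean)
    h2, h2_class = heritability(s2g, s2p)
    return VarianceComponents(
        trait=trait,
        environment=environment,
        sigma2_g=s2g,
        sigma2_e=s2e,
        sigma2_p=s2p,
        grand_mean=mean,
        gcv_pct=gcv,
        pcv_pct=pcv,
        h2_pct=h2,
        h2_class=h2_class,
        negative_component_flag=clamped,
    )


# ---------------------------------------------------------------------------
# Fisher's protected LSD


@dataclass
class LsdResult:
    """Fisher's LSD with compact-letter groupings of the genotype means."""

    lsd: float
    alpha: float
    protected: bool
    groups: "pd.Series"  # genotype -> letter string; empty when suppressed


def fisher_lsd(
    genotype_means: pd.Series,
    ms_e: float,
    residual_df: int,
    r: int,
    alpha: float = 0.05,
    f_p_value: Optional[float] = None,
) -> LsdResult:
    """Fisher's protected least significant difference and letter groups.

    LSD = t(1-alpha/2, residual_df) * sqrt(2 MS_e / r).  Letter groupings are
    produced only when the overall genotype F-test is significant at
    ``alpha`` ("protected"); otherwise the LSD value is still reported with
    the groupings suppressed.
    """
    if r < 2:
        raise ValueError("LSD requires r >= 2 replications")
    t = stats.t.ppf(1.0 - alpha / 2.0, residual_df)
    lsd = float(t * np.sqrt(2.0 * ms_e / r))
    protected = f_p_value is None or f_p_value <= alpha
    if not protected:
        return LsdResult(lsd, alpha, False, pd.Series(dtype=str))
    means = genotype_means.sort_values(ascending=False)
    ranges = []
    for i in range(len(means)):
        j = i
        while j + 1 < len(means) and means.iloc[i] - means.iloc[j + 1] <= lsd:
            j += 1
        ranges.append((i, j))
    # keep maximal ranges only
    maximal = [
        (a, b)
        for a, b in dict.fromkeys(ranges)
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in ranges)
    ]
    letters = {g: "" for g in means.index}
    for letter_idx, (a, b) in enumerate(sorted(maximal)):
        letter = _letter(letter_idx)
        for g in means.index[a : b + 1]:
            letters[g] += letter
    return LsdResult(lsd, alpha, True, pd.Series(letters).reindex(genotype_means.index))


def _letter(i: int) -> str:
    # a..z, then aa, ab, ... for very fragmented mean structures
    out = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out
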