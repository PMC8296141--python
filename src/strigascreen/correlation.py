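"""Trait-trait and field-vs-pot Pearson correlations with significance.

All correlations are computed on genotype means (the per-genotype average
over replicates within an environment) with pairwise-complete deletion of
missing values.  Significance uses the t-transform of r on n-2 degrees of
freedom, starred at the 0.05 / 0.01 / 0.001 levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anova import significance_stars


@dataclass
class CorrelationResult:
    label: str
    r: float
    n: int
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def pearson(x: Sequence[float], y: Sequence[float], label: str = "") -> CorrelationResult:
    """Pearson r = cov(x, y) / (sd_x sd_y) with a two-sided t-test on n-2 df.

    Pairs with a missing member are deleted; fewer than 3 complete pairs or a
    zero-variance argument is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(label=label, r=float(r), n=n, p=float(p))


def genotype_means(records: pd.DataFrame, trait: str) -> pd.Series:
    """Per-genotype mean of a trait over the plots of one environment."""
    return records.groupby("genotype_id")[trait].mean()


def trait_correlation_matrix(
    records: pd.DataFrame, traits: Sequence[str], environment: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Symmetric trait x trait correlation of genotype means.

    Returns (r, p, n) matrices; cells with an absent trait or fewer than 3
    complete pairs are NaN.  The diagonal is exactly 1 with p 0.
    """
    env = records[records["environment"] == environment]
    means = pd.DataFrame(
        {t: genotype_means(env, t) for t in traits if t in env.columns}
    )
    k = len(traits)
    r = pd.DataFrame(np.full((k, k), np.nan), index=traits, columns=traits)
    p = r.copy()
    n = r.copy()
    for i, a in enumerate(traits):
        for b in traits[i:]:
            if a == b:
                if a in means.columns:
                    r.loc[a, a], p.loc[a, a] = 1.0, 0.0
                    n.loc[a, a] = means[a].notna().sum()
                continue
            if a not in means.columns or b not in means.columns:
                continue
            try:
                res = pearson(means[a], means[b], label=f"{a}~{b}")
            except ValueError:
                continue
            r.loc[a, b] = r.loc[b, a] = res.r
            p.loc[a, b] = p.loc[b, a] = res.p
            n.loc[a, b] = n.loc[b, a] = res.n
    return r, p, n


def cross_trial_correlation(
    field_records: pd.DataFrame, pot_records: pd.DataFrame, trait: str
) -> CorrelationResult:
    """Field-vs-pot correlation of a trait's genotype means.

    Pairs genotypes present in both environments; fewer than 3 shared
    genotypes is an error.
    """
    fx = genotype_means(field_records[field_records["environment"] == "field"], trait)
    py = genotype_means(pot_records[pot_records["environment"] == "pot"], trait)
    shared = fx.index.intersection(py.index)
    if len(shared) < 3:
        raise ValueError(
            f"cross-trial correlation for {trait!r}: only {len(shared)} shared genotypes"
        )
    return pearson(fx.loc[shared], py.loc[shared], label=f"{trait} field~pot")


def cross_trial_table(
    field_records: pd.DataFrame, pot_records: pd.DataFrame, traits: Sequence[str]
) -> pd.DataFrame:
    """Per-trait field-vs-pot correlation table with significance stars."""
    rows = []
    for t in traits:
        try:
            res = cross_trial_correlation(field_records, pot_records, t)
        except (ValueError, KeyError):
            continue
        rows.append(
            {"trait": t, "r": res.r, "n": res.n, "p": res.p, "stars": res.stars}
        )
    return pd.DataFrame(rows, columns=["trait", "r", "n", "p", "stars"])
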