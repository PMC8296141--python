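"""Mid-parent values and residual heterosis for the F4 crosses.

Residual heterosis at F4 is the percent deviation of the cross mean from the
mid-parent value,

    MP = (P1 + P2) / 2        RH% = 100 (F4 - MP) / MP,

computed per trait within one environment from genotype means (the average
over the cross's plots).  Negative values indicate performance below the
mid-parent — inbreeding depression for yield traits, but the desirable
direction for Striga counts.  Crosses whose parents are absent from the
trial (e.g. failed to germinate) are excluded with a logged reason, and
A x B is kept distinct from B x A.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .correlation import genotype_means
from .model import CrossHeterosisRecord

logger = logging.getLogger(__name__)


def midparent(p1_mean: float, p2_mean: float) -> float:
    """Mid-parent value, the arithmetic mean of the two parental means."""
    return (p1_mean + p2_mean) / 2.0


def residual_heterosis(f4_mean: float, mp: float) -> float:
    """Percent deviation of the F4 mean from the mid-parent value."""
    if mp == 0:
        raise ValueError("residual heterosis undefined for a zero mid-parent value")
    return 100.0 * (f4_mean - mp) / mp


def heterosis_table(
    records: pd.DataFrame,
    crosses: pd.DataFrame,
    traits: Sequence[str],
    environment: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Residual-heterosis records for every cross and trait in one environment.

    ``crosses`` is the cross registry (columns id, female, male, cross_id)
    with ``id`` the F4 entry's genotype id.  Returns the record table and the
    list of exclusion reasons (missing parent or F4 mean, zero mid-parent).
    """
    env = records[records["environment"] == environment]
    exclusions: list[str] = []
    rows = []
    for _, cross in crosses.iterrows():
        for trait in traits:
            if trait not in env.columns:
                continue
            means = genotype_means(env, trait)
            missing = [
                p for p in (cross["female"], cross["male"]) if p not in means.index
                or pd.isna(means.get(p))
            ]
            if missing:
                reason = (
                    f"{cross['cross_id']} [{trait}, {environment}]: "
                    f"parent(s) {missing} absent from trial"
                )
                exclusions.append(reason)
                logger.warning("excluded cross: %s", reason)
                continue
            if cross["id"] not in means.index or pd.isna(means.get(cross["id"])):
                reason = f"{cross['cross_id']} [{trait}, {environment}]: no F4 plots"
                exclusions.append(reason)
                logger.warning("excluded cross: %s", reason)
                continue
            mp = midparent(means[cross["female"]], means[cross["male"]])
            if mp == 0:
                reason = f"{cross['cross_id']} [{trait}, {environment}]: zero mid-parent"
                exclusions.append(reason)
                logger.warning("excluded cross: %s", reason)
                continue
            rec = CrossHeterosisRecord(
                cross_id=cross["cross_id"],
                environment=environment,
                trait=trait,
                p1_mean=float(means[cross["female"]]),
                p2_mean=float(means[cross["male"]]),
                f4_mean=float(means[cross["id"]]),
                midparent=mp,
                residual_heterosis_pct=residual_heterosis(means[cross["id"]], mp),
            )
            rows.append(vars(rec))
    table = pd.DataFrame(
        rows,
        columns=[
            "cross_id",
            "environment",
            "trait",
            "p1_mean",
            "p2_mean",
            "f4_mean",
            "midparent",
            "residual_heterosis_pct",
        ],
    )
    return table, exclusions


def rank_crosses(
    table: pd.DataFrame, trait: str, desirability: str = "higher_better"
) -> pd.DataFrame:
    """Rank crosses by residual heterosis for one trait.

    ``higher_better`` sorts descending (e.g. 100-grain weight),
    ``lower_better`` ascending (e.g. NS_max, where negative heterosis means
    fewer Striga than the mid-parent).  Ties break on cross_id.
    """
    if desirability not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown desirability {desirability!r}")
    sub = table[table["trait"] == trait].copy()
    ascending = desirability == "lower_better"
    sub = sub.sort_values(
        ["residual_heterosis_pct", "cross_id"], ascending=[ascending, True]
    ).reset_index(drop=True)
    sub.insert(0, "rank", range(1, len(sub) + 1))
    return sub
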