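"""Per-plot *Striga* response statistics.

ASNPC (area under the *Striga* number progress curve) is the trapezoidal
integral of emerged-Striga counts over the assessment dates,

    ASNPC = sum_i [(Y_i + Y_{i+1}) / 2] * (t_{i+1} - t_i),

with Y_i the count and t_i the days after sowing at the i-th assessment.
Lower values indicate more resistant genotypes.  No zero count is prepended
at sowing or first emergence: the statistic uses exactly the recorded dates.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .model import StrigaCountSeries


def asnpc(series: StrigaCountSeries) -> float:
    """Area under the Striga number progress curve (count·days).

    A single-observation series has no interval to integrate and returns 0.
    """
    days, counts = series.assessment_days, series.counts
    return sum(
        (counts[i] + counts[i + 1]) / 2.0 * (days[i + 1] - days[i])
        for i in range(len(days) - 1)
    )


def ns_max(series: StrigaCountSeries) -> int:
    """Maximum above-ground Striga count across assessment dates."""
    return max(series.counts)


def first_emergence_day(series: StrigaCountSeries) -> Optional[int]:
    """Earliest assessment day with a positive count, or None if never."""
    for day, count in zip(series.assessment_days, series.counts):
        if count > 0:
            return day
    return None


def summarize_plots(series: Iterable[StrigaCountSeries]) -> pd.DataFrame:
    """Per-plot summary table of the Striga progress statistics."""
    rows = [
        {
            "plot_id": s.plot_id,
            "environment": s.environment,
            "ASNPC": asnpc(s),
            "NS_max": ns_max(s),
            "first_emergence_day": first_emergence_day(s),
        }
        for s in series
    ]
    return pd.DataFrame(
        rows, columns=["plot_id", "environment", "ASNPC", "NS_max", "first_emergence_day"]
    )


def join_with_traits(
    trait_table: pd.DataFrame, series: Iterable[StrigaCountSeries]
) -> pd.DataFrame:
    """Join the per-plot Striga summary onto the plot trait table.

    NSFC stays the directly recorded trait (measured once at 105 days after
    sowing); it is carried through, not derived from the count series.
    """
    summary = summarize_plots(series)
    return trait_table.merge(summary, on=["plot_id", "environment"], how="left")
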