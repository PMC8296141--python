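"""Shared domain types for the screening-trial analysis.

The trial screens sorghum germplasm (wild relatives, landraces, improved
varieties and F4 progenies of biparental crosses) against the parasitic weed
*Striga hermonthica* in two environments (an infested field and inoculated
pots).  Everything downstream — the *Striga* progress statistics, the lattice
ANOVA, heterosis and the SNP analyses — consumes the types defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Agronomic and biotic trait columns of a plot record, in reporting order.
#: DTF days to 50% flowering (d); DPW dry panicle weight (g); PH plant height
#: (cm); YLD grain yield (t/ha); HGW 100-grain weight (g); ODS/OPS overall
#: disease/pest score (1-9); NSFC number of Striga plants forming capsules.
TRAIT_COLUMNS = ("DTF", "DPW", "PH", "YLD", "HGW", "ODS", "OPS", "NSFC")

#: Traits scored on the 1-9 visual scale.
SCORE_TRAITS = ("ODS", "OPS")

#: Traits that cannot be negative (weights, heights, yields, counts).
NONNEGATIVE_TRAITS = ("DPW", "PH", "YLD", "HGW", "NSFC", "DTF")

ENVIRONMENTS = ("field", "pot")


class MaterialClass(str, enum.Enum):
    """Germplasm classification used in the trial."""

    WILD = "wild"
    LANDRACE = "landrace"
    IMPROVED = "improved"
    F4 = "F4"


@dataclass(frozen=True)
class GenotypeEntry:
    """One entry of the trial: a genotype and its pedigree class.

    F4 entries carry both parents; other classes carry none.
    """

    id: str
    material_class: MaterialClass
    female_parent: Optional[str] = None
    male_parent: Optional[str] = None

    def __post_init__(self) -> None:
        cls = MaterialClass(self.material_class)
        object.__setattr__(self, "material_class", cls)
        has_parents = self.female_parent is not None and self.male_parent is not None
        if cls is MaterialClass.F4 and not has_parents:
            raise ValueError(f"F4 entry {self.id!r} must have both parents set")
        if cls is not MaterialClass.F4 and (self.female_parent or self.male_parent):
            raise ValueError(f"non-F4 entry {self.id!r} must not have parents")

    @property
    def cross_id(self) -> Optional[str]:
        if self.material_class is MaterialClass.F4:
            return f"{self.female_parent} x {self.male_parent}"
        return None


@dataclass(frozen=True)
class StrigaCountSeries:
    """Emerged-*Striga* counts for one plot over the assessment dates.

    ``assessment_days`` are days after sowing, strictly increasing; counts
    are per-plot totals of emerged Striga plants on each date.
    """

    plot_id: str
    environment: str
    assessment_days: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.assessment_days)
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "assessment_days", days)
        object.__setattr__(self, "counts", counts)
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if len(days) == 0:
            raise ValueError(f"plot {self.plot_id!r}: empty count series")
        if len(days) != len(counts):
            raise ValueError(f"plot {self.plot_id!r}: days/counts length mismatch")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(
                f"plot {self.plot_id!r}: assessment days must be strictly increasing"
            )
        if any(c < 0 for c in counts):
            raise ValueError(f"plot {self.plot_id!r}: negative Striga count")

    def __len__(self) -> int:
        return len(self.assessment_days)


class SNPMatrix:
    """Diploid biallelic genotype calls as alternate-allele dosage.

    ``calls`` is a float array of shape (n_samples, n_markers) with values in
    {0, 1, 2} and ``nan`` for missing calls.  Rows follow ``sample_ids``,
    columns follow ``marker_ids``.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        marker_ids: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.sample_ids = list(map(str, sample_ids))
        self.marker_ids = list(map(str, marker_ids))
        calls = np.asarray(calls, dtype=float)
        if calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        finite = calls[np.isfinite(calls)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("calls must be coded 0/1/2 or missing (nan)")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        self.calls = calls

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample(self, sample_id: str) -> np.ndarray:
        """Return one sample's call vector (view)."""
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None
        return self.calls[i]

    def subset(
        self,
        sample_ids: Optional[Sequence[str]] = None,
        marker_ids: Optional[Sequence[str]] = None,
    ) -> "SNPMatrix":
        samples = self.sample_ids if sample_ids is None else list(sample_ids)
        markers = self.marker_ids if marker_ids is None else list(marker_ids)
        ri = [self.sample_ids.index(s) for s in samples]
        ci = [self.marker_ids.index(m) for m in markers]
        return SNPMatrix(samples, markers, self.calls[np.ix_(ri, ci)])

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return np.isfinite(self.calls).mean(axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing calls.

        Markers with no non-missing calls get MAF 0.
        """
        with np.errstate(invalid="ignore"):
            p_alt = np.nanmean(self.calls, axis=0) / 2.0
        p_alt = np.where(np.isfinite(p_alt), p_alt, 0.0)
        return np.minimum(p_alt, 1.0 - p_alt)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SNPMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls, equal_nan=True)
        )


@dataclass
class VarianceComponents:
    """Variance components and derived genetic parameters for one trait."""

    trait: str
    environment: str
    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    grand_mean: float
    gcv_pct: float
    pcv_pct: float
    h2_pct: float
    h2_class: str
    negative_component_flag: bool = False


@dataclass
class CrossHeterosisRecord:
    """Mid-parent comparison for one F4 cross, trait and environment."""

    cross_id: str
    environment: str
    trait: str
    p1_mean: float
    p2_mean: float
    f4_mean: float
    midparent: float
    residual_heterosis_pct: float


@dataclass
class HybridityReport:
    """Per-cross summary of ABH heterozygosity among tested progeny."""

    cross_id: str
    n_progeny_tested: int
    n_biallelic_markers: int
    het_pct_per_progeny: dict[str, float] = field(default_factory=dict)

    @property
    def het_pct_range(self) -> tuple[float, float]:
        vals = list(self.het_pct_per_progeny.values())
        return (min(vals), max(vals))
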