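"""SNP filtering, ABH hybridity coding, IBS distances and neighbor joining.

Hybridity of a putative biparental progeny is confirmed at informative
markers — SNPs at which the two parents are opposite homozygotes — by
recoding each progeny call as A (female-parent homozygote), B (male-parent
homozygote) or H (heterozygote).  A genuine F4 individual is expected to be
heterozygous at about 12.5% (0.5^3) of informative loci, while a selfed or
mislabelled line shows near-zero heterozygosity.

Diversity is summarized by allele-sharing identity-by-state distances,
d(i,j) = 1 - shared alleles / (2 x overlapping markers), fed to a
Saitou-Nei neighbor-joining agglomeration.  Ties in the Q-criterion break
on the lowest (i, j) index pair and negative branch-length estimates are
clamped to zero with the excess moved to the sister branch, so runs are
reproducible and trees remain non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix, TreeNode

from .model import HybridityReport, SNPMatrix

logger = logging.getLogger(__name__)

ABH_CODES = ("A", "B", "H", "")


@dataclass
class ABHMatrix:
    """Progeny x informative-marker calls recoded against the two parents."""

    progeny_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray  # dtype '<U1'; '' = missing
    female_id: str
    male_id: str

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.shape != (len(self.progeny_ids), len(self.marker_ids)):
            raise ValueError("ABH code matrix shape mismatch")
        if not np.isin(self.codes, ABH_CODES).all():
            raise ValueError("ABH codes must be A/B/H or missing ('')")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.progeny_ids, columns=self.marker_ids)


def filter_snps(
    matrix: SNPMatrix, min_call_rate: float = 0.80, min_maf: float = 0.05
) -> tuple[SNPMatrix, dict]:
    """Drop markers below the call-rate or minor-allele-frequency threshold.

    Returns the filtered matrix and a report dict with markers in/out and
    per-criterion removal counts.  Removing every marker is an error.
    Filtering is idempotent: surviving markers satisfy both thresholds.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    cr = matrix.call_rate()
    maf = matrix.minor_allele_frequency()
    keep = (cr >= min_call_rate) & (maf >= min_maf)
    if not keep.any():
        raise ValueError("all markers removed by filtering")
    kept = [m for m, k in zip(matrix.marker_ids, keep) if k]
    report = {
        "n_markers_in": matrix.n_markers,
        "n_markers_out": int(keep.sum()),
        "n_failed_call_rate": int((cr < min_call_rate).sum()),
        "n_failed_maf": int((maf < min_maf).sum()),
        "min_call_rate": min_call_rate,
        "min_maf": min_maf,
    }
    return matrix.subset(marker_ids=kept), report


def informative_markers(
    matrix: SNPMatrix, female_id: str, male_id: str
) -> list[str]:
    """Markers at which both parents are opposite homozygotes.

    Markers where either parent is missing or heterozygous are excluded —
    unambiguous A/B assignment needs two fixed, different parental alleles.
    """
    f = matrix.sample(female_id)
    m = matrix.sample(male_id)
    ok = (
        np.isfinite(f)
        & np.isfinite(m)
        & np.isin(f, (0.0, 2.0))
        & np.isin(m, (0.0, 2.0))
        & (f != m)
    )
    return [mid for mid, k in zip(matrix.marker_ids, ok) if k]


def encode_abh(
    matrix: SNPMatrix,
    progeny_ids: Sequence[str],
    female_id: str,
    male_id: str,
) -> ABHMatrix:
    """Recode progeny calls at the informative markers as A/B/H.

    A = identical to the female homozygote, B = male homozygote,
    H = heterozygote; missing calls stay missing.
    """
    markers = informative_markers(matrix, female_id, male_id)
    if not markers:
        raise ValueError(
            f"no informative markers for cross {female_id} x {male_id}"
        )
    sub = matrix.subset(marker_ids=markers)
    f = sub.sample(female_id)
    calls = np.vstack([sub.sample(p) for p in progeny_ids])
    codes = np.full(calls.shape, "", dtype="<U1")
    codes[calls == 1.0] = "H"
    codes[(calls != 1.0) & np.isfinite(calls) & (calls == f)] = "A"
    codes[(calls != 1.0) & np.isfinite(calls) & (calls != f)] = "B"
    return ABHMatrix(
        progeny_ids=list(progeny_ids),
        marker_ids=markers,
        codes=codes,
        female_id=female_id,
        male_id=male_id,
    )


def hybridity_report(abh: ABHMatrix, cross_id: str | None = None) -> HybridityReport:
    """Per-progeny heterozygous percentage over non-missing ABH codes.

    Progeny with all-missing codes are excluded with a warning; at least one
    scored progeny is required.
    """
    if len(abh.progeny_ids) == 0:
        raise ValueError("hybridity report requires at least one progeny")
    per_progeny: dict[str, float] = {}
    for i, pid in enumerate(abh.progeny_ids):
        row = abh.codes[i]
        scored = row != ""
        if not scored.any():
            logger.warning("progeny %s: all codes missing; excluded from report", pid)
            continue
        per_progeny[pid] = 100.0 * float((row == "H").sum()) / float(scored.sum())
    if not per_progeny:
        raise ValueError("no progeny with scored markers")
    return HybridityReport(
        cross_id=cross_id or f"{abh.female_id} x {abh.male_id}",
        n_progeny_tested=len(per_progeny),
        n_biallelic_markers=len(abh.marker_ids),
        het_pct_per_progeny=per_progeny,
    )


def hybridity_table(
    matrix: SNPMatrix, crosses: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cross hybridity summary shaped like a confirmation table.

    ``crosses`` maps progeny sample ids to (female, male).  Crosses whose
    parents are absent from the matrix are excluded with a logged reason.
    Returns one row per cross: progeny tested, informative biallelic
    markers, and the min-max range of heterozygous percentage.
    """
    rows, exclusions = [], []
    for cross_id, grp in crosses.groupby("cross_id", sort=True):
        female, male = grp["female"].iloc[0], grp["male"].iloc[0]
        progeny = [p for p in grp["id"] if p in matrix.sample_ids]
        missing_parents = [p for p in (female, male) if p not in matrix.sample_ids]
        if missing_parents:
            reason = f"{cross_id}: parent(s) {missing_parents} not genotyped"
            exclusions.append(reason)
            logger.warning("excluded cross: %s", reason)
            continue
        if not progeny:
            reason = f"{cross_id}: no genotyped progeny"
            exclusions.append(reason)
            logger.warning("excluded cross: %s", reason)
            continue
        try:
            abh = encode_abh(matrix, progeny, female, male)
        except ValueError as exc:
            reason = f"{cross_id}: {exc}"
            exclusions.append(reason)
            logger.warning("excluded cross: %s", reason)
            continue
        rep = hybridity_report(abh, cross_id=cross_id)
        lo, hi = rep.het_pct_range
        rows.append(
            {
                "cross_id": cross_id,
                "n_progeny_tested": rep.n_progeny_tested,
                "n_biallelic_markers": rep.n_biallelic_markers,
                "het_pct_min": lo,
                "het_pct_max": hi,
                "het_pct_mean": float(np.mean(list(rep.het_pct_per_progeny.values()))),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cross_id",
            "n_progeny_tested",
            "n_biallelic_markers",
            "het_pct_min",
            "het_pct_max",
            "het_pct_mean",
        ],
    )
    return table, exclusions


# ---------------------------------------------------------------------------
# distances and trees


def ibs_distance(matrix: SNPMatrix) -> DistanceMatrix:
    """Allele-sharing identity-by-state distance matrix.

    d(i, j) = 1 - shared alleles / (2 x overlapping non-missing markers)
            = mean |g_i - g_j| / 2 over the overlap.
    A pair with zero marker overlap is an error naming the pair.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    calls = matrix.calls
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            overlap = np.isfinite(calls[i]) & np.isfinite(calls[j])
            if not overlap.any():
                raise ValueError(
                    f"zero marker overlap between samples "
                    f"{matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r}"
                )
            diff = np.abs(calls[i, overlap] - calls[j, overlap]).mean() / 2.0
            d[i, j] = d[j, i] = diff
    return DistanceMatrix(d, ids=matrix.sample_ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining of a distance matrix.

    Iteratively joins the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j
    (ties: lowest (i, j) index pair), computes branch lengths by the
    standard three-point formulas, and reduces the matrix until three nodes
    remain, which are resolved directly onto an unrooted trifurcation.
    Negative branch-length estimates are clamped to zero with the excess
    transferred to the sister branch, preserving the pairwise sum.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry / zero diagonal
    n = dm.shape[0]
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 samples")
    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    if n == 2:
        # midpoint split of the single edge
        half = dm.data[0, 1] / 2.0
        for node in nodes:
            node.length = half
        return TreeNode(children=nodes)
    d = dm.data.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) with i < j among the minima
        i, j = min(
            (int(a), int(b))
            for a, b in zip(*np.nonzero(np.isclose(q, q.min())))
            if a < b
        )
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        du = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
    # resolve the final three nodes around an unrooted central node
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = d[0, 1] - la
    lc = d[0, 2] - la
    lengths = [max(x, 0.0) for x in (la, lb, lc)]
    for node, length in zip(nodes, lengths):
        node.length = length
    return TreeNode(children=nodes)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def tree_from_snps(
    matrix: SNPMatrix,
    min_call_rate: float = 0.80,
    min_maf: float = 0.05,
) -> tuple[TreeNode, DistanceMatrix, dict]:
    """Filter markers, compute IBS distances and build the NJ tree."""
    filtered, report = filter_snps(matrix, min_call_rate, min_maf)
    dm = ibs_distance(filtered)
    return neighbor_joining(dm), dm, report
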