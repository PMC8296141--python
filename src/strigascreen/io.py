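"""Readers and writers for the delimited-text, variant and tree formats.

Dialect: comma-separated UTF-8 with "." decimal; missing values are empty
cells or "NA".  Readers never silently drop rows — every rejected record is
logged with the reason, so records in = records kept + logged rejections.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import skbio

from .model import (
    ENVIRONMENTS,
    NONNEGATIVE_TRAITS,
    SCORE_TRAITS,
    SNPMatrix,
    StrigaCountSeries,
    TRAIT_COLUMNS,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_NA = ("", "NA", "NaN", "nan")

# accepted aliases for the mandatory trait-table columns
_COLUMN_ALIASES = {
    "plot": "plot_id",
    "plot_id": "plot_id",
    "genotype": "genotype_id",
    "genotype_id": "genotype_id",
    "rep": "replicate",
    "replicate": "replicate",
    "environment": "environment",
    "env": "environment",
    "block": "block",
}

_MANDATORY = ("plot_id", "genotype_id", "replicate", "environment")


def _read_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, na_values=list(_NA), keep_default_na=False, dtype=str)


def read_trait_table(path: PathLike) -> pd.DataFrame:
    """Read a plot-level trait table into a validated DataFrame.

    One row per plot with columns ``plot_id, environment, genotype_id,
    replicate, block`` plus any of the trait columns.  Unparseable trait
    cells become missing with a logged warning; rows violating a trait
    invariant (score outside 1-9, negative count/weight) are dropped with a
    logged warning.  A missing mandatory column is a hard error.
    """
    raw = _read_csv(path)
    raw.columns = [_COLUMN_ALIASES.get(c.strip(), c.strip()) for c in raw.columns]
    for col in _MANDATORY:
        if col not in raw.columns:
            raise ValueError(f"trait table {path}: missing mandatory column {col!r}")

    out: dict[str, list] = {c: [] for c in raw.columns}
    n_rejected = 0
    for idx, row in raw.iterrows():
        parsed, ok = _parse_trait_row(row, idx)
        if not ok:
            n_rejected += 1
            continue
        for c in raw.columns:
            out[c].append(parsed[c])
    df = pd.DataFrame(out, columns=list(raw.columns))
    df["replicate"] = df["replicate"].astype(int)
    if "block" in df.columns:
        df["block"] = df["block"].astype(int)
    bad_env = set(df["environment"]) - set(ENVIRONMENTS)
    if bad_env:
        raise ValueError(f"trait table {path}: unknown environment(s) {sorted(bad_env)}")
    dup = df.duplicated(subset=["environment", "replicate", "plot_id"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            f"trait table {path}: duplicate (environment, replicate, plot_id) = "
            f"({first['environment']}, {first['replicate']}, {first['plot_id']})"
        )
    if n_rejected:
        logger.warning("%s: rejected %d row(s); see preceding warnings", path, n_rejected)
    return df


def _parse_trait_row(row: pd.Series, idx) -> tuple[dict, bool]:
    parsed = {}
    for col, value in row.items():
        if col in _MANDATORY or col == "block":
            if value is None or (isinstance(value, float) and np.isnan(value)):
                logger.warning("row %s: missing mandatory cell %r; row rejected", idx, col)
                return parsed, False
            parsed[col] = value
            continue
        if value is None or (isinstance(value, float) and np.isnan(value)):
            parsed[col] = np.nan
            continue
        try:
            x = float(value)
        except (TypeError, ValueError):
            logger.warning("row %s: unparseable %s cell %r set to missing", idx, col, value)
            parsed[col] = np.nan
            continue
        if col in SCORE_TRAITS and not (1.0 <= x <= 9.0):
            logger.warning(
                "row %s: %s=%g outside the 1-9 score range; row rejected", idx, col, x
            )
            return parsed, False
        if col in NONNEGATIVE_TRAITS and x < 0:
            logger.warning("row %s: %s=%g negative; row rejected", idx, col, x)
            return parsed, False
        parsed[col] = x
    return parsed, True


def write_trait_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, na_rep="NA")


def read_striga_counts(path: PathLike) -> list[StrigaCountSeries]:
    """Read long-format (plot, environment, day, count) rows into series.

    Rows are grouped per (environment, plot) and sorted by day.  Duplicate
    (plot, day) observations and negative counts are hard errors.
    """
    df = pd.read_csv(path, na_values=list(_NA), keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        plot = cols.get("plot_id", cols.get("plot"))
        env = cols.get("environment", cols.get("env"))
        day = cols.get("day", cols.get("das"))
        count = cols["count"]
        if plot is None or env is None or day is None:
            raise KeyError
    except KeyError:
        raise ValueError(
            f"striga count file {path}: need columns plot, environment, day, count"
        ) from None
    if (df[count].astype(float) < 0).any():
        bad = df[df[count].astype(float) < 0].iloc[0]
        raise ValueError(
            f"striga count file {path}: negative count for plot {bad[plot]!r} day {bad[day]}"
        )
    dup = df.duplicated(subset=[env, plot, day])
    if dup.any():
        bad = df.loc[dup.idxmax()]
        raise ValueError(
            f"striga count file {path}: duplicate observation "
            f"(plot {bad[plot]!r}, day {bad[day]})"
        )
    series = []
    for (e, p), grp in df.groupby([env, plot], sort=True):
        grp = grp.sort_values(day)
        series.append(
            StrigaCountSeries(
                plot_id=str(p),
                environment=str(e),
                assessment_days=tuple(int(d) for d in grp[day]),
                counts=tuple(int(c) for c in grp[count]),
            )
        )
    return series


def write_striga_counts(series: Iterable[StrigaCountSeries], path: PathLike) -> None:
    rows = [
        {"plot_id": s.plot_id, "environment": s.environment, "day": d, "count": c}
        for s in series
        for d, c in zip(s.assessment_days, s.counts)
    ]
    pd.DataFrame(rows, columns=["plot_id", "environment", "day", "count"]).to_csv(
        path, index=False
    )


def read_cross_registry(path: PathLike) -> pd.DataFrame:
    """Read a cross registry: columns ``id, female, male``.

    ``id`` is the F4 entry id (phenotypic tables) or a progeny sample id
    (SNP matrix).  A ``cross_id`` column ``female x male`` is added; crosses
    are directional, so A x B and B x A stay distinct.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "female", "male"):
        if col not in df.columns:
            raise ValueError(f"cross registry {path}: missing column {col!r}")
    if df["id"].duplicated().any():
        raise ValueError(f"cross registry {path}: duplicate id")
    df = df.copy()
    df["cross_id"] = df["female"] + " x " + df["male"]
    return df


def write_cross_registry(df: pd.DataFrame, path: PathLike) -> None:
    df[["id", "female", "male"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SNP matrices


def read_snp_matrix(path: PathLike) -> SNPMatrix:
    """Read a sample x marker dosage matrix (first column = sample id)."""
    df = pd.read_csv(path, index_col=0, na_values=list(_NA), keep_default_na=False)
    return SNPMatrix(
        sample_ids=[str(s) for s in df.index],
        marker_ids=[str(m) for m in df.columns],
        calls=df.to_numpy(dtype=float),
    )


def write_snp_matrix(matrix: SNPMatrix, path: PathLike) -> None:
    df = pd.DataFrame(matrix.calls, index=matrix.sample_ids, columns=matrix.marker_ids)
    # keep integral dosages unpadded in the text output
    df.to_csv(path, index_label="sample_id", na_rep="NA", float_format="%.0f")


def read_vcf(path: PathLike) -> SNPMatrix:
    """Read diploid biallelic genotypes from a VCF into dosage coding.

    Multi-allelic sites are skipped with a warning.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_ids, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("VCF %s: skipping multi-allelic site %s", path, variant.ID)
            continue
        mid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gts012: 0/1/2 = dosage, 3 = missing
        gt = np.asarray(variant.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        marker_ids.append(mid)
        columns.append(gt)
    calls = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return SNPMatrix(samples, marker_ids, calls)


# ---------------------------------------------------------------------------
# Trees


def write_newick(tree: skbio.TreeNode, path: PathLike) -> None:
    """Serialize a tree to Newick with branch lengths.

    Labels containing whitespace or punctuation are quoted; branch lengths
    are written with 6 significant digits.
    """
    for node in tree.traverse(include_self=False):
        if node.length is not None:
            node.length = float(f"{node.length:.6g}")
    tree.write(str(path), format="newick")


def read_newick(path: PathLike) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")
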