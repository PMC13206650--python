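"""Containers and ingestion for multi-tissue circadian expression matrices.

The basic unit is a :class:`TimeSeriesExpression`: one tissue under one
feeding condition, holding a gene x time matrix sampled over a single 24-h
cycle. A :class:`StudyDataset` bundles all (condition, tissue) series of a
study on a common time grid.

Preprocessing follows the conventional order for correlation-based
coordination analyses: biological replicates are averaged first, detection
filtering and gene-set restriction are applied to the averaged profiles, and
min-max normalization (per gene, across time) is applied only on the paths
that feed correlation or clustering — never on amplitude paths, which need
the original expression scale.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    EmptyResultError,
    TableFormatError,
    TableParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesExpression",
    "StudyDataset",
    "TableLayout",
    "read_expression_table",
    "write_expression_table",
    "average_replicates",
    "filter_detected",
    "filter_gene_set",
    "minmax_normalize",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class TimeSeriesExpression:
    """Gene x time expression matrix for one tissue under one condition.

    When ``replicate_averaged`` is False the matrix holds one column per
    (timepoint, replicate) pair and ``column_timepoint_idx[j]`` gives the
    index into ``timepoints_h`` for column ``j``.
    """

    tissue_id: str
    condition_id: str
    genes: tuple[str, ...]
    timepoints_h: np.ndarray
    values: np.ndarray
    replicate_averaged: bool = True
    column_timepoint_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        genes = tuple(str(g).strip() for g in self.genes)
        object.__setattr__(self, "genes", genes)
        tp = np.asarray(self.timepoints_h, dtype=float)
        object.__setattr__(self, "timepoints_h", tp)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if tp.ndim != 1 or len(tp) < 3:
            raise ValidationError("need at least 3 timepoints in a 24-h series")
        if np.any(np.diff(tp) <= 0):
            raise ValidationError("timepoints_h must be strictly increasing")
        if tp[0] < 0 or tp[-1] >= 24:
            raise ValidationError("timepoints_h must lie in [0, 24)")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValidationError(f"duplicate gene symbols: {dupes}")
        if vals.ndim != 2 or vals.shape[0] != len(genes):
            raise ValidationError("values must be a genes x columns matrix")
        if self.replicate_averaged:
            if vals.shape[1] != len(tp):
                raise ValidationError(
                    f"expected {len(tp)} columns for averaged series, got {vals.shape[1]}"
                )
            if not np.all(np.isfinite(vals)):
                raise ValidationError("averaged series must have no missing entries")
        else:
            idx = self.column_timepoint_idx
            if idx is None:
                raise ValidationError(
                    "replicate-level series require column_timepoint_idx"
                )
            idx = np.asarray(idx, dtype=int)
            object.__setattr__(self, "column_timepoint_idx", idx)
            if idx.shape != (vals.shape[1],):
                raise ValidationError("column_timepoint_idx length must match columns")
            if idx.min() < 0 or idx.max() >= len(tp):
                raise ValidationError("column_timepoint_idx out of range")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints_h)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in tissue {self.tissue_id!r}") from None

    def profile(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset(self, genes: Iterable[str]) -> "TimeSeriesExpression":
        """Restrict to ``genes`` (kept in this series' original order)."""
        keep = set(genes)
        rows = [i for i, g in enumerate(self.genes) if g in keep]
        return replace(
            self,
            genes=tuple(self.genes[i] for i in rows),
            values=self.values[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        if self.replicate_averaged:
            cols = [_zt_name(t) for t in self.timepoints_h]
        else:
            cols = []
            rep_counter: dict[int, int] = {}
            for ti in self.column_timepoint_idx:  # type: ignore[union-attr]
                rep_counter[ti] = rep_counter.get(ti, 0) + 1
                cols.append(f"{_zt_name(self.timepoints_h[ti])}_rep{rep_counter[ti]}")
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "gene", list(self.genes))
        return df


@dataclass
class StudyDataset:
    """All (condition, tissue) expression series of one study."""

    conditions: tuple[str, ...]
    tissues: tuple[str, ...]
    series: dict[tuple[str, str], TimeSeriesExpression]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.tissues = tuple(self.tissues)
        grids: dict[str, np.ndarray] = {}
        for (cond, tissue), ts in self.series.items():
            if ts.condition_id != cond or ts.tissue_id != tissue:
                raise ValidationError(
                    f"series key {(cond, tissue)} does not match ids "
                    f"({ts.condition_id!r}, {ts.tissue_id!r})"
                )
            if cond in grids:
                if not np.array_equal(grids[cond], ts.timepoints_h):
                    raise ValidationError(
                        f"time grids differ within condition {cond!r}"
                    )
            else:
                grids[cond] = ts.timepoints_h

    def get(self, condition: str, tissue: str) -> TimeSeriesExpression:
        return self.series[(condition, tissue)]

    def condition_series(self, condition: str) -> dict[str, TimeSeriesExpression]:
        return {
            t: self.series[(condition, t)]
            for t in self.tissues
            if (condition, t) in self.series
        }

    def map_series(self, func) -> "StudyDataset":
        """Apply ``func`` to every series, returning a new dataset."""
        return StudyDataset(
            conditions=self.conditions,
            tissues=self.tissues,
            series={k: func(v) for k, v in self.series.items()},
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class TableLayout:
    """Declares how a delimited expression table is organized.

    ``orientation`` is ``"wide"`` (genes as rows, columns like ``ZT0`` or
    ``ZT0_rep1``) or ``"long"`` (one row per gene/timepoint/replicate).
    """

    delimiter: str = "\t"
    orientation: str = "wide"
    gene_column: str = "gene"
    time_prefix: str = "ZT"
    replicate_sep: str = "_rep"
    time_column: str = "timepoint_h"
    replicate_column: str = "replicate"
    value_column: str = "value"
    tissue_id: str = ""
    condition_id: str = ""


def _zt_name(t: float) -> str:
    return f"ZT{t:g}"


def read_expression_table(path, layout: TableLayout = TableLayout()) -> TimeSeriesExpression:
    """Read one tissue/condition expression table.

    Replicate-level tables (any column carrying the replicate suffix) are
    returned un-averaged with ``replicate_averaged=False``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=layout.delimiter, dtype=str)
    if layout.orientation == "long":
        return _read_long(df, layout, path)
    if layout.gene_column not in df.columns:
        raise TableFormatError(
            f"{path}: missing gene-identifier column {layout.gene_column!r}"
        )
    genes = [str(g).strip() for g in df[layout.gene_column]]
    dupes = sorted({g for g in genes if genes.count(g) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate gene symbols: {dupes}")

    expr_cols = [c for c in df.columns if c != layout.gene_column]
    parsed: list[tuple[float, int, str]] = []  # (time, replicate ordinal, column)
    has_reps = False
    for col in expr_cols:
        name = col.strip()
        if not name.startswith(layout.time_prefix):
            raise TableFormatError(
                f"{path}: column {col!r} does not start with {layout.time_prefix!r}"
            )
        body = name[len(layout.time_prefix):]
        if layout.replicate_sep in body:
            t_str, rep_str = body.split(layout.replicate_sep, 1)
            has_reps = True
            rep_match = re.match(r"(\d+)", rep_str)
            if rep_match is None:
                raise TableFormatError(f"{path}: cannot parse replicate in {col!r}")
            rep = int(rep_match.group(1))
        else:
            t_str, rep = body, 1
        try:
            t = float(t_str)
        except ValueError:
            raise TableFormatError(f"{path}: cannot parse timepoint in {col!r}") from None
        parsed.append((t, rep, col))
    if not parsed:
        raise TableFormatError(f"{path}: no expression columns found")
    parsed.sort(key=lambda x: (x[0], x[1]))
    timepoints = sorted({t for t, _, _ in parsed})
    tp_index = {t: i for i, t in enumerate(timepoints)}

    values = np.empty((len(genes), len(parsed)))
    col_tp_idx = np.array([tp_index[t] for t, _, _ in parsed], dtype=int)
    for j, (_, _, col) in enumerate(parsed):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at "
                f"gene {genes[row]!r} (row {row}), column {col!r}"
            )
        # python float() is correctly rounded (exact round trip of repr());
        # pandas' fast to_numeric parser is not
        values[:, j] = [float(v) for v in df[col]]

    averaged = not has_reps and len(parsed) == len(timepoints)
    return TimeSeriesExpression(
        tissue_id=layout.tissue_id,
        condition_id=layout.condition_id,
        genes=tuple(genes),
        timepoints_h=np.array(timepoints, dtype=float),
        values=values,
        replicate_averaged=averaged,
        column_timepoint_idx=None if averaged else col_tp_idx,
    )


def _read_long(df: pd.DataFrame, layout: TableLayout, path: Path) -> TimeSeriesExpression:
    needed = [layout.gene_column, layout.time_column, layout.value_column]
    for col in needed:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r} in long layout")
    has_reps = layout.replicate_column in df.columns
    work = df.copy()
    work[layout.time_column] = pd.to_numeric(work[layout.time_column], errors="raise")
    numeric = pd.to_numeric(work[layout.value_column], errors="coerce")
    bad = numeric.isna() & work[layout.value_column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableParseError(
            f"{path}: non-numeric value {work[layout.value_column].iloc[row]!r} "
            f"at row {row}"
        )
    work[layout.value_column] = numeric
    rep = work[layout.replicate_column] if has_reps else 1
    work = work.assign(_rep=rep)
    genes = list(dict.fromkeys(str(g).strip() for g in work[layout.gene_column]))
    pivot = work.pivot_table(
        index=layout.gene_column,
        columns=[layout.time_column, "_rep"],
        values=layout.value_column,
        aggfunc="first",
        sort=True,
    ).reindex([g for g in genes])
    timepoints = sorted({t for t, _ in pivot.columns})
    tp_index = {t: i for i, t in enumerate(timepoints)}
    col_tp_idx = np.array([tp_index[t] for t, _ in pivot.columns], dtype=int)
    averaged = not has_reps
    return TimeSeriesExpression(
        tissue_id=layout.tissue_id,
        condition_id=layout.condition_id,
        genes=tuple(genes),
        timepoints_h=np.array(timepoints, dtype=float),
        values=pivot.to_numpy(dtype=float),
        replicate_averaged=averaged,
        column_timepoint_idx=None if averaged else col_tp_idx,
    )


def write_expression_table(series: TimeSeriesExpression, path, delimiter: str = "\t") -> None:
    """Write a series as a wide delimited table (round-trip exact)."""
    df = series.to_frame()
    # repr() of a float round-trips exactly; pandas' default formatting may not
    for col in df.columns:
        if col != "gene":
            df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, sep=delimiter, index=False)


def average_replicates(series: TimeSeriesExpression) -> TimeSeriesExpression:
    """Collapse replicate columns to the per-timepoint arithmetic mean."""
    if series.replicate_averaged:
        return series
    idx = series.column_timepoint_idx
    assert idx is not None
    counts = np.bincount(idx, minlength=series.n_timepoints)
    if np.any(counts == 0):
        missing = [series.timepoints_h[i] for i in np.flatnonzero(counts == 0)]
        raise ValidationError(f"timepoints with zero replicates: {missing}")
    if len(set(counts.tolist())) > 1:
        logger.info(
            "tissue %s/%s: unequal replicate counts across timepoints: %s",
            series.condition_id, series.tissue_id, counts.tolist(),
        )
    out = np.zeros((series.n_genes, series.n_timepoints))
    for ti in range(series.n_timepoints):
        out[:, ti] = series.values[:, idx == ti].mean(axis=1)
    return replace(
        series,
        values=out,
        replicate_averaged=True,
        column_timepoint_idx=None,
    )


def filter_detected(
    series: TimeSeriesExpression,
    min_value: float = 0.0,
    require_all_timepoints: bool = True,
) -> TimeSeriesExpression:
    """Keep genes detected (expression > ``min_value``) at the sampled timepoints.

    With ``require_all_timepoints`` (default) a gene must exceed the
    threshold at every timepoint; otherwise at any timepoint.
    """
    if not series.replicate_averaged:
        raise ValidationError("filter_detected requires a replicate-averaged series")
    above = series.values > min_value
    keep = above.all(axis=1) if require_all_timepoints else above.any(axis=1)
    retained = [g for g, k in zip(series.genes, keep) if k]
    if not retained:
        raise EmptyResultError(
            f"tissue {series.tissue_id!r}: no genes detected above {min_value}; "
            "review the detection threshold"
        )
    logger.info(
        "tissue %s/%s: detection filter retained %d of %d genes",
        series.condition_id, series.tissue_id, len(retained), series.n_genes,
    )
    return series.subset(retained)


def filter_gene_set(dataset: StudyDataset, annotation) -> StudyDataset:
    """Restrict every series to genes in the annotation universe.

    ``annotation`` is either a plain set of gene symbols or any object with a
    ``universe_genes`` attribute (e.g. a parsed pathway annotation).
    """
    universe = getattr(annotation, "universe_genes", annotation)
    universe = set(universe)
    if not universe:
        raise ValidationError("annotation universe is empty")

    def restrict(ts: TimeSeriesExpression) -> TimeSeriesExpression:
        out = ts.subset(universe)
        if out.n_genes == 0:
            raise EmptyResultError(
                f"tissue {ts.tissue_id!r}: no overlap with annotation universe"
            )
        logger.info(
            "tissue %s/%s: gene-set filter retained %d of %d genes",
            ts.condition_id, ts.tissue_id, out.n_genes, ts.n_genes,
        )
        return out

    return dataset.map_series(restrict)


def minmax_normalize(series: TimeSeriesExpression) -> TimeSeriesExpression:
    """Map each gene to (x - min)/(max - min) across its own timepoints.

    Constant genes (zero temporal variance) are dropped with a warning:
    Pearson correlation is undefined for them and min-max has no scale.
    Intended only for correlation/clustering paths; amplitude analyses use
    the original expression units.
    """
    if not series.replicate_averaged:
        raise ValidationError("minmax_normalize requires a replicate-averaged series")
    lo = series.values.min(axis=1, keepdims=True)
    hi = series.values.max(axis=1, keepdims=True)
    span = (hi - lo).ravel()
    constant = span == 0
    if constant.any():
        dropped = [g for g, c in zip(series.genes, constant) if c]
        logger.warning(
            "tissue %s/%s: dropping %d constant gene(s) before normalization: %s",
            series.condition_id, series.tissue_id, len(dropped), dropped[:10],
        )
    keep = ~constant
    vals = (series.values[keep] - lo[keep]) / (hi[keep] - lo[keep])
    return replace(
        series,
        genes=tuple(g for g, k in zip(series.genes, keep) if k),
        values=vals,
    )


def write_dataset(dataset: StudyDataset, out_dir) -> None:
    """Write one wide TSV per (condition, tissue) plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (cond, tissue), ts in sorted(dataset.series.items()):
        write_expression_table(ts, out_dir / f"{cond}__{tissue}.tsv")
    meta = {
        "conditions": list(dataset.conditions),
        "tissues": list(dataset.tissues),
        "provenance": dataset.provenance,
    }
    (out_dir / "dataset.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_dataset(in_dir) -> StudyDataset:
    """Read a dataset written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "dataset.json").read_text())
    series: dict[tuple[str, str], TimeSeriesExpression] = {}
    for cond in meta["conditions"]:
        for tissue in meta["tissues"]:
            path = in_dir / f"{cond}__{tissue}.tsv"
            if not path.exists():
                continue
            layout = TableLayout(tissue_id=tissue, condition_id=cond)
            series[(cond, tissue)] = read_expression_table(path, layout)
    return StudyDataset(
        conditions=tuple(meta["conditions"]),
        tissues=tuple(meta["tissues"]),
        series=series,
        provenance=meta.get("provenance", ""),
    )
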