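"""Inter-tissue temporal-coordination analysis.

For every unordered pair of tissues within one feeding condition, gene
profiles from the two tissues are cross-correlated over the shared 24-h
grid, either

* ``all_pairs`` — every gene in tissue A against every gene in tissue B
  (the same construction as the intra-tissue matrices, applied across the
  tissue boundary), or
* ``same_gene`` — each gene against itself across the two tissues (the
  construction underlying the whole-body synchronization score).

Pair-level summaries (mean |r|, significant-entry counts) roll up into a
per-tissue summed coordination strength Sigma|r| and a network edge table
for external graph tools.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import TimeSeriesExpression
from .errors import ValidationError
from .intra import _standardize_rows
from .stats import critical_r

logger = logging.getLogger(__name__)

__all__ = [
    "CrossCorrelation",
    "TissuePairSummary",
    "TissueSigma",
    "cross_correlation_matrix",
    "summarize_pair",
    "tissue_sigma",
    "relative_change",
    "network_edges",
    "condition_pair_summaries",
]


@dataclass(frozen=True)
class CrossCorrelation:
    """Cross-tissue Pearson matrix (all_pairs) or same-gene vector."""

    tissue_a: str
    tissue_b: str
    condition_id: str
    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]
    r: np.ndarray  # 2-D (all_pairs) or 1-D (same_gene, over shared genes)
    n_timepoints: int
    mode: str


@dataclass(frozen=True)
class TissuePairSummary:
    tissue_a: str
    tissue_b: str
    mean_abs_r: float
    n_significant: int
    n_entries: int
    mode: str
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.tissue_a == self.tissue_b:
            raise ValidationError("tissue pair must involve two distinct tissues")


@dataclass(frozen=True)
class TissueSigma:
    tissue: str
    sigma_abs_r: float
    n_pairs: int


def cross_correlation_matrix(
    series_a: TimeSeriesExpression,
    series_b: TimeSeriesExpression,
    mode: str = "all_pairs",
) -> CrossCorrelation:
    """Pearson correlations between gene profiles of two tissues.

    Both series must be replicate-averaged, share the time grid, and contain
    no constant genes.
    """
    if mode not in ("all_pairs", "same_gene"):
        raise ValidationError(f"unknown mode {mode!r}")
    if not (series_a.replicate_averaged and series_b.replicate_averaged):
        raise ValidationError("cross-correlation requires replicate-averaged series")
    if not np.array_equal(series_a.timepoints_h, series_b.timepoints_h):
        raise ValidationError(
            f"time grids differ between tissues {series_a.tissue_id!r} "
            f"and {series_b.tissue_id!r}"
        )
    if mode == "all_pairs":
        za = _standardize_rows(series_a.values)
        zb = _standardize_rows(series_b.values)
        r = np.clip(za @ zb.T, -1.0, 1.0)
        genes_a, genes_b = series_a.genes, series_b.genes
    else:
        shared = [g for g in series_a.genes if g in set(series_b.genes)]
        if not shared:
            raise ValidationError(
                f"no shared genes between tissues {series_a.tissue_id!r} "
                f"and {series_b.tissue_id!r}"
            )
        za = _standardize_rows(np.array([series_a.profile(g) for g in shared]))
        zb = _standardize_rows(np.array([series_b.profile(g) for g in shared]))
        r = np.clip(np.sum(za * zb, axis=1), -1.0, 1.0)
        genes_a = genes_b = tuple(shared)
    return CrossCorrelation(
        tissue_a=series_a.tissue_id,
        tissue_b=series_b.tissue_id,
        condition_id=series_a.condition_id,
        genes_a=genes_a,
        genes_b=genes_b,
        r=r,
        n_timepoints=series_a.n_timepoints,
        mode=mode,
    )


def summarize_pair(xc: CrossCorrelation, alpha: float = 0.05) -> TissuePairSummary:
    """Mean |r| and significant-entry count over all cross-tissue entries."""
    flat = np.abs(xc.r).ravel()
    r_crit = critical_r(xc.n_timepoints, alpha)
    return TissuePairSummary(
        tissue_a=xc.tissue_a,
        tissue_b=xc.tissue_b,
        mean_abs_r=float(flat.mean()),
        n_significant=int(np.sum(flat > r_crit)),
        n_entries=int(flat.size),
        mode=xc.mode,
        alpha=alpha,
    )


def tissue_sigma(summaries: Sequence[TissuePairSummary]) -> list[TissueSigma]:
    """Per-tissue summed coordination strength Sigma|r| over incident pairs.

    Requires the summaries to cover every unordered pair of the implied
    tissue set exactly once.
    """
    tissues = sorted({s.tissue_a for s in summaries} | {s.tissue_b for s in summaries})
    seen = {tuple(sorted((s.tissue_a, s.tissue_b))) for s in summaries}
    expected = {tuple(sorted(p)) for p in itertools.combinations(tissues, 2)}
    missing = expected - seen
    if missing:
        raise ValidationError(f"missing tissue pairs: {sorted(missing)[:5]}")
    if len(seen) != len(summaries):
        raise ValidationError("duplicate tissue pairs in summaries")
    sigma = {t: 0.0 for t in tissues}
    for s in summaries:
        sigma[s.tissue_a] += s.mean_abs_r
        sigma[s.tissue_b] += s.mean_abs_r
    return [
        TissueSigma(tissue=t, sigma_abs_r=sigma[t], n_pairs=len(tissues) - 1)
        for t in tissues
    ]


def relative_change(value_alf: float, value_trf: float, mode: str = "fraction") -> float:
    """Relative change from the control (ALF) to the restricted (TRF) value.

    ``fraction`` returns (TRF - ALF)/ALF; ``ratio`` returns TRF/ALF.
    """
    if mode not in ("fraction", "ratio"):
        raise ValidationError(f"unknown mode {mode!r}")
    if value_alf == 0:
        raise ValidationError("relative change undefined for a zero baseline value")
    if mode == "ratio":
        return value_trf / value_alf
    return (value_trf - value_alf) / value_alf


def network_edges(summaries: Sequence[TissuePairSummary]) -> pd.DataFrame:
    """Edge table (tissue_a, tissue_b, mean_abs_r, n_significant) for graph tools."""
    rows = [
        {
            "tissue_a": min(s.tissue_a, s.tissue_b),
            "tissue_b": max(s.tissue_a, s.tissue_b),
            "mean_abs_r": s.mean_abs_r,
            "n_significant": s.n_significant,
        }
        for s in summaries
    ]
    return (
        pd.DataFrame(rows, columns=["tissue_a", "tissue_b", "mean_abs_r", "n_significant"])
        .sort_values(["tissue_a", "tissue_b"])
        .reset_index(drop=True)
    )


def condition_pair_summaries(
    series_by_tissue: Mapping[str, TimeSeriesExpression],
    mode: str = "all_pairs",
    alpha: float = 0.05,
) -> list[TissuePairSummary]:
    """Summaries for every unordered tissue pair of one condition."""
    tissues = sorted(series_by_tissue)
    if len(tissues) < 2:
        raise ValidationError("need >= 2 tissues")
    out = []
    for ta, tb in itertools.combinations(tissues, 2):
        xc = cross_correlation_matrix(series_by_tissue[ta], series_by_tissue[tb], mode)
        out.append(summarize_pair(xc, alpha=alpha))
    return out
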