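"""Whole-body synchronization scoring, threshold calibration, wave clusters.

The per-gene whole-body synchronization score is

    S_g = sum over unordered tissue pairs (A, B) of r(x_gA, x_gB),

where x_gA is gene g's 24-h profile in tissue A and r the sample Pearson
coefficient. Signs are preserved (no |r|) so anti-phased tissues pull the
score down: the score rewards in-phase alignment specifically. With T
tissues the maximum is C(T, 2) (231 for T = 22), attained only when every
pairwise correlation is exactly 1.

A "clock-like" threshold on the score is calibrated from a benchmark gene
panel (canonical circadian clock genes): the benchmark scores are sorted
descending and the threshold is placed in the first pronounced decline —
either the single largest gap (``largest_gap``), the first gap from the top
exceeding a multiple of the median gap (``first_gap``), or a user-supplied
value (``manual``). Genes scoring at or above the threshold form the
globally synchronized set, which is then clustered into temporal waves by
complete linkage on 1 - r at a fixed dendrogram height.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datasets import StudyDataset, TimeSeriesExpression, minmax_normalize
from .errors import ValidationError
from .intra import _standardize_rows

logger = logging.getLogger(__name__)

__all__ = [
    "SyncScoreTable",
    "ThresholdCalibration",
    "WaveClustering",
    "SetOverlap",
    "sync_score",
    "score_table",
    "calibrate_threshold",
    "global_set",
    "overlap_sets",
    "whole_body_waveform",
    "wave_clusters",
]


@dataclass(frozen=True)
class SyncScoreTable:
    """Per-gene signed whole-body synchronization scores for one condition."""

    condition: str
    scores: dict[str, float]
    n_pairs_used: dict[str, int]
    tissues_used: tuple[str, ...]

    @property
    def mean_score(self) -> float:
        return float(np.mean(list(self.scores.values())))

    def ranked(self) -> list[tuple[str, float]]:
        """Genes by descending score, alphabetical tie-break."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class ThresholdCalibration:
    benchmark_scores: tuple[float, ...]  # sorted descending
    strategy: str
    threshold: float
    boundary_genes: tuple[str, str] | None = None


@dataclass(frozen=True)
class WaveClustering:
    labels: dict[str, int]
    cut_height: float
    n_clusters: int
    timepoints_h: np.ndarray
    # cluster -> (mean, sd) whole-body waveform across member genes
    whole_body: dict[int, tuple[np.ndarray, np.ndarray]]
    # (cluster, tissue) -> mean waveform across member genes
    per_tissue: dict[tuple[int, str], np.ndarray]


@dataclass(frozen=True)
class SetOverlap:
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    shared: tuple[str, ...]
    unique_a: tuple[str, ...]
    unique_b: tuple[str, ...]


def _gene_tissue_profiles(
    dataset: StudyDataset, condition: str, gene: str
) -> dict[str, np.ndarray]:
    """Gene's profile per tissue, skipping tissues where it is absent/constant."""
    out: dict[str, np.ndarray] = {}
    for tissue, ts in dataset.condition_series(condition).items():
        if gene in ts.genes:
            prof = ts.profile(gene)
            if np.ptp(prof) > 0:
                out[tissue] = prof
    return out


def sync_score(gene: str, dataset: StudyDataset, condition: str) -> tuple[float, int]:
    """Signed sum of same-gene Pearson r over all unordered tissue pairs.

    Tissues where the gene is absent or constant are skipped; the returned
    pair count reflects the pairs actually used.
    """
    profiles = _gene_tissue_profiles(dataset, condition, gene)
    if len(profiles) < 2:
        raise ValidationError(
            f"gene {gene!r} usable in {len(profiles)} tissue(s); need >= 2"
        )
    mat = np.array([profiles[t] for t in sorted(profiles)])
    z = _standardize_rows(mat)
    m = z.shape[0]
    total = z.sum(axis=0)
    score = (float(total @ total) - m) / 2.0
    return score, m * (m - 1) // 2


def score_table(
    dataset: StudyDataset,
    condition: str,
    require_all_tissues: bool = True,
) -> SyncScoreTable:
    """Synchronization scores for every eligible gene of one condition.

    With ``require_all_tissues`` (default) a gene must be present and
    non-constant in every tissue, so every score shares the C(T, 2) pair
    ceiling; otherwise genes are scored over the tissue pairs available to
    them, with the pair count reported per gene.
    """
    series = dataset.condition_series(condition)
    tissues = sorted(series)
    if len(tissues) < 2:
        raise ValidationError("score_table requires >= 2 tissues")
    # genes usable (present, non-constant) per tissue
    usable: dict[str, set[str]] = {}
    for t in tissues:
        ts = series[t]
        ok = np.ptp(ts.values, axis=1) > 0
        usable[t] = {g for g, k in zip(ts.genes, ok) if k}
    if require_all_tissues:
        eligible = sorted(set.intersection(*usable.values()))
    else:
        from collections import Counter

        counts = Counter(g for s in usable.values() for g in s)
        eligible = sorted(g for g, c in counts.items() if c >= 2)
    if not eligible:
        raise ValidationError("no eligible genes for synchronization scoring")

    gene_idx = {g: i for i, g in enumerate(eligible)}
    T = len(tissues)
    nt = series[tissues[0]].n_timepoints
    z_sum = np.zeros((len(eligible), nt))
    m = np.zeros(len(eligible), dtype=int)
    for t in tissues:
        ts = series[t]
        rows = [i for i, g in enumerate(ts.genes) if g in gene_idx and g in usable[t]]
        if not rows:
            continue
        z = _standardize_rows(ts.values[rows])
        tgt = [gene_idx[ts.genes[i]] for i in rows]
        z_sum[tgt] += z
        m[tgt] += 1
    # sum of pairwise dot products = (|sum z|^2 - sum |z|^2) / 2, |z| = 1
    scores = (np.einsum("ij,ij->i", z_sum, z_sum) - m) / 2.0
    return SyncScoreTable(
        condition=condition,
        scores={g: float(scores[gene_idx[g]]) for g in eligible},
        n_pairs_used={g: int(m[gene_idx[g]] * (m[gene_idx[g]] - 1) // 2) for g in eligible},
        tissues_used=tuple(tissues),
    )


def calibrate_threshold(
    benchmark_scores,
    strategy: str = "largest_gap",
    manual_value: float | None = None,
    first_gap_factor: float = 3.0,
) -> ThresholdCalibration:
    """Place the clock-like threshold in the benchmark score distribution.

    ``benchmark_scores`` is a mapping gene -> score or a plain sequence of
    scores. Gap strategies sort scores descending and place the threshold at
    the midpoint of the detected drop between consecutive scores, so the pass
    set equals "everything at or above the last gene before the drop".
    """
    if isinstance(benchmark_scores, dict):
        items = sorted(benchmark_scores.items(), key=lambda kv: (-kv[1], kv[0]))
        names = [g for g, _ in items]
        scores = [s for _, s in items]
    else:
        scores = sorted((float(s) for s in benchmark_scores), reverse=True)
        names = None
    if len(scores) < 3:
        raise ValidationError("threshold calibration requires >= 3 benchmark scores")
    if strategy == "manual":
        if manual_value is None:
            raise ValidationError("manual strategy requires manual_value")
        return ThresholdCalibration(
            benchmark_scores=tuple(scores),
            strategy="manual",
            threshold=float(manual_value),
        )
    gaps = [scores[i] - scores[i + 1] for i in range(len(scores) - 1)]
    if strategy == "largest_gap":
        i = int(np.argmax(gaps))
    elif strategy == "first_gap":
        median_gap = float(np.median(gaps))
        i = next(
            (k for k, g in enumerate(gaps) if g > first_gap_factor * median_gap),
            None,
        )
        if i is None:
            logger.info("first_gap: no pronounced decline; falling back to largest_gap")
            i = int(np.argmax(gaps))
    else:
        raise ValidationError(f"unknown threshold strategy {strategy!r}")
    threshold = (scores[i] + scores[i + 1]) / 2.0
    boundary = (names[i], names[i + 1]) if names is not None else None
    return ThresholdCalibration(
        benchmark_scores=tuple(scores),
        strategy=strategy,
        threshold=float(threshold),
        boundary_genes=boundary,
    )


def global_set(table: SyncScoreTable, threshold: float) -> list[str]:
    """Genes with score >= threshold, by descending score (alphabetical ties)."""
    return [g for g, s in table.ranked() if s >= threshold]


def overlap_sets(set_a, set_b) -> SetOverlap:
    """Set algebra on two gene sets (e.g. the ALF and TRF global sets)."""
    a, b = set(set_a), set(set_b)
    return SetOverlap(
        n_shared=len(a & b),
        n_unique_a=len(a - b),
        n_unique_b=len(b - a),
        shared=tuple(sorted(a & b)),
        unique_a=tuple(sorted(a - b)),
        unique_b=tuple(sorted(b - a)),
    )


def whole_body_waveform(
    gene: str,
    dataset: StudyDataset,
    condition: str,
    normalize: bool = True,
):
    """Cross-tissue mean +/- SEM profile of one gene, plus per-tissue profiles.

    Per-tissue profiles are min-max normalized by default and returned
    ordered by peak time (earliest first, ties by tissue name).
    Returns (mean, sem, ordered list of (tissue, profile)).
    """
    series = dataset.condition_series(condition)
    profiles: list[tuple[str, np.ndarray]] = []
    for tissue in sorted(series):
        ts = series[tissue]
        if gene not in ts.genes:
            continue
        prof = ts.profile(gene)
        if normalize:
            if np.ptp(prof) == 0:
                continue
            prof = (prof - prof.min()) / np.ptp(prof)
        profiles.append((tissue, prof))
    if len(profiles) < 2:
        raise ValidationError(f"gene {gene!r} present in < 2 tissues")
    mat = np.array([p for _, p in profiles])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
    tp = series[profiles[0][0]].timepoints_h
    ordered = sorted(profiles, key=lambda kv: (tp[int(np.argmax(kv[1]))], kv[0]))
    return mean, sem, ordered


def wave_clusters(
    genes,
    dataset: StudyDataset,
    condition: str,
    cut_height: float = 1.0,
    profile_mode: str = "concatenated",
) -> WaveClustering:
    """Cluster globally synchronized genes into temporal waves.

    Gene similarity is Pearson r over either the per-tissue min-max
    normalized profiles concatenated in a fixed tissue order (default; robust
    to anti-phase tissues) or the whole-body mean waveform. Complete-linkage
    on d = 1 - r is cut at ``cut_height`` (default 1.0, the r = 0 boundary).
    Cluster labels are renumbered 1..k in order of first member appearance in
    the input gene order.
    """
    if profile_mode not in ("concatenated", "whole_body"):
        raise ValidationError(f"unknown profile_mode {profile_mode!r}")
    genes = list(genes)
    series = dataset.condition_series(condition)
    tissues = sorted(series)
    normed = {t: minmax_normalize(series[t]) for t in tissues}

    feats: list[np.ndarray] = []
    kept: list[str] = []
    for g in genes:
        parts = []
        ok = True
        for t in tissues:
            ts = normed[t]
            if g not in ts.genes:
                ok = False
                break
            parts.append(ts.profile(g))
        if not ok:
            logger.warning("wave_clusters: gene %r missing from a tissue; skipped", g)
            continue
        vec = np.concatenate(parts) if profile_mode == "concatenated" else np.mean(parts, axis=0)
        if np.ptp(vec) == 0:
            logger.warning("wave_clusters: gene %r has a constant feature; skipped", g)
            continue
        feats.append(vec)
        kept.append(g)
    if len(kept) < 2:
        raise ValidationError("wave_clusters requires >= 2 usable genes")

    z = _standardize_rows(np.array(feats))
    r = np.clip(z @ z.T, -1.0, 1.0)
    d = np.clip(1.0 - (r + r.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="complete")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    # deterministic relabel by first appearance
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for g, lab in zip(kept, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[g] = remap[lab]
    n_clusters = len(remap)

    tp = series[tissues[0]].timepoints_h
    whole_body: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    per_tissue: dict[tuple[int, str], np.ndarray] = {}
    for c in range(1, n_clusters + 1):
        members = [g for g in kept if labels[g] == c]
        # per-gene whole-body profile = mean of its per-tissue normalized profiles
        gene_profiles = np.array([
            np.mean([normed[t].profile(g) for t in tissues], axis=0) for g in members
        ])
        mean = gene_profiles.mean(axis=0)
        sd = gene_profiles.std(axis=0, ddof=1) if len(members) > 1 else np.zeros_like(mean)
        whole_body[c] = (mean, sd)
        for t in tissues:
            per_tissue[(c, t)] = np.array([normed[t].profile(g) for g in members]).mean(axis=0)
    return WaveClustering(
        labels=labels,
        cut_height=cut_height,
        n_clusters=n_clusters,
        timepoints_h=tp,
        whole_body=whole_body,
        per_tissue=per_tissue,
    )
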