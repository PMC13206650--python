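"""Hierarchical pathway-term enrichment for gene clusters.

Annotations follow the MitoCarta-style convention: each gene carries one or
more pathway *paths* — ">"-separated hierarchy strings such as
``"Metabolism > Lipid metabolism > Fatty acid oxidation"`` — and a gene is
reduced to the multiset of terms at *every* hierarchy level of every path.
A term appearing in two of a gene's paths therefore counts twice for that
gene (the occurrence-counting mode; a per-gene de-duplicated mode is
available).

For a gene cluster, two descriptive rankings are produced:

* term frequency — the term's occurrence count within the cluster; and
* term ratio — cluster count divided by the term's total occurrence count
  across the full annotation universe.

The broad category "Metabolism" is excluded by default for lack of
interpretive specificity. No enrichment p-values are computed; the output is
a ranking, not a hypothesis test.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_TERMS = frozenset({"Metabolism"})

__all__ = [
    "GeneSetAnnotation",
    "TermEnrichment",
    "parse_term_paths",
    "read_annotation_table",
    "term_frequency",
    "term_ratio",
    "universe_term_counts",
    "top_terms",
    "enrich_cluster",
    "DEFAULT_EXCLUDED_TERMS",
]


@dataclass(frozen=True)
class GeneSetAnnotation:
    """Gene -> pathway-term multiset, with exclusions and a gene universe."""

    gene_to_terms: dict[str, tuple[str, ...]]
    excluded_terms: frozenset[str] = DEFAULT_EXCLUDED_TERMS
    universe_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        universe = frozenset(self.universe_genes) or frozenset(self.gene_to_terms)
        object.__setattr__(self, "universe_genes", universe)
        missing = set(self.gene_to_terms) - universe
        if missing:
            raise ValidationError(
                f"annotated genes missing from universe: {sorted(missing)[:5]}"
            )

    def terms_for(self, gene: str, dedupe: bool = False) -> tuple[str, ...]:
        terms = tuple(
            t for t in self.gene_to_terms.get(gene, ()) if t not in self.excluded_terms
        )
        if dedupe:
            terms = tuple(dict.fromkeys(terms))
        return terms


def parse_term_paths(
    rows: Iterable[tuple[str, str]],
    path_sep: str = ">",
    multi_sep: str = ";",
    excluded_terms: Iterable[str] = DEFAULT_EXCLUDED_TERMS,
) -> GeneSetAnnotation:
    """Build an annotation from (gene, term-path string) rows.

    Every hierarchy level of every path becomes one term occurrence for the
    gene; empty terms after whitespace trimming are skipped with a warning.
    """
    gene_to_terms: dict[str, tuple[str, ...]] = {}
    for gene, paths in rows:
        gene = str(gene).strip()
        terms: list[str] = list(gene_to_terms.get(gene, ()))
        for path in str(paths).split(multi_sep):
            for level in path.split(path_sep):
                term = level.strip()
                if not term:
                    logger.warning("empty term for gene %r; skipped", gene)
                    continue
                terms.append(term)
        gene_to_terms[gene] = tuple(terms)
    return GeneSetAnnotation(
        gene_to_terms=gene_to_terms,
        excluded_terms=frozenset(excluded_terms),
    )


def read_annotation_table(
    path,
    delimiter: str = "\t",
    gene_column: str = "gene",
    pathways_column: str = "pathways",
    **kwargs,
) -> GeneSetAnnotation:
    """Read a two-column (gene, pathways) annotation TSV."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in (gene_column, pathways_column):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return parse_term_paths(
        zip(df[gene_column], df[pathways_column].fillna("")), **kwargs
    )


def term_frequency(
    cluster: Iterable[str],
    annotation: GeneSetAnnotation,
    dedupe_per_gene: bool = False,
) -> Counter:
    """Occurrence counts of each (non-excluded) term across cluster genes."""
    counts: Counter = Counter()
    for gene in cluster:
        if gene not in annotation.gene_to_terms:
            logger.info("cluster gene %r has no annotation; counted as zero terms", gene)
            continue
        counts.update(annotation.terms_for(gene, dedupe=dedupe_per_gene))
    return counts


def universe_term_counts(
    annotation: GeneSetAnnotation, dedupe_per_gene: bool = False
) -> Counter:
    """Baseline occurrence counts of every term across the full annotation."""
    return term_frequency(annotation.gene_to_terms, annotation, dedupe_per_gene)


def term_ratio(
    cluster: Iterable[str],
    annotation: GeneSetAnnotation,
    dedupe_per_gene: bool = False,
    universe_counts: Counter | None = None,
) -> dict[str, float]:
    """Per term: cluster occurrence count / universe occurrence count."""
    freq = term_frequency(cluster, annotation, dedupe_per_gene)
    if universe_counts is None:
        universe_counts = universe_term_counts(annotation, dedupe_per_gene)
    out: dict[str, float] = {}
    for term, c in freq.items():
        u = universe_counts.get(term, 0)
        if u == 0:
            raise ValidationError(
                f"term {term!r} occurs in the cluster but not in the universe"
            )
        out[term] = c / u
    return out


def top_terms(
    frequencies: Mapping[str, int],
    ratios: Mapping[str, float],
    k: int = 5,
    metric: str = "frequency",
) -> list[str]:
    """Top-k terms by one metric, ties broken by the other, then alphabetically."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if metric == "frequency":
        key = lambda t: (-frequencies[t], -ratios.get(t, 0.0), t)
    elif metric == "ratio":
        key = lambda t: (-ratios[t], -frequencies.get(t, 0), t)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    pool = frequencies if metric == "frequency" else ratios
    return sorted(pool, key=key)[:k]


@dataclass(frozen=True)
class TermEnrichment:
    """Descriptive term statistics for one gene cluster."""

    cluster_id: str
    table: pd.DataFrame  # term, cluster_count, universe_count, ratio
    top_by_frequency: tuple[str, ...]
    top_by_ratio: tuple[str, ...]
    excluded: frozenset[str]


def enrich_cluster(
    cluster_id: str,
    cluster_genes: Sequence[str],
    annotation: GeneSetAnnotation,
    k: int = 5,
    dedupe_per_gene: bool = False,
) -> TermEnrichment:
    """Full frequency/ratio table and top-k rankings for one cluster."""
    universe = universe_term_counts(annotation, dedupe_per_gene)
    freq = term_frequency(cluster_genes, annotation, dedupe_per_gene)
    ratios = term_ratio(
        cluster_genes, annotation, dedupe_per_gene, universe_counts=universe
    )
    table = pd.DataFrame(
        [
            {
                "term": t,
                "cluster_count": freq[t],
                "universe_count": universe[t],
                "ratio": ratios[t],
            }
            for t in sorted(freq)
        ],
        columns=["term", "cluster_count", "universe_count", "ratio"],
    )
    return TermEnrichment(
        cluster_id=str(cluster_id),
        table=table,
        top_by_frequency=tuple(top_terms(freq, ratios, k, "frequency")),
        top_by_ratio=tuple(top_terms(freq, ratios, k, "ratio")),
        excluded=frozenset(annotation.excluded_terms),
    )
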