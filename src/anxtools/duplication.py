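"""Tandem / segmental duplication classification and chromosome summaries.

Family members on one chromosome separated by at most ``max_intervening``
non-family genes form tandem clusters (connected components, so chains are
allowed). Segmental duplicates are the family-internal rows of a collinear
gene-pair table. Summary percentages follow the additive convention in which
the combined percentage is the sum of the (rounded) tandem and segmental
percentages — classes may overlap, so the sum can exceed the distinct-gene
union percentage, which is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import CollinearPairTable, FormatError, GenomeOrderTable

DEFAULT_MAX_INTERVENING = 5


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int
    end: int


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    members: tuple[str, ...]  # ordered along the chromosome
    max_intervening_observed: int


@dataclass(frozen=True)
class SegmentalPair:
    gene_id_a: str
    gene_id_b: str
    block_id: str


@dataclass
class DuplicationSummary:
    family_size: int
    tandem_genes: int
    segmental_genes: int
    tandem_pct: float
    segmental_pct: float
    combined_pct: float
    union_pct: float  # distinct genes in either class, for honesty
    per_chromosome: dict[str, int] = field(default_factory=dict)


def round_percent(value: float, mode: str = "half_up") -> float:
    """Round a percentage: 'half_up' to integer, 'none' leaves it untouched."""
    if mode == "none":
        return value
    if mode == "half_up":
        return float(math.floor(value + 0.5))
    raise ValueError(f"unknown rounding mode {mode!r}")


def detect_tandem(family_loci: Sequence[GeneLocus],
                  genome_order: GenomeOrderTable,
                  max_intervening: int = DEFAULT_MAX_INTERVENING
                  ) -> list[TandemCluster]:
    """Tandem clusters of family genes.

    Two family genes are linked when they share a chromosome and at most
    ``max_intervening`` non-family genes sit between them in gene order;
    clusters are the connected components of that relation (computed by
    chaining consecutive family genes, which is equivalent).
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    family_ids = {l.gene_id for l in family_loci}
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for locus in family_loci:
        try:
            idx = genome_order.order_index(locus.chromosome, locus.gene_id)
        except KeyError as exc:
            raise FormatError(str(exc)) from exc
        by_chrom.setdefault(locus.chromosome, []).append((idx, locus.gene_id))

    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom])
        current: list[tuple[int, str]] = [ordered[0]]
        gaps: list[int] = []
        for prev, nxt in zip(ordered, ordered[1:]):
            # non-family genes between two consecutive family members
            between = [
                gid for gid, _ in
                genome_order.by_chromosome[chrom][prev[0] + 1:nxt[0]]
                if gid not in family_ids
            ]
            if len(between) <= max_intervening:
                current.append(nxt)
                gaps.append(len(between))
            else:
                if len(current) >= 2:
                    clusters.append(TandemCluster(
                        chrom, tuple(g for _, g in current), max(gaps)))
                current, gaps = [nxt], []
        if len(current) >= 2:
            clusters.append(TandemCluster(
                chrom, tuple(g for _, g in current), max(gaps)))
    return clusters


def annotate_segmental(family_ids: Iterable[str],
                       pair_table: CollinearPairTable) -> list[SegmentalPair]:
    """Collinear pairs whose two members are both family genes.

    A gene may appear in several pairs (one-to-many blocks are kept).
    """
    family = set(family_ids)
    return [
        SegmentalPair(a, b, block)
        for a, b, block in pair_table.pairs
        if a in family and b in family
    ]


def chromosome_distribution(family_loci: Sequence[GeneLocus]
                            ) -> tuple[dict[str, int], list[str]]:
    """Per-chromosome gene counts and the chromosome(s) holding the most."""
    counts: dict[str, int] = {}
    for locus in family_loci:
        counts[locus.chromosome] = counts.get(locus.chromosome, 0) + 1
    if not counts:
        return {}, []
    top = max(counts.values())
    return counts, sorted(c for c, n in counts.items() if n == top)


def summarize_duplication(family_loci: Sequence[GeneLocus],
                          clusters: Sequence[TandemCluster],
                          pairs: Sequence[SegmentalPair],
                          rounding_mode: str = "half_up") -> DuplicationSummary:
    """Family-level duplication percentages.

    tandem% and segmental% are each 100 × (distinct genes in that class) /
    family size, rounded per ``rounding_mode``; combined% is their sum.
    """
    n = len(family_loci)
    if n == 0:
        raise FormatError("empty gene family")
    tandem_genes = {g for c in clusters for g in c.members}
    segmental_genes = {g for p in pairs for g in (p.gene_id_a, p.gene_id_b)}
    tandem_pct = round_percent(100.0 * len(tandem_genes) / n, rounding_mode)
    segmental_pct = round_percent(100.0 * len(segmental_genes) / n, rounding_mode)
    union_pct = round_percent(
        100.0 * len(tandem_genes | segmental_genes) / n, rounding_mode)
    counts, _ = chromosome_distribution(family_loci)
    return DuplicationSummary(
        family_size=n,
        tandem_genes=len(tandem_genes),
        segmental_genes=len(segmental_genes),
        tandem_pct=tandem_pct,
        segmental_pct=segmental_pct,
        combined_pct=tandem_pct + segmental_pct,
        union_pct=union_pct,
        per_chromosome=counts,
    )
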