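"""Region-to-gene mapping and cross-comparison set algebra.

Candidate regions from each pairwise comparison are intersected with the
gene annotation (interval overlap, >=1 bp by default); the per-comparison
gene lists are then combined: the deduplicated union is the overall
candidate set, and the genes present in *every* comparison involving the
focal population are its breed-unique candidates (the Venn intersection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import GeneModel, Region, SweepscanError


@dataclass
class ComparisonResult:
    """Candidate regions and mapped genes for one pairwise comparison."""

    label: str
    regions: list[Region]
    genes: list[str] = field(default_factory=list)


def overlap_genes(regions: Sequence[Region], genes: Sequence[GeneModel],
                  min_overlap: int = 1) -> list[str]:
    """Gene ids sharing >= ``min_overlap`` bp with any region.

    Coordinates are 1-based inclusive on both sides.  Each gene is reported
    at most once, in annotation order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        # interval tree is half-open; [start, end] inclusive -> [start, end+1)
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1)
    hits: list[str] = []
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            continue
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(g.start, g.end + 1):
            ov = min(g.end, iv.end - 1) - max(g.start, iv.begin) + 1
            if ov >= min_overlap:
                hits.append(g.gene_id)
                seen.add(g.gene_id)
                break
    return hits


def _gene_list(obj) -> list[str]:
    return list(obj.genes) if isinstance(obj, ComparisonResult) else list(obj)


def dedup_union(results: Sequence[ComparisonResult | Iterable[str]]) -> list[str]:
    """Set union of comparison gene lists, preserving first-seen order."""
    if not results:
        raise SweepscanError("need >=1 comparison")
    out: list[str] = []
    seen: set[str] = set()
    for res in results:
        for g in _gene_list(res):
            if g not in seen:
                out.append(g)
                seen.add(g)
    return out


def shared_genes(results: Sequence[ComparisonResult | Iterable[str]]) -> list[str]:
    """Genes present in every comparison's gene set (Venn intersection).

    These are the candidates selected against *all* reference populations —
    the reading of 'unique to the focal breed'.  Order follows the first
    comparison.
    """
    if len(results) < 2:
        raise SweepscanError("shared_genes needs >=2 comparisons")
    sets = [set(_gene_list(r)) for r in results[1:]]
    out: list[str] = []
    for g in _gene_list(results[0]):
        if all(g in s for s in sets) and g not in out:
            out.append(g)
    return out
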