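"""Term over-representation with an FDR of the form P*n/rank(P).

The test is the one-sided hypergeometric (Fisher upper tail): with N
background genes of which K carry a term, and a candidate set of n_cand
genes of which k carry it, p = P[X >= k] for X ~ Hypergeom(N, K, n_cand).

The multiple-testing correction is FDR_i = p_i * n_tests / rank_i with
ascending 1-based ranks — the Benjamini–Hochberg quantity *without* the
step-up cumulative-minimum pass.  That literal form is the default;
``mode="monotone"`` additionally applies the step-up pass, which makes it
the standard BH adjusted p-value.  Significance is FDR <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import SweepscanError

SIGNIFICANCE_FDR = 0.05


@dataclass
class EnrichmentResult:
    term: str
    k: int          # candidate genes carrying the term
    K: int          # background genes carrying the term
    n_cand: int
    N: int
    p: float
    rank: int = 0
    n_tests: int = 0
    fdr: float = float("nan")
    significant: bool = False


def hypergeom_enrich(candidates: Iterable[str],
                     term_map: Mapping[str, Iterable[str]],
                     background: Iterable[str],
                     include_empty: bool = True) -> list[EnrichmentResult]:
    """Per-term upper-tail hypergeometric p-values (no correction yet).

    Term genes outside the background are ignored.  Terms with k = 0 are
    reported with p = 1 unless ``include_empty`` is false.
    """
    cand = list(dict.fromkeys(candidates))
    bg = set(background)
    stray = [g for g in cand if g not in bg]
    if stray:
        raise SweepscanError(
            "candidate genes absent from background: " + ", ".join(sorted(stray)))
    N, n_cand = len(bg), len(cand)
    cand_set = set(cand)
    results: list[EnrichmentResult] = []
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & bg
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & cand_set)
        if k == 0 and not include_empty:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n_cand))
        results.append(EnrichmentResult(term, k, K, n_cand, N, min(p, 1.0)))
    return results


def fdr_correct(pvalues, mode: str = "literal",
                ties: str = "ordinal") -> tuple[np.ndarray, np.ndarray]:
    """FDR = p * n / rank, in the input order.

    Returns ``(fdr, rank)``.  Ranks are ascending and 1-based; ties are
    broken by input position (``ties="ordinal"``, deterministic) or all tied
    p-values receive the maximum rank of their group (``ties="max"``, as in
    common BH implementations).  Values are capped at 1.  ``mode="monotone"``
    additionally enforces the step-up cumulative minimum from the largest p.
    """
    if mode not in ("literal", "monotone"):
        raise ValueError("mode must be 'literal' or 'monotone'")
    if ties not in ("ordinal", "max"):
        raise ValueError("ties must be 'ordinal' or 'max'")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)
    if ties == "max":
        for val in np.unique(p):
            mask = p == val
            rank[mask] = rank[mask].max()
    fdr = p * n / rank
    if mode == "monotone":
        sorted_fdr = fdr[order]
        fdr[order] = np.minimum.accumulate(sorted_fdr[::-1])[::-1]
    return np.minimum(fdr, 1.0), rank


def enrich(candidates: Iterable[str],
           term_map: Mapping[str, Iterable[str]],
           background: Iterable[str] | None = None,
           mode: str = "literal",
           alpha: float = SIGNIFICANCE_FDR) -> list[EnrichmentResult]:
    """Full over-representation analysis, sorted by (p, term).

    ``background`` defaults to the union of all term-map genes.  The
    pre-sort by (p-value, term id) makes ordinal tie ranks lexicographic and
    the output deterministic.
    """
    if background is None:
        background = set().union(*(set(v) for v in term_map.values()))
    results = hypergeom_enrich(candidates, term_map, background)
    results.sort(key=lambda r: (r.p, r.term))
    fdr, rank = fdr_correct([r.p for r in results], mode=mode)
    for r, f, rk in zip(results, fdr, rank):
        r.fdr = float(f)
        r.rank = int(rk)
        r.n_tests = len(results)
        r.significant = bool(f <= alpha)
    results.sort(key=lambda r: (r.fdr, r.p, r.term))
    return results


def to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n_cand": [r.n_cand for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "rank": [r.rank for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
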