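"""Per-SNP allele frequencies, expected heterozygosity and FST.

The default FST is the Wright/Nei-style ratio

    FST = (HT - HS) / HT

with HT the expected heterozygosity of the pooled population (pooled allele
frequency is the allele-count-weighted mean of subpopulation frequencies)
and HS the allele-count-weighted mean of within-population expected
heterozygosities.  FST is undefined (NaN) at globally monomorphic sites
(HT = 0).  A Weir & Cockerham (1984) theta is available as ``mode="wc"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, SweepscanError


@dataclass
class PerSnpStats:
    """Per-variant statistics for a set of populations.

    Arrays of shape (n_variants,) or (n_variants, n_pops); ``freq`` and
    ``he`` are NaN where a population has no called alleles, and ``fst`` is
    NaN where undefined (monomorphic overall, or fewer than two populations
    with data).
    """

    chrom: np.ndarray
    pos: np.ndarray
    pops: list[str]
    freq: np.ndarray      # (V, P) alt-allele frequency
    n: np.ndarray         # (V, P) non-missing allele count (2 * called samples)
    he: np.ndarray        # (V, P) within-population expected heterozygosity
    hs: np.ndarray        # (V,) weighted mean subpopulation He
    ht: np.ndarray        # (V,) pooled-population He
    fst: np.ndarray       # (V,) NaN where undefined
    usable: np.ndarray    # (V,) bool: every population has >=1 called allele

    def to_frame(self) -> pd.DataFrame:
        cols = {"chrom": self.chrom, "pos": self.pos}
        for j, p in enumerate(self.pops):
            cols[f"freq_{p}"] = self.freq[:, j]
            cols[f"n_{p}"] = self.n[:, j]
            cols[f"he_{p}"] = self.he[:, j]
        cols["hs"] = self.hs
        cols["ht"] = self.ht
        cols["fst"] = self.fst
        return pd.DataFrame(cols)

    def he_of(self, pop: str) -> np.ndarray:
        try:
            j = self.pops.index(pop)
        except ValueError:
            raise SweepscanError(f"unknown population label: {pop!r}") from None
        return self.he[:, j]


def expected_het(freq):
    """He = 1 - sum(p_i^2) = 2p(1-p) for a biallelic site."""
    freq = np.asarray(freq, dtype=float)
    return 2.0 * freq * (1.0 - freq)


def allele_freqs(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequency and non-missing allele count per SNP per pop.

    Returns ``(freq, n)`` of shape (n_variants, n_pops), population order as
    in ``matrix.pop_labels``.  freq is NaN where n == 0.
    """
    pops = matrix.pop_labels
    V = matrix.n_variants
    freq = np.full((V, len(pops)), np.nan)
    n = np.zeros((V, len(pops)), dtype=np.int64)
    for j, p in enumerate(pops):
        d = matrix.dosage[:, matrix.sample_indices(p)].astype(float)
        called = d != MISSING
        n[:, j] = 2 * called.sum(axis=1)
        alt = np.where(called, d, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, j] = np.where(n[:, j] > 0, alt / n[:, j], np.nan)
    return freq, n


def fst_per_snp(freq: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HS, HT and FST = (HT-HS)/HT from per-population (freq, n).

    Weights are non-missing allele counts.  Populations with n = 0 at a SNP
    drop out of the weighted means; FST is NaN when fewer than two
    populations have data or when HT = 0.
    """
    freq = np.atleast_2d(np.asarray(freq, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    has = n > 0
    w = np.where(has, n, 0.0)
    wtot = w.sum(axis=1)
    f0 = np.where(has, freq, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (w * f0).sum(axis=1) / wtot
        ht = expected_het(pbar)
        hs = (w * expected_het(f0)).sum(axis=1) / wtot
        fst = (ht - hs) / ht
    bad = (has.sum(axis=1) < 2) | (ht <= 0) | ~np.isfinite(ht)
    fst = np.where(bad, np.nan, fst)
    return hs, ht, fst


def wc_theta_per_snp(freq: np.ndarray, n: np.ndarray,
                     het_obs: np.ndarray) -> np.ndarray:
    """Weir & Cockerham (1984) single-SNP theta for r populations.

    ``het_obs`` is the observed heterozygote frequency per population.
    Returns NaN where the denominator a+b+c is zero or <2 pops have data.
    """
    freq = np.atleast_2d(np.asarray(freq, dtype=float))
    nall = np.atleast_2d(np.asarray(n, dtype=float))
    hobs = np.atleast_2d(np.asarray(het_obs, dtype=float))
    ni = nall / 2.0  # individuals
    has = ni > 0
    r = has.sum(axis=1).astype(float)
    ni0 = np.where(has, ni, 0.0)
    p0 = np.where(has, freq, 0.0)
    h0 = np.where(has, hobs, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = ni0.sum(axis=1) / r
        nc = (r * nbar - (ni0 ** 2).sum(axis=1) / (r * nbar)) / (r - 1.0)
        pbar = (ni0 * p0).sum(axis=1) / (r * nbar)
        s2 = (ni0 * (p0 - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1.0) * nbar)
        hbar = (ni0 * h0).sum(axis=1) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (pbar * (1 - pbar)
                                   - (r - 1.0) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        theta = a / (a + b + c)
    theta = np.where((r < 2) | ~np.isfinite(theta), np.nan, theta)
    return theta


def per_snp_stats(matrix: GenotypeMatrix, mode: str = "nei") -> PerSnpStats:
    """Compute the full per-SNP statistics table for a genotype matrix.

    ``mode="nei"`` (default) uses FST = (HT-HS)/HT; ``mode="wc"`` replaces
    the fst column with the Weir & Cockerham theta (HS/HT still reported).
    """
    if mode not in ("nei", "wc"):
        raise ValueError("mode must be 'nei' or 'wc'")
    pops = matrix.pop_labels
    if len(pops) < 2:
        raise SweepscanError("FST requires >=2 populations")
    freq, n = allele_freqs(matrix)
    he = expected_het(freq)
    hs, ht, fst = fst_per_snp(freq, n)
    if mode == "wc":
        het_obs = np.full_like(freq, np.nan)
        for j, p in enumerate(pops):
            d = matrix.dosage[:, matrix.sample_indices(p)]
            called = d != MISSING
            cnt = called.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                het_obs[:, j] = np.where(cnt > 0, (d == 1).sum(axis=1) / cnt, np.nan)
        fst = wc_theta_per_snp(freq, n, het_obs)
    usable = (n > 0).all(axis=1)
    return PerSnpStats(
        chrom=matrix.chrom, pos=matrix.pos, pops=pops,
        freq=freq, n=n, he=he, hs=hs, ht=ht, fst=fst, usable=usable,
    )
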