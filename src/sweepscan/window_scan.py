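"""Sliding-window aggregation, top-5% dual thresholds and region merging.

The genome is tiled with overlapping windows (100 kb advanced by 50 kb by
default).  Each eligible window (>= ``min_snps`` SNPs) carries an aggregated
FST and the mean focal-population expected heterozygosity of its SNPs.  A
window is a candidate when its FST lies strictly above the genome-wide upper
5% quantile AND its heterozygosity lies strictly below the lower 5%
quantile; overlapping or book-ended candidate windows merge into regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, Region, SweepscanError
from .popgen_stats import PerSnpStats, per_snp_stats


@dataclass
class Window:
    """A genomic window, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    n_snps: int = 0
    fst_win: float = float("nan")
    h_win: float = float("nan")
    pass_fst: bool = False
    pass_h: bool = False
    selected: bool = False

    @property
    def eligible(self) -> bool:
        """Window carries statistics (enough SNPs, FST defined)."""
        return np.isfinite(self.fst_win) and np.isfinite(self.h_win)


def make_windows(chrom_lengths: Mapping[str, int],
                 size: int = 100_000, step: int = 50_000) -> list[Window]:
    """Tile chromosomes with windows starting at 1, 1+step, 1+2*step, ...

    The final window on a chromosome is the first one that runs past the
    chromosome end; it is truncated there (a chromosome shorter than one
    window yields a single truncated window).
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        start = 1
        while start <= length:
            windows.append(Window(chrom, start, min(start + size - 1, length)))
            if start + size - 1 > length:
                break
            start += step
    return windows


def aggregate_windows(per_snp: PerSnpStats, windows: Sequence[Window],
                      focal_pop: str, fst_mode: str = "ratio",
                      min_snps: int = 10) -> list[Window]:
    """Fill n_snps, fst_win and h_win for each window.

    h_win is the arithmetic mean of the focal population's per-SNP He over
    every SNP in the window.  fst_win is sum(HT-HS)/sum(HT) over SNPs where
    FST is defined (``fst_mode="ratio"``, default) or the mean per-SNP FST
    (``fst_mode="mean"``).  Windows with fewer than ``min_snps`` SNPs carry
    no statistics.
    """
    if fst_mode not in ("ratio", "mean"):
        raise ValueError("fst_mode must be 'ratio' or 'mean'")
    he_focal = per_snp.he_of(focal_pop)  # raises on unknown label
    chrom_arr = per_snp.chrom.astype(str)
    pos = per_snp.pos
    by_chrom: dict[str, np.ndarray] = {
        c: np.flatnonzero(chrom_arr == c) for c in dict.fromkeys(chrom_arr.tolist())
    }
    for w in windows:
        idx = by_chrom.get(w.chrom)
        if idx is None:
            w.n_snps = 0
            w.fst_win = w.h_win = float("nan")
            continue
        p = pos[idx]
        lo, hi = np.searchsorted(p, [w.start, w.end + 1])
        sel = idx[lo:hi]
        w.n_snps = int(sel.size)
        if w.n_snps < min_snps:
            w.fst_win = w.h_win = float("nan")
            continue
        w.h_win = float(np.nanmean(he_focal[sel]))
        defined = sel[np.isfinite(per_snp.fst[sel])]
        if defined.size == 0:
            w.fst_win = float("nan")
        elif fst_mode == "mean":
            w.fst_win = float(np.mean(per_snp.fst[defined]))
        else:
            num = float(np.sum(per_snp.ht[defined] - per_snp.hs[defined]))
            den = float(np.sum(per_snp.ht[defined]))
            w.fst_win = num / den if den > 0 else float("nan")
    return list(windows)


def quantile_threshold(values, tail: str, fraction: float = 0.05) -> float:
    """Upper (95th) or lower (5th) percentile with linear interpolation.

    Selection downstream uses strict inequality (FST > threshold,
    H < threshold), so ties at the threshold are excluded.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise SweepscanError("no finite values to threshold")
    if vals.size < 20:
        warnings.warn(
            f"only {vals.size} finite values; a {fraction:.0%} tail threshold "
            "is poorly determined"
        )
    q = 100 * (1 - fraction) if tail == "upper" else 100 * fraction
    return float(np.percentile(vals, q, method="linear"))


def select_and_merge(windows: Sequence[Window], fst_thr: float,
                     h_thr: float) -> list[Region]:
    """Flag candidate windows (FST > fst_thr AND H < h_thr) and merge them.

    Overlapping or book-ended (end+1 == start) candidate windows on the same
    chromosome merge into one Region carrying the member count, max fst_win
    and min h_win.
    """
    if not (np.isfinite(fst_thr) and np.isfinite(h_thr)):
        raise ValueError("thresholds must be finite")
    for w in windows:
        w.pass_fst = bool(w.eligible and w.fst_win > fst_thr)
        w.pass_h = bool(w.eligible and w.h_win < h_thr)
        w.selected = w.pass_fst and w.pass_h
    chosen = sorted((w for w in windows if w.selected),
                    key=lambda w: (w.chrom, w.start, w.end))
    regions: list[Region] = []
    cur: list[Window] = []
    for w in chosen:
        if cur and w.chrom == cur[-1].chrom and w.start <= max(x.end for x in cur) + 1:
            cur.append(w)
        else:
            if cur:
                regions.append(_to_region(cur))
            cur = [w]
    if cur:
        regions.append(_to_region(cur))
    return regions


def _to_region(members: list[Window]) -> Region:
    return Region(
        chrom=members[0].chrom,
        start=min(w.start for w in members),
        end=max(w.end for w in members),
        n_windows=len(members),
        max_fst=max(w.fst_win for w in members),
        min_h=min(w.h_win for w in members),
    )


def merge_regions(regions: Sequence[Region]) -> list[Region]:
    """Merge overlapping/book-ended regions (idempotent on scan output)."""
    out: list[Region] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and r.chrom == out[-1].chrom and r.start <= out[-1].end + 1:
            last = out[-1]
            out[-1] = Region(last.chrom, last.start, max(last.end, r.end),
                             last.n_windows + r.n_windows,
                             max(last.max_fst, r.max_fst),
                             min(last.min_h, r.min_h))
        else:
            out.append(r)
    return out


@dataclass
class ScanResult:
    """Windows, thresholds and merged candidate regions for one comparison."""

    windows: list[Window]
    fst_threshold: float
    h_threshold: float
    regions: list[Region]
    focal_pop: str
    pops: list[str] = field(default_factory=list)

    @property
    def eligible_windows(self) -> list[Window]:
        return [w for w in self.windows if w.eligible]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "n_snps": [w.n_snps for w in self.windows],
                "fst": [w.fst_win for w in self.windows],
                "h": [w.h_win for w in self.windows],
                "pass_fst": [w.pass_fst for w in self.windows],
                "pass_h": [w.pass_h for w in self.windows],
                "selected": [w.selected for w in self.windows],
            }
        )


def scan(matrix: GenotypeMatrix, pop_a: str, pop_b: str, focal_pop: str,
         window_size: int = 100_000, step: int = 50_000,
         top_fraction: float = 0.05, fst_mode: str = "ratio",
         min_snps: int = 10, chrom_lengths: Mapping[str, int] | None = None,
         snp_mode: str = "nei") -> ScanResult:
    """Run the full two-population scan for one comparison.

    The matrix is restricted to ``pop_a`` and ``pop_b``; per-SNP FST/He are
    computed, aggregated into sliding windows, and dual top-``top_fraction``
    thresholds (upper tail of FST, lower tail of focal-population H) select
    candidate windows whose union of overlaps forms the candidate regions.
    """
    if focal_pop not in (pop_a, pop_b):
        raise SweepscanError(f"focal population {focal_pop!r} must be one of "
                             f"{pop_a!r}, {pop_b!r}")
    sub = matrix.subset_pops([pop_a, pop_b])
    stats = per_snp_stats(sub, mode=snp_mode)
    if chrom_lengths is None:
        chrom_lengths = sub.chrom_extents()
    windows = make_windows(chrom_lengths, window_size, step)
    aggregate_windows(stats, windows, focal_pop, fst_mode, min_snps)
    eligible = [w for w in windows if w.eligible]
    fst_thr = quantile_threshold([w.fst_win for w in eligible], "upper", top_fraction)
    h_thr = quantile_threshold([w.h_win for w in eligible], "lower", top_fraction)
    regions = select_and_merge(windows, fst_thr, h_thr)
    return ScanResult(windows=list(windows), fst_threshold=fst_thr,
                      h_threshold=h_thr, regions=regions,
                      focal_pop=focal_pop, pops=[pop_a, pop_b])
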