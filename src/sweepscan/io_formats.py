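"""Readers and writers for the formats the scan touches.

Internal coordinates are 1-based inclusive everywhere (the VCF convention);
BED's 0-based half-open convention is converted exactly once, at the file
boundary.  Genotypes live in a :class:`GenotypeMatrix` as alt-allele dosage
(0/1/2, ``-1`` for missing) with variants on rows and samples on columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1


class SweepscanError(Exception):
    """User-facing error (bad input, inconsistent files)."""


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes for samples x variants.

    Attributes
    ----------
    chrom, pos : per-variant chromosome name and 1-based position,
        sorted by (chrom, pos) with no duplicates.
    dosage : int8 array of shape (n_variants, n_samples); alt-allele count
        in {0, 1, 2} or -1 for a missing call.
    samples : ordered sample identifiers.
    pops : population label per sample, aligned with ``samples``.
    ref, alt : optional per-variant alleles (defaulted for simulated data).
    """

    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    pops: list[str]
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage shape must be (n_variants, n_samples)")
        if len(self.pops) != len(self.samples):
            raise ValueError("one population label per sample required")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.dosage = self.dosage[order]
            if self.ref is not None:
                self.ref = np.asarray(self.ref, dtype=object)[order]
            if self.alt is not None:
                self.alt = np.asarray(self.alt, dtype=object)[order]
        key = np.char.add(np.char.add(self.chrom.astype(str), ":"),
                          self.pos.astype(str))
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate (chrom, pos) pairs in genotype matrix")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def pop_labels(self) -> list[str]:
        """Distinct population labels in first-seen order."""
        return list(dict.fromkeys(self.pops))

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.pops, dtype=object) == pop)
        if idx.size == 0:
            raise SweepscanError(f"unknown population label: {pop!r}")
        return idx

    def subset_pops(self, pops: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the samples of the given populations."""
        cols = np.concatenate([self.sample_indices(p) for p in pops])
        return GenotypeMatrix(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            dosage=self.dosage[:, cols],
            samples=[self.samples[i] for i in cols],
            pops=[self.pops[i] for i in cols],
            ref=None if self.ref is None else self.ref.copy(),
            alt=None if self.alt is None else self.alt.copy(),
        )

    def chrom_extents(self) -> dict[str, int]:
        """Max observed position per chromosome (a lower bound on length)."""
        out: dict[str, int] = {}
        for c in dict.fromkeys(self.chrom.tolist()):
            out[c] = int(self.pos[self.chrom == c].max())
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    source_line: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class Region:
    """A candidate interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    n_windows: int = 0
    max_fst: float = float("nan")
    min_h: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# population / term maps

def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>population table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise SweepscanError(f"population map {path} needs 2 columns")
    return dict(zip(df[0], df[1]))


def write_pop_map(pop_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_map.items():
            fh.write(f"{sample}\t{pop}\n")


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column term<TAB>gene table into term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise SweepscanError(f"term map {path} needs 2 columns")
    out: dict[str, set[str]] = {}
    for term, gene in zip(df[0], df[1]):
        out.setdefault(term, set()).add(gene)
    return out


def write_term_map(term_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{term}\t{gene}\n")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(
    path: str | Path,
    pop_map: Mapping[str, str],
    multiallelic: str = "drop",
) -> GenotypeMatrix:
    """Read a VCF into a biallelic :class:`GenotypeMatrix`.

    Records failing FILTER (anything other than PASS or '.') are dropped, as
    are indels.  Multi-allelic records are dropped by default or decomposed
    into one pseudo-biallelic variant per alternate allele with
    ``multiallelic="split"`` (split twins at the same position keep only the
    first allele, preserving the unique-(chrom,pos) invariant).

    Raises
    ------
    SweepscanError
        If a VCF sample is absent from ``pop_map`` or the VCF has no GT.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "split"):
        raise ValueError("multiallelic must be 'drop' or 'split'")
    vcf = VCF(str(path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise SweepscanError(f"{path}: no GT field in FORMAT")
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pop_map]
    if missing_samples:
        raise SweepscanError(
            "samples absent from population map: " + ", ".join(missing_samples)
        )
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    for v in vcf:
        if v.FILTER is not None:  # None <=> PASS or '.'
            continue
        if not v.ALT:
            continue
        if len(v.ALT) > 1:
            if multiallelic == "drop":
                continue
            alt_alleles = v.ALT
        else:
            alt_alleles = v.ALT
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        for ai, alt in enumerate(alt_alleles, start=1):
            if len(v.REF) != 1 or len(alt) != 1:
                continue  # indel
            key = (v.CHROM, v.POS)
            if key in seen:
                continue
            dos = (gts == ai).sum(axis=1).astype(np.int8)
            dos[(gts < 0).any(axis=1)] = MISSING
            seen.add(key)
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(alt)
            rows.append(dos)
            if len(alt_alleles) > 1:
                break  # one record per position
    dosage = (np.vstack(rows) if rows
              else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosage=dosage,
        samples=samples,
        pops=[pop_map[s] for s in samples],
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              chrom_lengths: Mapping[str, int] | None = None) -> None:
    """Write the matrix as minimal VCF 4.2 (GT only)."""
    if chrom_lengths is None:
        chrom_lengths = matrix.chrom_extents()
    ref = matrix.ref if matrix.ref is not None else np.full(matrix.n_variants, "A", dtype=object)
    alt = matrix.alt if matrix.alt is not None else np.full(matrix.n_variants, "G", dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_variants):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.dosage[i])
            fh.write(f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{ref[i]}\t{alt[i]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# gene annotation

def read_genes(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read a gene annotation from BED4 or GFF3 into 1-based GeneModels.

    BED intervals (0-based half-open) are shifted to 1-based inclusive; GFF3
    rows are kept only if their feature type is ``gene``.  Lines that are
    invalid after normalization (start > end) are skipped with a warning.
    """
    import pyranges as pr

    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if format == "bed":
        df = pr.read_bed(str(path)).df
        if "Name" not in df.columns:
            raise SweepscanError(f"{path}: BED gene annotation needs a name column")
    elif format == "gff3":
        df = pr.read_gff3(str(path)).df
        df = df[df["Feature"] == "gene"]
        name_col = "ID" if "ID" in df.columns else "Name"
        df = df.rename(columns={name_col: "Name"})
    else:
        raise ValueError("format must be 'bed' or 'gff3'")
    genes: list[GeneModel] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        start = int(row.Start) + 1  # pyranges stores 0-based starts
        end = int(row.End)
        if start > end or not str(row.Name):
            n_bad += 1
            continue
        genes.append(GeneModel(str(row.Name), str(row.Chromosome), start, end))
    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} invalid gene line(s)")
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))
    with open(path, "w") as fh:
        for g in rows:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# BED regions

def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    """Write 1-based inclusive regions as (0-based half-open) BED3."""
    rows = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


def read_bed_regions(path: str | Path) -> list[Region]:
    """Read BED3+ intervals back into 1-based inclusive Regions."""
    out: list[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(Region(parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


def write_newick(tree, path: str | Path) -> None:
    """Serialize an skbio TreeNode with branch lengths."""
    tree.write(str(path), format="newick")
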