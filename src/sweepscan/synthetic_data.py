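"""Multi-population genotype simulator with planted selective sweeps.

Allele frequencies follow the Balding–Nichols construction: an ancestral
frequency p ~ Uniform(0.05, 0.95) per SNP, and each population draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so F controls the expected
differentiation (E[FST] ~ F).  Inside a planted sweep the focal population
uses a larger divergence parameter ``sweep_F`` and its frequency is pulled
toward the nearer allele-frequency boundary with weight ``fixation_bias``,
which elevates FST and depresses heterozygosity — the signature the scan is
built to detect.  Genotypes are binomial(2, freq) per diploid sample; no
linkage disequilibrium or demography is modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import GeneModel, GenotypeMatrix, Region, SweepscanError


@dataclass(frozen=True)
class SweepSpec:
    """One planted sweep: interval, focal population and strength."""

    chrom: str
    start: int
    end: int
    focal_pop: str
    sweep_F: float
    fixation_bias: float

    def as_region(self) -> Region:
        return Region(self.chrom, self.start, self.end)


def _default_chroms() -> dict[str, int]:
    return {"chr1": 5_000_000, "chr2": 5_000_000}


def _default_sweeps() -> tuple[SweepSpec, ...]:
    # one 300-kb sweep in the middle of chr1, focal population "pop1"
    return (SweepSpec("chr1", 2_000_001, 2_300_000, "pop1",
                      sweep_F=0.6, fixation_bias=0.7),)


@dataclass(frozen=True)
class SimSpec:
    """Simulation parameters.

    Defaults give the desk-scale study condition: 2 populations of 30
    diploids, 2 chromosomes of 5 Mb, 10,000 SNPs, background divergence
    F = 0.05 and a single 300-kb sweep (sweep_F = 0.6, fixation_bias = 0.7)
    — a dataset that runs through the whole pipeline in seconds.
    """

    n_pops: int = 2
    samples_per_pop: int = 30
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    n_snps: int = 10_000
    background_F: float = 0.05
    sweep_regions: tuple[SweepSpec, ...] = field(default_factory=_default_sweeps)
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("need >=2 populations")
        if not 0 < self.background_F < 1:
            raise ValueError("background_F must be in (0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        for s in self.sweep_regions:
            if s.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {s.chrom}")
            if not (1 <= s.start <= s.end <= self.chrom_lengths[s.chrom]):
                raise ValueError(f"sweep {s} outside chromosome bounds")
            if s.sweep_F <= self.background_F:
                raise ValueError("sweep_F must exceed background_F")
            if s.focal_pop not in self.pop_labels:
                raise ValueError(f"sweep focal_pop {s.focal_pop!r} not among "
                                 f"{self.pop_labels}")
            if not 0 <= s.fixation_bias <= 1:
                raise ValueError("fixation_bias must be in [0,1]")

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]

    @classmethod
    def from_mapping(cls, data: dict) -> "SimSpec":
        """Build a SimSpec from plain dicts (e.g. parsed YAML)."""
        data = dict(data)
        sweeps = data.get("sweep_regions")
        if sweeps is not None:
            data["sweep_regions"] = tuple(
                s if isinstance(s, SweepSpec) else SweepSpec(**s)
                for s in sweeps)
        return cls(**data)

    def with_seed(self, seed: int) -> "SimSpec":
        return replace(self, seed=seed)


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated dataset."""

    regions: list[Region]
    genes_in_sweeps: list[str] = field(default_factory=list)


def _bn_freq(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols draw of a population frequency around ancestral p."""
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def simulate(spec: SimSpec) -> tuple[GenotypeMatrix, TruthSet]:
    """Generate a genotype matrix and its truth set, reproducibly from seed.

    SNP positions are drawn uniformly without replacement per chromosome
    (count proportional to chromosome length) and sorted.  A sweep interval
    that happens to contain no SNP raises a warning naming the region; its
    truth entry is still emitted.
    """
    rng = np.random.default_rng(spec.seed)
    pops = spec.pop_labels
    total_len = sum(spec.chrom_lengths.values())
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    remaining = spec.n_snps
    items = list(spec.chrom_lengths.items())
    for i, (chrom, length) in enumerate(items):
        k = remaining if i == len(items) - 1 else round(
            spec.n_snps * length / total_len)
        k = min(k, remaining, length)
        pos = np.sort(rng.choice(length, size=k, replace=False)) + 1
        chroms.extend([chrom] * k)
        positions.append(pos)
        remaining -= k
    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.concatenate(positions) if positions else np.empty(0, np.int64)
    V = len(pos_arr)

    p_anc = rng.uniform(0.05, 0.95, size=V)
    freqs = np.empty((V, spec.n_pops))
    for j in range(spec.n_pops):
        freqs[:, j] = _bn_freq(rng, p_anc, spec.background_F)

    for s in spec.sweep_regions:
        in_sweep = (chrom_arr == s.chrom) & (pos_arr >= s.start) & (pos_arr <= s.end)
        if not in_sweep.any():
            warnings.warn(f"sweep region {s.chrom}:{s.start}-{s.end} "
                          "contains no simulated SNPs")
            continue
        j = pops.index(s.focal_pop)
        f = _bn_freq(rng, p_anc[in_sweep], s.sweep_F)
        boundary = (f >= 0.5).astype(float)
        freqs[in_sweep, j] = (1 - s.fixation_bias) * f + s.fixation_bias * boundary

    dosage = np.empty((V, spec.n_pops * spec.samples_per_pop), dtype=np.int8)
    labels: list[str] = []
    samples: list[str] = []
    for j, pop in enumerate(pops):
        cols = slice(j * spec.samples_per_pop, (j + 1) * spec.samples_per_pop)
        dosage[:, cols] = rng.binomial(
            2, freqs[:, j][:, None], size=(V, spec.samples_per_pop))
        labels.extend([pop] * spec.samples_per_pop)
        samples.extend(f"{pop}_s{i + 1}" for i in range(spec.samples_per_pop))

    if spec.missing_rate > 0:
        mask = rng.random(dosage.shape) < spec.missing_rate
        dosage[mask] = -1

    matrix = GenotypeMatrix(chrom=chrom_arr, pos=pos_arr, dosage=dosage,
                            samples=samples, pops=labels)
    truth = TruthSet(regions=[s.as_region() for s in spec.sweep_regions])
    return matrix, truth


def make_toy_annotation(spec: SimSpec, genes_per_chrom: int = 20,
                        gene_length: int = 50_000) -> list[GeneModel]:
    """Evenly spaced, non-overlapping toy genes on each chromosome.

    The geometry is deterministic and independent of the seed: gene i on a
    chromosome of length L sits centred in the i-th of ``genes_per_chrom``
    equal slots, so sweeps of a few hundred kb always contain genes.
    """
    genes: list[GeneModel] = []
    for chrom, length in spec.chrom_lengths.items():
        if genes_per_chrom * gene_length > length:
            raise SweepscanError(
                f"{genes_per_chrom} genes of {gene_length} bp exceed "
                f"{chrom} ({length} bp)")
        slot = length // genes_per_chrom
        offset = (slot - gene_length) // 2
        for i in range(genes_per_chrom):
            start = i * slot + offset + 1
            genes.append(GeneModel(f"{chrom}_g{i + 1:03d}", chrom,
                                   start, start + gene_length - 1))
    return genes


def genes_in_regions(genes: list[GeneModel], regions: list[Region]) -> list[str]:
    """Gene ids overlapping any region by >=1 bp, in gene order."""
    hits: list[str] = []
    for g in genes:
        for r in regions:
            if g.chrom == r.chrom and g.start <= r.end and g.end >= r.start:
                hits.append(g.gene_id)
                break
    return hits


def attach_truth_genes(truth: TruthSet, genes: list[GeneModel]) -> TruthSet:
    """Fill ``truth.genes_in_sweeps`` from a gene annotation."""
    truth.genes_in_sweeps = genes_in_regions(genes, truth.regions)
    return truth


def make_toy_termmap(genes: list[GeneModel], n_terms: int = 20,
                     enriched_term_fraction: float = 0.8, seed: int = 0,
                     sweep_genes: list[str] | None = None) -> dict[str, set[str]]:
    """Random term->gene map with one deliberately loaded term.

    Every gene is assigned to at least one of ``n_terms`` generic terms.
    When ``sweep_genes`` is given, the designated term ``TERM_ENRICHED``
    additionally receives ``enriched_term_fraction`` of those genes (rounded
    up), giving enrichment tests a positive control.
    """
    if not genes:
        raise SweepscanError("empty gene list")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    term_names = [f"TERM_{i + 1:04d}" for i in range(n_terms)]
    term_map: dict[str, set[str]] = {t: set() for t in term_names}
    for g in genes:
        k = rng.integers(1, min(3, n_terms) + 1)
        for t in rng.choice(term_names, size=k, replace=False):
            term_map[t].add(g.gene_id)
    # ensure no empty term
    for t in term_names:
        if not term_map[t]:
            term_map[t].add(genes[rng.integers(len(genes))].gene_id)
    if sweep_genes:
        n_load = int(np.ceil(enriched_term_fraction * len(sweep_genes)))
        loaded = list(sweep_genes)[:n_load]
        term_map["TERM_ENRICHED"] = set(loaded)
    return term_map
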