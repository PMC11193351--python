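"""End-to-end orchestration: config, staged execution, run manifest.

``run_all`` executes simulate/load → scan → genes → enrichment → structure
and writes every table, BED, gene list and the newick tree into the output
directory together with a JSON manifest (package version, seed, a hash of
the parameters, and per-stage bookkeeping counts).  The same config and
inputs always produce identical outputs: all randomness flows from the
single root seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from . import candidate_genes as cg
from . import enrichment as enr
from . import io_formats as io
from . import structure as st
from . import synthetic_data as sd
from . import window_scan as ws

log = logging.getLogger("sweepscan")


@dataclass
class Comparison:
    pop_a: str
    pop_b: str
    focal: str


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults follow the scan's conventions
    (100-kb windows, 50-kb step, top 5% dual thresholds)."""

    out_dir: str = "sweepscan_out"
    vcf: str | None = None
    pop_map: str | None = None
    annotation: str | None = None
    term_map: str | None = None
    simulate: bool = False
    sim: dict[str, Any] = field(default_factory=dict)
    window: int = 100_000
    step: int = 50_000
    top_fraction: float = 0.05
    fst_mode: str = "ratio"
    min_snps: int = 10
    comparisons: list[Comparison] = field(default_factory=list)
    enrich_mode: str = "literal"
    enrich_gene_set: str = "union"   # or "shared"
    tree: bool = True
    pca: bool = True
    n_boot: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 0.5:
            raise ValueError("top_fraction must be in (0, 0.5)")
        self.comparisons = [
            c if isinstance(c, Comparison) else Comparison(**c)
            for c in self.comparisons
        ]
        focals = {c.focal for c in self.comparisons}
        if len(self.comparisons) > 1 and len(focals) != 1:
            raise ValueError("the focal population must be the same in "
                             "every comparison")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def params_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _build_sim_spec(config: PipelineConfig) -> sd.SimSpec:
    overrides = dict(config.sim)
    overrides.setdefault("seed", config.seed)
    return sd.SimSpec.from_mapping(overrides)


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns the manifest dict (also written to disk).

    On a stage failure, files already written are renamed with a
    ``.partial`` suffix and a :class:`StageError` naming the stage is
    raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, Any] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    sim_seed, boot_seed, term_seed = (int(s.generate_state(1)[0] % 2**31)
                                      for s in seeds)

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        stage = "input"
        chrom_lengths = None
        truth = None
        if config.simulate:
            spec = _build_sim_spec(config).with_seed(sim_seed)
            matrix, truth = sd.simulate(spec)
            chrom_lengths = spec.chrom_lengths
            genes = sd.make_toy_annotation(spec)
            sd.attach_truth_genes(truth, genes)
            term_map = sd.make_toy_termmap(
                genes, seed=term_seed, sweep_genes=truth.genes_in_sweeps)
            io.write_vcf(matrix, emit(out / "simulated.vcf"), chrom_lengths)
            io.write_pop_map(dict(zip(matrix.samples, matrix.pops)),
                             emit(out / "pops.tsv"))
            io.write_bed(truth.regions, emit(out / "truth_sweeps.bed"))
            io.write_genes_bed(genes, emit(out / "genes.bed"))
            io.write_term_map(term_map, emit(out / "term_map.tsv"))
            if not config.comparisons:
                pops = spec.pop_labels
                config.comparisons = [Comparison(pops[0], p, pops[0])
                                      for p in pops[1:]]
        else:
            if not (config.vcf and config.pop_map):
                raise io.SweepscanError("vcf and pop_map required unless simulating")
            matrix = io.read_vcf(config.vcf, io.read_pop_map(config.pop_map))
            genes = io.read_genes(config.annotation) if config.annotation else []
            term_map = (io.read_term_map(config.term_map)
                        if config.term_map else {})
        counts["n_snps"] = matrix.n_variants
        counts["n_samples"] = matrix.n_samples
        counts["populations"] = matrix.pop_labels
        log.info("input: %d SNPs x %d samples, pops %s", matrix.n_variants,
                 matrix.n_samples, matrix.pop_labels)
        if not config.comparisons:
            pops = matrix.pop_labels
            config.comparisons = [Comparison(pops[0], p, pops[0])
                                  for p in pops[1:]]

        stage = "scan"
        comparisons: list[cg.ComparisonResult] = []
        counts["comparisons"] = {}
        for comp in config.comparisons:
            label = f"{comp.focal}_vs_{comp.pop_b if comp.focal == comp.pop_a else comp.pop_a}"
            res = ws.scan(matrix, comp.pop_a, comp.pop_b, comp.focal,
                          config.window, config.step, config.top_fraction,
                          config.fst_mode, config.min_snps, chrom_lengths)
            res.to_frame().to_csv(emit(out / f"windows_{label}.tsv"),
                                  sep="\t", index=False)
            io.write_bed(res.regions, emit(out / f"regions_{label}.bed"))
            gene_ids = cg.overlap_genes(res.regions, genes) if genes else []
            comparisons.append(cg.ComparisonResult(label, res.regions, gene_ids))
            counts["comparisons"][label] = {
                "eligible_windows": len(res.eligible_windows),
                "selected_windows": sum(w.selected for w in res.windows),
                "fst_threshold": res.fst_threshold,
                "h_threshold": res.h_threshold,
                "regions": len(res.regions),
                "genes": len(gene_ids),
            }
            log.info("scan %s: %d regions, %d genes (FST>%.6f, H<%.6f)",
                     label, len(res.regions), len(gene_ids),
                     res.fst_threshold, res.h_threshold)

        stage = "genes"
        union = cg.dedup_union(comparisons) if comparisons else []
        _write_gene_list(union, emit(out / "genes_union.txt"))
        counts["genes_union"] = len(union)
        shared: list[str] = []
        if len(comparisons) >= 2:
            shared = cg.shared_genes(comparisons)
            _write_gene_list(shared, emit(out / "genes_shared.txt"))
            counts["genes_shared"] = len(shared)
        else:
            log.warning("only one comparison: no shared-genes file")
        for c in comparisons:
            _write_gene_list(c.genes, emit(out / f"genes_{c.label}.txt"))

        stage = "enrichment"
        if term_map:
            cand = shared if (config.enrich_gene_set == "shared" and shared) else union
            background = sorted({g.gene_id for g in genes}) if genes else None
            results = enr.enrich(cand, term_map, background,
                                 mode=config.enrich_mode)
            enr.to_frame(results).to_csv(emit(out / "enrichment.tsv"),
                                         sep="\t", index=False)
            counts["terms_tested"] = len(results)
            counts["terms_significant"] = sum(r.significant for r in results)

        stage = "structure"
        if config.tree:
            if config.n_boot > 0:
                tree = st.bootstrap_support(matrix, config.n_boot, boot_seed)
            else:
                tree = st.neighbor_joining(st.ibs_distance(matrix))
            io.write_newick(tree, emit(out / "tree.nwk"))
        if config.pca:
            coords, explained = st.pca_genotypes(matrix, k=min(10, matrix.n_samples - 1))
            import pandas as pd
            df = pd.DataFrame(coords,
                              columns=[f"PC{i+1}" for i in range(coords.shape[1])])
            df.insert(0, "sample", matrix.samples)
            df.insert(1, "population", matrix.pops)
            df.to_csv(emit(out / "pca.tsv"), sep="\t", index=False)
            counts["pca_explained"] = [float(e) for e in explained[:5]]

        stage = "manifest"
        manifest = {
            "sweepscan_version": __version__,
            "seed": config.seed,
            "params_hash": config.params_hash(),
            "counts": counts,
            "outputs": sorted(p.name for p in written),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        for p in written:
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        raise StageError(stage, exc) from exc


def _write_gene_list(genes: list[str], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
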