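import numpy as np
import pytest

from sweepscan import SimSpec, SweepSpec, simulate
from sweepscan.io_formats import SweepscanError
from sweepscan.popgen_stats import per_snp_stats
from sweepscan.synthetic_data import (attach_truth_genes, genes_in_regions,
                                      make_toy_annotation, make_toy_termmap)
from sweepscan.window_scan import aggregate_windows, make_windows

SMALL = dict(samples_per_pop=10, n_snps=2000,
             chrom_lengths={"chr1": 2_000_000},
             sweep_regions=(SweepSpec("chr1", 800_001, 1_100_000, "pop1",
                                      0.6, 0.7),))


class TestSimulate:
    def test_same_seed_bit_identical(self):
        a, _ = simulate(SimSpec(seed=5, **SMALL))
        b, _ = simulate(SimSpec(seed=5, **SMALL))
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(a.pos, b.pos)

    def test_different_seeds_differ(self):
        a, _ = simulate(SimSpec(seed=5, **SMALL))
        b, _ = simulate(SimSpec(seed=6, **SMALL))
        assert not np.array_equal(a.dosage, b.dosage)

    def test_shape_labels_and_truth(self):
        m, truth = simulate(SimSpec(seed=1, **SMALL))
        assert m.n_variants == 2000 and m.n_samples == 20
        assert m.pop_labels == ["pop1", "pop2"]
        assert [(r.chrom, r.start, r.end) for r in truth.regions] == \
               [("chr1", 800_001, 1_100_000)]

    def test_missing_rate_applied(self):
        m, _ = simulate(SimSpec(seed=1, missing_rate=0.1, **SMALL))
        frac = np.mean(m.dosage == -1)
        assert 0.08 < frac < 0.12

    def test_empty_sweep_warns_but_emits_truth(self):
        spec = SimSpec(seed=1, samples_per_pop=5, n_snps=10,
                       chrom_lengths={"chr1": 10_000_000},
                       sweep_regions=(SweepSpec("chr1", 1, 50, "pop1",
                                                0.6, 0.7),))
        with pytest.warns(UserWarning, match="no simulated SNPs"):
            _, truth = simulate(spec)
        assert len(truth.regions) == 1

    @pytest.mark.parametrize("bad", [
        dict(n_pops=1),
        dict(background_F=0.0),
        dict(missing_rate=1.0),
        dict(sweep_regions=(SweepSpec("chrX", 1, 10, "pop1", 0.6, 0.7),)),
        dict(sweep_regions=(SweepSpec("chr1", 1, 10, "pop1", 0.01, 0.7),)),
        dict(sweep_regions=(SweepSpec("chr1", 1, 10, "pop9", 0.6, 0.7),)),
    ])
    def test_invalid_specs_rejected(self, bad):
        kwargs = {**SMALL, **bad}
        kwargs.setdefault("chrom_lengths", {"chr1": 2_000_000})
        with pytest.raises(ValueError):
            SimSpec(seed=0, **kwargs)


def _mean_windowed_fst(matrix, chrom_lengths):
    stats = per_snp_stats(matrix)
    windows = make_windows(chrom_lengths)
    aggregate_windows(stats, windows, "pop1")
    vals = [w.fst_win for w in windows if w.eligible]
    return float(np.mean(vals))


def test_low_divergence_limit_gives_near_zero_fst():
    """As background F -> 0 with no sweeps, windowed FST stays < 0.02."""
    for seed in range(5):
        spec = SimSpec(seed=seed, background_F=0.001, sweep_regions=())
        m, _ = simulate(spec)
        assert _mean_windowed_fst(m, spec.chrom_lengths) < 0.02


def test_mean_fst_monotone_in_divergence():
    means = []
    for F in (0.01, 0.1, 0.3):
        vals = []
        for seed in range(3):
            spec = SimSpec(seed=seed, background_F=F, sweep_regions=())
            m, _ = simulate(spec)
            vals.append(_mean_windowed_fst(m, spec.chrom_lengths))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_full_fixation_bias_zeroes_focal_het_in_sweep():
    spec = SimSpec(seed=2, samples_per_pop=10, n_snps=2000,
                   chrom_lengths={"chr1": 2_000_000},
                   sweep_regions=(SweepSpec("chr1", 800_001, 1_100_000,
                                            "pop1", 0.9, 1.0),))
    m, truth = simulate(spec)
    stats = per_snp_stats(m)
    r = truth.regions[0]
    in_sweep = (m.pos >= r.start) & (m.pos <= r.end)
    assert in_sweep.sum() > 50
    assert np.nanmax(stats.he_of("pop1")[in_sweep]) == 0.0


def test_sweep_windows_have_depressed_focal_het():
    """Paired sweep-vs-background comparison of focal-population He."""
    for seed in range(5):
        spec = SimSpec(seed=seed)
        m, truth = simulate(spec)
        stats = per_snp_stats(m)
        windows = make_windows(spec.chrom_lengths)
        aggregate_windows(stats, windows, "pop1")
        r = truth.regions[0]
        sweep = [w.h_win for w in windows if w.eligible and w.chrom == r.chrom
                 and w.start <= r.end and w.end >= r.start]
        bg = [w.h_win for w in windows if w.eligible and not (
            w.chrom == r.chrom and w.start <= r.end and w.end >= r.start)]
        assert np.mean(sweep) < np.mean(bg)


class TestToyAnnotation:
    def test_disjoint_even_tiling(self):
        spec = SimSpec(seed=0, chrom_lengths={"chr1": 1_000_000}, sweep_regions=())
        genes = make_toy_annotation(spec, genes_per_chrom=10, gene_length=10_000)
        assert len(genes) == 10
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start
        assert all(g.end - g.start + 1 == 10_000 for g in genes)

    def test_geometry_is_seed_independent(self):
        g1 = make_toy_annotation(SimSpec(seed=1))
        g2 = make_toy_annotation(SimSpec(seed=99))
        assert g1 == g2

    def test_sweeps_contain_genes(self):
        spec = SimSpec(seed=0)
        genes = make_toy_annotation(spec)
        _, truth = simulate(spec)
        attach_truth_genes(truth, genes)
        assert truth.genes_in_sweeps

    def test_overflow_rejected(self):
        spec = SimSpec(seed=0, chrom_lengths={"chr1": 100_000}, sweep_regions=())
        with pytest.raises(SweepscanError):
            make_toy_annotation(spec, genes_per_chrom=10, gene_length=20_000)


class TestToyTermMap:
    def test_deterministic_and_covering(self):
        genes = make_toy_annotation(SimSpec(seed=0))
        t1 = make_toy_termmap(genes, seed=4)
        t2 = make_toy_termmap(genes, seed=4)
        assert t1 == t2
        covered = set().union(*t1.values())
        assert covered == {g.gene_id for g in genes}

    def test_loaded_term_holds_stated_fraction(self):
        genes = make_toy_annotation(SimSpec(seed=0))
        sweep_genes = [g.gene_id for g in genes[:10]]
        tm = make_toy_termmap(genes, enriched_term_fraction=0.8, seed=4,
                              sweep_genes=sweep_genes)
        assert len(tm["TERM_ENRICHED"]) == 8
        assert tm["TERM_ENRICHED"] <= set(sweep_genes)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(SweepscanError):
            make_toy_termmap([], seed=0)


def test_genes_in_regions_boundary():
    spec = SimSpec(seed=0, chrom_lengths={"chr1": 1_000_000}, sweep_regions=())
    genes = make_toy_annotation(spec, genes_per_chrom=4, gene_length=1000)
    from sweepscan import Region
    g = genes[0]
    assert genes_in_regions([g], [Region("chr1", g.end, g.end + 10)]) == [g.gene_id]
    assert genes_in_regions([g], [Region("chr1", g.end + 1, g.end + 10)]) == []
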