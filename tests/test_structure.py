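import numpy as np
import pytest
from skbio import DistanceMatrix

from sweepscan import (GenotypeMatrix, SimSpec, bootstrap_support,
                       ibs_distance, is_monophyletic, neighbor_joining,
                       pca_genotypes, simulate)
from sweepscan.io_formats import SweepscanError
from sweepscan.structure import tip_bipartitions

from conftest import random_additive_tree


def _matrix(dosage, pops=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    V, S = dosage.shape
    return GenotypeMatrix(
        chrom=np.array(["c"] * V, dtype=object), pos=np.arange(1, V + 1),
        dosage=dosage, samples=[f"s{i}" for i in range(S)],
        pops=pops or ["A"] * S)


class TestIbsDistance:
    def test_identical_samples_distance_zero(self):
        d = ibs_distance(_matrix([[1, 1], [2, 2], [0, 0]]))
        assert d["s0", "s1"] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        d = ibs_distance(_matrix([[0, 2], [0, 2], [0, 2]]))
        assert d["s0", "s1"] == 1.0

    def test_hand_example_two_thirds(self):
        d = ibs_distance(_matrix([[0, 2], [1, 1], [2, 0]]))
        assert d["s0", "s1"] == pytest.approx(2 / 3)

    def test_missing_excluded_pairwise(self):
        d = ibs_distance(_matrix([[0, 2], [-1, 1], [0, 0]]))
        assert d["s0", "s1"] == pytest.approx(0.5)  # mean of (1, 0)

    def test_no_joint_snps_names_pair(self):
        with pytest.raises(SweepscanError, match="s0.*s1"):
            ibs_distance(_matrix([[0, -1], [-1, 2]]))

    def test_axioms_on_random_data(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(0, 3, size=(100, 8)))
        d = ibs_distance(m)
        arr = np.asarray(d.data)
        assert np.allclose(arr, arr.T)
        assert np.all(np.diag(arr) == 0)
        assert np.all(arr >= 0) and np.all(arr <= 1)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                            ids=["a", "b", "c"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): internal edge length 1
        d = {("A", "B"): 3, ("C", "D"): 7, ("A", "C"): 5,
             ("A", "D"): 6, ("B", "C"): 6, ("B", "D"): 7}
        ids = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = neighbor_joining(DistanceMatrix(mat, ids=ids))
        assert tip_bipartitions(tree) == {frozenset({"A", "B"})}
        back = tree.tip_tip_distances(endpoints=ids)
        np.testing.assert_allclose(np.asarray(back.data), mat, atol=1e-12)

    def test_identical_rows_join_at_zero(self):
        dm = DistanceMatrix([[0, 0, 5, 5], [0, 0, 5, 5],
                             [5, 5, 0, 2], [5, 5, 2, 0]],
                            ids=["a", "b", "c", "d"])
        tree = neighbor_joining(dm)
        a = tree.find("a")
        sibs = {t.name for t in a.parent.tips()}
        assert sibs == {"a", "b"}
        assert a.length == pytest.approx(0.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(SweepscanError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            true_tree, dm = random_additive_tree(int(rng.integers(5, 9)), rng)
            est = neighbor_joining(dm)
            back = est.tip_tip_distances(endpoints=list(dm.ids))
            np.testing.assert_allclose(np.asarray(back.data),
                                       np.asarray(dm.data), atol=1e-9)
            assert tip_bipartitions(est) == tip_bipartitions(true_tree)

    def test_agrees_with_skbio_nj_oracle(self):
        """Independent cross-check: same topology as scikit-bio's NJ on
        generic (noise-perturbed additive) matrices."""
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(4)
        for _ in range(5):
            _, dm = random_additive_tree(6, rng)
            noisy = np.asarray(dm.data) + rng.uniform(0, 0.01, size=(6, 6))
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0)
            ndm = DistanceMatrix(noisy, ids=list(dm.ids))
            assert tip_bipartitions(neighbor_joining(ndm)) == \
                tip_bipartitions(skbio_nj(ndm))


class TestMonophyly:
    def test_hand_tree(self):
        dm = DistanceMatrix([[0, 1, 8, 8, 8], [1, 0, 8, 8, 8],
                             [8, 8, 0, 1, 2], [8, 8, 1, 0, 2],
                             [8, 8, 2, 2, 0]],
                            ids=["a1", "a2", "b1", "b2", "b3"])
        tree = neighbor_joining(dm)
        assert is_monophyletic(tree, {"a1", "a2"})
        assert is_monophyletic(tree, {"b1", "b2", "b3"})
        assert not is_monophyletic(tree, {"a1", "b1"})
        with pytest.raises(ValueError):
            is_monophyletic(tree, {"zz"})


class TestPca:
    def test_two_point_configuration(self):
        dosage = np.zeros((100, 10), dtype=np.int8)
        dosage[:, 5:] = 2
        m = _matrix(dosage, pops=["A"] * 5 + ["B"] * 5)
        coords, explained = pca_genotypes(m, k=2, patterson=False)
        assert np.ptp(coords[:5, 0]) == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(coords[5:, 0]) == pytest.approx(0.0, abs=1e-9)
        assert abs(coords[0, 0] - coords[5, 0]) > 1
        assert explained[0] == pytest.approx(1.0)

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(200, 6)).astype(np.int8)
        dosage[:, 5] = dosage[:, 4]
        coords, _ = pca_genotypes(_matrix(dosage), k=3)
        np.testing.assert_allclose(coords[4], coords[5], atol=1e-9)

    def test_order_permutation_invariance_up_to_sign(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(300, 12)).astype(np.int8)
        m = _matrix(dosage)
        perm = rng.permutation(12)
        mp = _matrix(dosage[:, perm])
        c1, _ = pca_genotypes(m, k=3)
        c2, _ = pca_genotypes(mp, k=3)
        for j in range(3):
            col = c1[perm, j]
            assert (np.allclose(col, c2[:, j], atol=1e-8)
                    or np.allclose(col, -c2[:, j], atol=1e-8))

    def test_k_above_rank_reduced_with_warning(self):
        dosage = np.zeros((50, 3), dtype=np.int8)
        dosage[:, 1] = 1
        dosage[:, 2] = 2
        with pytest.warns(UserWarning, match="rank"):
            coords, _ = pca_genotypes(_matrix(dosage), k=3, patterson=False)
        assert coords.shape[1] < 3


def test_bootstrap_support_on_clear_structure():
    spec = SimSpec(samples_per_pop=8, n_snps=500, background_F=0.3,
                   chrom_lengths={"chr1": 1_000_000}, sweep_regions=(),
                   seed=6)
    m, _ = simulate(spec)
    tree = bootstrap_support(m, n_boot=25, seed=1)
    supports = [int(n.name) for n in tree.non_tips(include_self=False)
                if n.name is not None]
    assert supports and all(0 <= s <= 100 for s in supports)
    # the split between the two populations is recovered with high support
    pop1 = {s for s, p in zip(m.samples, m.pops) if p == "pop1"}
    assert is_monophyletic(tree, pop1)
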