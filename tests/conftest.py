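import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from sweepscan import GenotypeMatrix, SimSpec, simulate


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """3 SNPs x 4 samples in two populations, one missing call."""
    dosage = np.array(
        [[0, 1, 2, 2],
         [2, 2, 0, 0],
         [1, 1, 1, -1]], dtype=np.int8)
    return GenotypeMatrix(
        chrom=np.array(["chr1", "chr1", "chr2"], dtype=object),
        pos=np.array([100, 200, 150]),
        dosage=dosage,
        samples=["a1", "a2", "b1", "b2"],
        pops=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default study condition: 2 pops x 30, 10k SNPs, one 300-kb sweep."""
    return simulate(SimSpec(seed=11))


def random_additive_tree(n_tips: int, rng: np.random.Generator):
    """A random binary tree with branch lengths in [0.1, 2] and its
    (additive) tip-to-tip distance matrix."""
    tips = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 2)))
            for i in range(n_tips)]
    while len(tips) > 2:
        i, j = sorted(rng.choice(len(tips), 2, replace=False))[::-1]
        a, b = tips.pop(int(i)), tips.pop(int(j))
        tips.append(TreeNode(children=[a, b], length=float(rng.uniform(0.1, 2))))
    root = TreeNode(children=tips)
    dm = root.tip_tip_distances()
    return root, DistanceMatrix(dm.data, ids=list(dm.ids))
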