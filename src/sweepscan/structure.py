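"""Population-structure diagnostics: IBS distances, NJ trees, genotype PCA.

The distance between two diploid genotypes is allele-sharing identity by
state: d(a,b) = mean over jointly called SNPs of |dosage_a - dosage_b| / 2,
i.e. one minus the shared-allele proportion.  Trees are built with the
Saitou–Nei neighbor-joining algorithm implemented here from the Q-criterion
up (scikit-bio supplies only the DistanceMatrix/TreeNode containers and the
newick serialization).  PCA operates on mean-imputed, centred dosages with
optional Patterson (sqrt(p(1-p))) scaling.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .io_formats import MISSING, GenotypeMatrix, SweepscanError


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing (IBS) distance matrix over all samples.

    Raises on a sample pair with zero jointly called SNPs.
    """
    if matrix.n_samples < 2:
        raise SweepscanError("need >=2 samples for a distance matrix")
    D = matrix.dosage.astype(float)
    D[matrix.dosage == MISSING] = np.nan
    S = matrix.n_samples
    out = np.zeros((S, S))
    for i in range(S):
        diff = np.abs(D[:, i][:, None] - D[:, i + 1:]) / 2.0
        counts = np.sum(~np.isnan(diff), axis=0)
        zero = np.flatnonzero(counts == 0)
        if zero.size:
            j = i + 1 + zero[0]
            raise SweepscanError(
                f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} "
                "share no jointly called SNPs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[i, i + 1:] = np.nanmean(diff, axis=0)
    out = out + out.T
    return DistanceMatrix(out, ids=list(matrix.samples))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei NJ tree from a distance matrix.

    Iteratively joins the pair (i, j) minimizing
    Q(i,j) = (r-2) d(i,j) - R_i - R_j, with limb lengths
    l_i = d(i,j)/2 + (R_i - R_j) / (2(r-2)); a negative limb is clamped to
    zero and its deficit moved to the sister limb, preserving l_i + l_j =
    d(i,j).  The result is unrooted: the root node is the final three-way
    (or, for 3 taxa, the unique central) junction.
    """
    labels = list(dm.ids)
    r = len(labels)
    if r < 3:
        raise SweepscanError("neighbor joining needs >=3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (R[i] - R[j]) / (2 * (r - 2))
        lj = d_ij - li
        if li < 0:
            li, lj = 0.0, d_ij
        elif lj < 0:
            li, lj = d_ij, 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        keep = np.arange(len(nodes)) != j
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]
    # final three-way join: closed-form limb lengths
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = float(max(ln, 0.0))
    return TreeNode(children=nodes)


def tip_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial tip bipartitions (one side each) induced by internal edges."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            parts.add(min(side, all_tips - side, key=sorted))
    return parts


def is_monophyletic(tree: TreeNode, tips: set[str]) -> bool:
    """True if ``tips`` form a clade of the unrooted tree.

    On an unrooted tree a sample set is monophyletic iff some edge separates
    exactly that set from the rest (trivial single-tip and all-but-one sets
    included).
    """
    all_tips = frozenset(t.name for t in tree.tips())
    target = frozenset(tips)
    if not target or not target <= all_tips:
        raise ValueError("tips must be a non-empty subset of the tree's tips")
    if len(target) in (1, len(all_tips), len(all_tips) - 1):
        return True
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == target or all_tips - side == target:
            return True
    return False


def bootstrap_support(matrix: GenotypeMatrix, n_boot: int = 100,
                      seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap support (% of replicates) on internal nodes.

    Replicates resample SNP columns with replacement; each internal node of
    the full-data tree is named with the percentage of replicate trees
    containing the same tip bipartition.
    """
    tree = neighbor_joining(ibs_distance(matrix))
    rng = np.random.default_rng(seed)
    all_tips = frozenset(matrix.samples)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, matrix.n_variants, size=matrix.n_variants)
        boot = GenotypeMatrix(
            chrom=np.array([f"bs{i}" for i in range(matrix.n_variants)], dtype=object),
            pos=np.arange(1, matrix.n_variants + 1),
            dosage=matrix.dosage[idx],
            samples=matrix.samples, pops=matrix.pops)
        for part in tip_bipartitions(neighbor_joining(ibs_distance(boot))):
            counts[part] = counts.get(part, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            key = min(side, all_tips - side, key=sorted)
            node.name = str(round(100 * counts.get(key, 0) / n_boot))
    return tree


def pca_genotypes(matrix: GenotypeMatrix, k: int = 10,
                  patterson: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA: (sample coordinates on k PCs, explained-variance ratio).

    Missing dosages are imputed to the SNP mean; each SNP is mean-centred
    and, with ``patterson=True``, divided by sqrt(p(1-p)) where p is the
    mean alt-allele frequency.  Zero-variance SNPs are dropped.  ``k`` above
    the data rank is reduced with a warning.
    """
    if matrix.n_samples < 2:
        raise SweepscanError("need >=2 samples for PCA")
    X = matrix.dosage.astype(float)
    X[matrix.dosage == MISSING] = np.nan
    mean = np.nanmean(X, axis=1)
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[0]]
    keep = X.std(axis=1) > 0
    X = X[keep] - mean[keep, None]
    if patterson:
        p = mean[keep] / 2.0
        X /= np.sqrt(p * (1 - p))[:, None]
    U, s, Vt = np.linalg.svd(X.T, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds data rank {rank}; reduced")
        k = rank
    coords = U[:, :k] * s[:k]
    explained = s[:k] ** 2 / np.sum(s ** 2)
    return coords, explained
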