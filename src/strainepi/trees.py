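"""Approximate per-species phylogenies from gene presence profiles.

Whole-genome phylogenies are rarely available for every species in a
metagenomic survey, but the binarized gene presence matrix carries the same
subspecies structure.  The pipeline here: adaptive PCA of the presence
matrix (keeping components up to and including the first eigenvalue below a
tenth of the leading one, to suppress presence/absence noise), Euclidean
distances between samples in the reduced space, neighbor-joining, midpoint
rooting, and ladderization.  The whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .containers import GeneMatrix

__all__ = [
    "PcaResult",
    "adaptive_pca",
    "pc_distance",
    "neighbor_join",
    "ladderize",
    "midpoint_root",
    "build_tree",
]


@dataclass
class PcaResult:
    """Eigenvalues, number of components kept, and sample scores."""

    eigenvalues: np.ndarray
    components_kept: int
    scores: np.ndarray  # (n_samples, components_kept)


def _select_k(eigenvalues: np.ndarray, ratio: float, inclusive: bool) -> int:
    """First eigenvalue under ratio * lambda_1, kept inclusively by default."""
    lam1 = eigenvalues[0]
    below = np.flatnonzero(eigenvalues < ratio * lam1)
    if below.size == 0:
        return len(eigenvalues)
    k = int(below[0]) + 1 if inclusive else int(below[0])
    return max(k, 1)


def adaptive_pca(
    m: GeneMatrix | np.ndarray, ratio: float = 0.1, inclusive: bool = True
) -> PcaResult:
    """PCA of a presence matrix with adaptive component selection.

    Samples are observations, genes are variables; columns are mean-centered
    but not scaled (presence columns share the 0/1 scale).  Components are
    kept up to the first eigenvalue smaller than ``ratio`` times the leading
    eigenvalue, including that component (set ``inclusive=False`` for the
    exclusive variant).
    """
    X = m.abundance.T if isinstance(m, GeneMatrix) else np.asarray(m, dtype=float)
    n, g = X.shape
    if n < 3 or g < 2:
        raise ValueError("need at least 3 samples and 2 genes")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (n - 1)
    if lam[0] <= 0 or not np.any(lam > 1e-12):
        raise ValueError("no variation: all samples are identical")
    nz = int((lam > 1e-12 * lam[0]).sum())
    lam = lam[:nz]
    k = _select_k(lam, ratio, inclusive)
    scores = u[:, :k] * s[:k]
    return PcaResult(eigenvalues=lam, components_kept=k, scores=scores)


def pc_distance(scores: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between sample rows of a score matrix."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score matrix")
    return squareform(pdist(scores, metric="euclidean"))


def neighbor_join(d: np.ndarray, names: list[str]) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    For an additive input matrix the patristic distances of the returned
    tree reproduce the input exactly.  Negative estimated branch lengths are
    clipped to zero with the deficit transferred to the adjacent edge.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    if len(names) != d.shape[0]:
        raise ValueError("names do not match matrix size")
    if len(names) < 2:
        raise ValueError("need at least 2 taxa")
    if len(names) == 2:
        half = d[0, 1] / 2.0
        a = TreeNode(name=names[0])
        a.length = half
        b = TreeNode(name=names[1])
        b.length = half
        return TreeNode(children=[a, b])
    return _skbio_nj(DistanceMatrix(d, [str(n) for n in names]), neg_as_zero=True)


def ladderize(tree: TreeNode, ascending: bool = True) -> TreeNode:
    """Reorder children of every internal node by descendant-leaf count.

    Topology-preserving and idempotent; returns a copy.
    """
    out = tree.copy()
    for node in out.postorder():
        node._tipcount = 1 if node.is_tip() else sum(c._tipcount for c in node.children)
    for node in out.preorder():
        if node.children:
            node.children = sorted(
                node.children, key=lambda c: c._tipcount, reverse=not ascending
            )
    for node in out.traverse(include_self=True):
        del node._tipcount
    return out


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root the tree at the midpoint of the longest tip-to-tip path."""
    return tree.root_at_midpoint()


def build_tree(
    presence: GeneMatrix, ratio: float = 0.1, inclusive: bool = True
) -> TreeNode:
    """Full pipeline: adaptive PCA -> Euclidean distance -> neighbor joining
    -> midpoint rooting -> ladderize.  Leaves are the matrix's sample ids."""
    pca = adaptive_pca(presence, ratio=ratio, inclusive=inclusive)
    d = pc_distance(pca.scores)
    tree = neighbor_join(d, presence.sample_ids)
    return ladderize(midpoint_root(tree))
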