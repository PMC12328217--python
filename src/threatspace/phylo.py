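"""Tree input/output and phylogenetic covariance matrices.

Species that share evolutionary history are not independent samples: under a
Brownian-motion model of trait change, the covariance between two tips equals
the length of root-to-ancestor path they share.  Pagel's lambda scales the
off-diagonal (shared) part of that matrix, interpolating between a star
phylogeny (lambda = 0, independence) and full Brownian covariance
(lambda = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "tip_depths",
    "phylo_covariance",
]


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree with branch lengths.

    Raises ``ValueError`` on malformed input, missing branch lengths on
    non-root edges, or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick string: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    return depths


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance matrix with a fixed species ordering.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of species i and j
    scaled by ``lam`` for i != j; the diagonal holds unscaled tip depths.
    """

    species: list[str]
    matrix: np.ndarray
    lam: float

    def index_of(self, labels) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.species)}
        return np.array([pos[s] for s in labels], dtype=int)

    def reordered(self, labels) -> "PhyloCovariance":
        idx = self.index_of(labels)
        return PhyloCovariance(
            species=list(labels), matrix=self.matrix[np.ix_(idx, idx)], lam=self.lam
        )


def _shared_path_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Dense matrix of shared root-to-MRCA path lengths for all tip pairs.

    Post-order sweep: at each internal node, every pair of tips drawn from two
    different child subtrees has its MRCA exactly there, so the shared path is
    that node's depth.  O(n^2) total work.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    tree.calc_node_root_distances(return_leaf_distances_only=False)
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            C[i, i] = node.root_distance
        else:
            children = [below.pop(id(ch)) for ch in node.child_nodes()]
            depth = node.root_distance or 0.0
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = np.asarray(children[a])
                    ib = np.asarray(children[b])
                    C[np.ix_(ia, ib)] = depth
                    C[np.ix_(ib, ia)] = depth
            below[id(node)] = [i for ch in children for i in ch]
    return labels, C


def phylo_covariance(tree: dendropy.Tree, lam: float = 1.0) -> PhyloCovariance:
    """Brownian-motion covariance of the tips under Pagel's lambda scaling.

    The diagonal (tip depths) is unchanged by ``lam``; off-diagonal entries
    are multiplied by it.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    labels, C = _shared_path_matrix(tree)
    off = C - np.diag(np.diag(C))
    M = lam * off + np.diag(np.diag(C))
    return PhyloCovariance(species=labels, matrix=M, lam=lam)
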