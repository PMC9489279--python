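"""Ultrametric phylogeny handling for phylogenetic mixed models.

The host-range models need three quantities derived from a rooted,
ultrametric species tree:

* the cophenetic distance of every species from the focal (native) host,
  used as a fixed-effect covariate;
* the relatedness matrix ``A`` whose entry ``A[i, j]`` is the depth (distance
  from the root) of the most recent common ancestor of tips *i* and *j* --
  the Brownian-motion trait covariance structure on an ultrametric tree;
* the inverse of ``A``, which enters the mixed-model equations.

Newick I/O is delegated to :mod:`dendropy`; this module adds validation
(ultrametricity, branch-length presence), the derived matrices, and pruning
that preserves the tree height and all pairwise tip distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "NotUltrametricError",
    "UltrametricTree",
    "RelatednessStructure",
    "FocalDistanceVector",
    "parse_newick",
    "to_newick",
    "validate_ultrametric",
    "cophenetic_distance",
    "distance_from_focal",
    "relatedness_matrix",
    "prune_to_taxa",
]

#: Relative tolerance used by default when checking that all tips are
#: equidistant from the root.
DEFAULT_ULTRAMETRIC_TOL = 1e-6

#: Effective minimum branch length (as a fraction of tree height) imposed
#: when building the relatedness matrix, so that zero-length terminal splits
#: cannot make A singular.
MIN_BRANCH_FRACTION = 1e-9


class TreeError(ValueError):
    """Malformed or invalid input tree."""


class NotUltrametricError(TreeError):
    """Tips are not all equidistant from the root."""


@dataclass
class UltrametricTree:
    """A rooted tree with branch lengths, intended to be ultrametric.

    ``taxa`` lists tip labels in Newick first-appearance order, which is the
    deterministic taxon order used everywhere downstream (design matrices,
    relatedness matrix rows).  The underlying dendropy tree is kept for
    structural operations; ``depths`` maps every node to its distance from
    the root.
    """

    taxa: list[str]
    _tree: dendropy.Tree
    depths: dict = field(repr=False)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def tip_depth(self, label: str) -> float:
        node = self._find_tip(label)
        return self.depths[node]

    def _find_tip(self, label: str):
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is not None and leaf.taxon.label == label:
                return leaf
        raise TreeError(f"unknown tip label: {label!r} (known tips: {self.taxa})")

    def newick(self) -> str:
        return to_newick(self)


def _compute_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0 if node.edge.length is None else float(node.edge.length)
        else:
            if node.edge.length is None:
                label = node.taxon.label if node.taxon else "<internal>"
                raise TreeError(
                    f"missing branch length on edge leading to {label}; "
                    "all non-root edges must carry a length"
                )
            if node.edge.length < 0:
                raise TreeError(f"negative branch length {node.edge.length}")
            depths[node] = depths[node.parent_node] + float(node.edge.length)
    return depths


def _from_dendropy(tree: dendropy.Tree) -> UltrametricTree:
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    return UltrametricTree(taxa=taxa, _tree=tree, depths=_compute_depths(tree))


def parse_newick(text: str) -> UltrametricTree:
    """Parse a Newick string into an :class:`UltrametricTree`.

    Branch lengths are required on every non-root edge; quoted labels are
    supported.  Raises :class:`TreeError` with the offending position for
    malformed input.  No ultrametricity check is performed here -- call
    :func:`validate_ultrametric`.
    """
    if not text or not text.strip():
        raise TreeError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return _from_dendropy(tree)


def to_newick(tree: UltrametricTree) -> str:
    """Serialize with full float precision so write -> parse round-trips."""
    s = tree._tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    return s.strip()


def validate_ultrametric(
    tree: UltrametricTree, tol: float = DEFAULT_ULTRAMETRIC_TOL
) -> float:
    """Check all tips are equidistant from the root; return the height ``H``.

    The check is relative: ``max_i |depth_i - H| / H <= tol`` where ``H`` is
    the maximum tip depth.  On failure the error names the worst-offending
    tip and its deviation.
    """
    tip_depths = {
        leaf.taxon.label: tree.depths[leaf] for leaf in tree._tree.leaf_node_iter()
    }
    height = max(tip_depths.values())
    if height <= 0:
        raise NotUltrametricError("tree has zero height")
    worst_tip, worst_depth = min(tip_depths.items(), key=lambda kv: kv[1])
    deviation = (height - worst_depth) / height
    if deviation > tol:
        raise NotUltrametricError(
            f"tree is not ultrametric at relative tolerance {tol:g}: tip "
            f"{worst_tip!r} has depth {worst_depth:.6g} vs height {height:.6g} "
            f"(relative deviation {deviation:.3g})"
        )
    return height


def _mrca_depth_matrix(tree: UltrametricTree) -> np.ndarray:
    """Matrix of root-to-MRCA depths for every tip pair (diag = tip depth)."""
    index = {label: i for i, label in enumerate(tree.taxa)}
    n = len(tree.taxa)
    A = np.zeros((n, n))
    # Postorder: a node is the MRCA of every cross-pair of tips drawn from
    # two different child subtrees.
    leafsets: dict = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            leafsets[node] = [i]
            A[i, i] = tree.depths[node]
        else:
            children = [leafsets.pop(c) for c in node.child_nodes()]
            depth = tree.depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            A[i, j] = A[j, i] = depth
            leafsets[node] = [i for sub in children for i in sub]
    return A


def cophenetic_distance(tree: UltrametricTree, a: str, b: str) -> float:
    """Sum of branch lengths on the tip-to-tip path between ``a`` and ``b``."""
    if a == b:
        tree._find_tip(a)  # raises on unknown label
        return 0.0
    A = _mrca_depth_matrix(tree)
    index = {label: i for i, label in enumerate(tree.taxa)}
    for label in (a, b):
        if label not in index:
            raise TreeError(f"unknown tip label: {label!r}")
    i, j = index[a], index[b]
    return float(A[i, i] + A[j, j] - 2.0 * A[i, j])


@dataclass
class FocalDistanceVector:
    """Cophenetic distances of every tip from the focal host tip."""

    focal: str
    distances: dict[str, float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.distances, name=f"distance_from_{self.focal}")


def distance_from_focal(tree: UltrametricTree, focal: str) -> FocalDistanceVector:
    """Cophenetic distance of each tip from ``focal`` (the native host)."""
    index = {label: i for i, label in enumerate(tree.taxa)}
    if focal not in index:
        raise TreeError(f"focal taxon {focal!r} is not a tip of the tree")
    A = _mrca_depth_matrix(tree)
    f = index[focal]
    distances = {
        label: float(A[i, i] + A[f, f] - 2.0 * A[i, f]) for label, i in index.items()
    }
    return FocalDistanceVector(focal=focal, distances=distances)


@dataclass
class RelatednessStructure:
    """Tip-pair MRCA-depth matrix ``A``, its inverse, and the tree height."""

    taxon_order: list[str]
    A: np.ndarray
    A_inv: np.ndarray
    height: float

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(self.A, index=self.taxon_order, columns=self.taxon_order)
        frame.to_csv(path, sep="\t")

    def index_of(self, label: str) -> int:
        try:
            return self.taxon_order.index(label)
        except ValueError:
            raise TreeError(f"taxon {label!r} not in relatedness structure") from None


def relatedness_matrix(
    tree: UltrametricTree, tol: float = DEFAULT_ULTRAMETRIC_TOL
) -> RelatednessStructure:
    """Build ``A`` (root-to-MRCA depths) and its inverse for a validated tree.

    ``A`` is the Brownian-motion covariance structure on an ultrametric tree:
    the diagonal equals the height ``H`` and cophenetic distances satisfy
    ``d(i, j) = 2 (H - A[i, j])``.  The inverse is computed by dense Cholesky
    factorization (trees here are small); positive definiteness is verified
    in the process.  If the matrix is singular -- typically two tips joined
    by a zero-length split -- a minimum effective branch length of
    ``1e-9 * H`` is applied and the factorization retried once.
    """
    height = validate_ultrametric(tree, tol=tol)
    A = _mrca_depth_matrix(tree)

    def _try_invert(mat: np.ndarray):
        factor = cho_factor(mat)
        return cho_solve(factor, np.eye(mat.shape[0]))

    try:
        A_inv = _try_invert(A)
    except np.linalg.LinAlgError:
        # Pull near-duplicate rows apart by shrinking off-diagonal MRCA
        # depths that coincide with the tip depth.
        floor = MIN_BRANCH_FRACTION * height
        A_adj = A.copy()
        off = ~np.eye(A.shape[0], dtype=bool)
        A_adj[off] = np.minimum(A_adj[off], height - floor)
        try:
            A_inv = _try_invert(A_adj)
            A = A_adj
        except np.linalg.LinAlgError as exc:
            raise TreeError(
                "relatedness matrix is singular; ensure every pair of tips is "
                f"separated by a branch of length at least {floor:g} "
                "(duplicated taxa or zero-length terminal splits are the usual cause)"
            ) from exc
    return RelatednessStructure(
        taxon_order=list(tree.taxa), A=A, A_inv=A_inv, height=height
    )


def prune_to_taxa(tree: UltrametricTree, keep) -> UltrametricTree:
    """Induced subtree on ``keep``, preserving height and pairwise distances.

    Degree-2 internal nodes created by pruning are suppressed with their
    branch lengths summed.  The root is retained even if it becomes
    unifurcate, so tip depths (and hence the tree height) are unchanged.
    """
    keep = set(keep)
    unknown = sorted(keep - set(tree.taxa))
    if unknown:
        raise TreeError(f"cannot prune: unknown tips {unknown}")
    if len(keep) < 2:
        raise TreeError("pruning requires at least 2 tips to keep")
    clone = dendropy.Tree(tree._tree)
    clone.retain_taxa_with_labels(sorted(keep), suppress_unifurcations=False)
    # Suppress non-root unifurcations, summing branch lengths.
    changed = True
    while changed:
        changed = False
        for node in list(clone.preorder_node_iter()):
            if node.parent_node is None or node.is_leaf():
                continue
            children = node.child_nodes()
            if len(children) == 1:
                child = children[0]
                child.edge.length = (child.edge.length or 0.0) + (
                    node.edge.length or 0.0
                )
                parent = node.parent_node
                parent.remove_child(node)
                parent.add_child(child)
                changed = True
                break
    return _from_dendropy(clone)
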