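"""Rooted trees with branch lengths: newick I/O, patristic distances, and
mega-tree grafting.

The tree object is a :class:`dendropy.Tree`; this module adds the operations
a community-phylogenetics pipeline needs on top of it, most importantly
grafting species that are absent from a backbone phylogeny onto the basal
node of their genus (the V.PhyloMaker "scenario 3" style of placement, with
the genus basal node taken as the MRCA of the genus' largest monophyletic
cluster of tips).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "PatristicMatrix",
    "parse_newick",
    "read_newick",
    "write_newick",
    "patristic_distances",
    "mrca",
    "graft_tip",
    "prune_tips",
    "is_ultrametric",
    "tip_labels",
    "node_height",
]

PhyloTree = dendropy.Tree


class NewickError(ValueError):
    """Raised when a newick string cannot be parsed into a valid tree."""


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted newick statement into a tree.

    Tip labels must be unique. Branches without an explicit length are read
    as length 0 (with a warning), so the result always has numeric branch
    lengths.
    """
    if not text or not text.strip():
        raise NewickError("empty newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise NewickError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge: no length needed
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise NewickError(f"negative branch length {edge.length}")
    if n_missing:
        warnings.warn(
            f"{n_missing} branch length(s) missing in newick; read as 0",
            stacklevel=2,
        )
    return tree


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path=None) -> str:
    """Serialize a tree to newick; round-trips labels, topology and lengths."""
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def tip_labels(tree: PhyloTree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class PatristicMatrix:
    """Square matrix of tip-to-tip path-length sums on a tree.

    ``values[i, j]`` is the sum of branch lengths on the unique path between
    ``taxa[i]`` and ``taxa[j]``; symmetric with a zero diagonal.
    """

    taxa: list[str]
    values: np.ndarray
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def indices(self, labels) -> np.ndarray:
        try:
            return np.asarray([self._index[l] for l in labels], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"taxon not in distance matrix: {exc.args[0]}") from exc

    def submatrix(self, labels) -> np.ndarray:
        idx = self.indices(labels)
        return self.values[np.ix_(idx, idx)]

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def n(self) -> int:
        return len(self.taxa)


def patristic_distances(tree: PhyloTree, taxa=None) -> PatristicMatrix:
    """Compute the patristic distance matrix for ``taxa`` (default: all tips).

    Uses root distances and MRCA depths: d(i, j) = depth(i) + depth(j)
    − 2·depth(mrca(i, j)), accumulated in a single postorder pass.
    """
    leaves = list(tree.leaf_node_iter())
    all_labels = [lf.taxon.label for lf in leaves]
    if taxa is None:
        taxa = all_labels
    else:
        taxa = list(taxa)
        unknown = set(taxa) - set(all_labels)
        if unknown:
            raise KeyError(f"taxa not on tree: {sorted(unknown)}")
    pos = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    dist = np.zeros((n, n), dtype=float)

    # Postorder: each node carries (tip_index, root_distance) pairs of the
    # requested tips below it; pairs meeting first at a node have that node
    # as MRCA.
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            below[node] = [(pos[lbl], depth[node])] if lbl in pos else []
            continue
        children = [below.pop(ch) for ch in node.child_nodes()]
        merged: list = []
        d_node = depth[node]
        for ci, group in enumerate(children):
            for other in children[ci + 1:]:
                for i, di in group:
                    for j, dj in other:
                        d = di + dj - 2.0 * d_node
                        dist[i, j] = d
                        dist[j, i] = d
            merged.extend(group)
        below[node] = merged
    return PatristicMatrix(taxa=list(taxa), values=dist)


def mrca(tree: PhyloTree, tips) -> dendropy.Node:
    """Most recent common ancestor of the given tip labels.

    A single tip is its own MRCA.
    """
    tips = list(tips)
    if not tips:
        raise ValueError("mrca of an empty tip set")
    known = set(tip_labels(tree))
    unknown = set(tips) - known
    if unknown:
        raise KeyError(f"taxa not on tree: {sorted(unknown)}")
    tree.is_rooted = True
    return tree.mrca(taxon_labels=tips)


def node_height(node: dendropy.Node) -> float:
    """Maximum path length from a node down to any of its descendant tips."""
    if node.is_leaf():
        return 0.0
    return max(
        node_height(ch) + (ch.edge.length or 0.0) for ch in node.child_nodes()
    )


def is_ultrametric(tree: PhyloTree, tol: float = 1e-9) -> bool:
    """True iff all root-to-tip path lengths agree within ``tol``."""
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    depths = []
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            depths.append(depth[node])
    return (max(depths) - min(depths)) <= tol


def _genus_of(label: str) -> str:
    return label.split("_", 1)[0]


def _largest_genus_cluster(tree: PhyloTree, genus_tips: set[str]):
    """Maximal monophyletic clusters of the genus' tips; return the largest.

    Largest = most tips; ties broken by the shallower (closer to the root)
    cluster MRCA, then alphabetically by first tip label, for determinism.
    Returns the cluster's root node.
    """
    depth = {tree.seed_node: 0.0}
    pure: dict = {}  # node -> set of genus tip labels if clade is pure
    best = None
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            pure[node] = {lbl} if lbl in genus_tips else None
        else:
            kids = [pure.pop(ch) for ch in node.child_nodes()]
            if all(k is not None for k in kids):
                pure[node] = set().union(*kids)
            else:
                pure[node] = None
                # children that are pure but whose parent is not are maximal
                for ch, k in zip(node.child_nodes(), kids):
                    if k is not None:
                        key = (-len(k), depth[ch], min(k))
                        if best is None or key < best[0]:
                            best = (key, ch)
    root = tree.seed_node
    if pure.get(root) is not None:
        k = pure[root]
        key = (-len(k), depth[root], min(k))
        if best is None or key < best[0]:
            best = (key, root)
    return best[1] if best is not None else None


def graft_tip(
    tree: PhyloTree,
    new_species: str,
    genus: str | None = None,
    genus_tips=None,
    family_node=None,
) -> PhyloTree:
    """Attach a species absent from the backbone at its genus basal node.

    Placement rules (applied to a copy; the input tree is untouched):

    * genus with ≥ 2 tips in its largest monophyletic cluster — the new tip
      joins the cluster's MRCA as an extra child (polytomy) with pendant
      length equal to that node's height, preserving ultrametricity;
    * genus with exactly one tip — the tip's pendant branch is bisected and
      the new species hangs from the new midpoint node with the remaining
      half-length;
    * genus absent — the new tip joins the supplied ``family_node`` (a node
      of the copied tree found by MRCA of the given tip labels) by the same
      polytomy rule.

    Distances among pre-existing tips are never altered.
    """
    labels = set(tip_labels(tree))
    if new_species in labels:
        raise ValueError(f"{new_species!r} is already a tip")
    if genus_tips is None:
        g = genus if genus is not None else _genus_of(new_species)
        genus_tips = {l for l in labels if _genus_of(l) == g}
    else:
        genus_tips = set(genus_tips)
        unknown = genus_tips - labels
        if unknown:
            raise KeyError(f"genus tips not on tree: {sorted(unknown)}")

    new_tree = tree.clone(depth=1)
    by_label = {lf.taxon.label: lf for lf in new_tree.leaf_node_iter()}

    if genus_tips:
        cluster = _largest_genus_cluster(new_tree, genus_tips)
        cluster_tips = [lf.taxon.label for lf in cluster.leaf_iter()]
        if len(cluster_tips) >= 2:
            attach = cluster
            pendant = node_height(attach)
        else:
            # single-tip cluster: bisect the pendant branch
            tip = by_label[cluster_tips[0]]
            attach = _bisect_pendant(new_tree, tip)
            pendant = node_height(attach)
        if len(genus_tips) > len(cluster_tips):
            logger.info(
                "genus of %s non-monophyletic: grafting at largest cluster "
                "(%d of %d tips)", new_species, len(cluster_tips), len(genus_tips),
            )
    else:
        if family_node is None:
            raise ValueError(
                f"genus of {new_species!r} absent from backbone and no "
                "family node supplied"
            )
        if isinstance(family_node, dendropy.Node):
            # locate the corresponding node on the copy via its leaf set
            family_node = [lf.taxon.label for lf in family_node.leaf_iter()]
        family_node = mrca(new_tree, family_node)
        logger.info(
            "genus of %s absent from backbone; attaching at family node",
            new_species,
        )
        attach = family_node
        pendant = node_height(attach)
    taxon = new_tree.taxon_namespace.new_taxon(label=new_species)
    attach.new_child(taxon=taxon, edge_length=pendant)
    return new_tree


def _bisect_pendant(tree: PhyloTree, tip: dendropy.Node) -> dendropy.Node:
    parent = tip.parent_node
    half = (tip.edge.length or 0.0) / 2.0
    if parent is None:  # single-tip tree: tip hangs from the seed node
        parent = tree.seed_node
    mid = parent.new_child(edge_length=half)
    parent.remove_child(tip)
    mid.add_child(tip)
    tip.edge.length = half
    return mid


def prune_tips(tree: PhyloTree, labels) -> PhyloTree:
    """Copy of the tree with the given tips removed (unifurcations merged)."""
    labels = list(labels)
    new_tree = tree.clone(depth=1)
    new_tree.prune_taxa_with_labels(labels)
    new_tree.purge_taxon_namespace()
    return new_tree
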