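"""Phylogenetic trees: Newick I/O, rooting, pruning, patristic distances.

``PhyloTree`` wraps a :class:`dendropy.Tree`.  Node support values are kept
as fractions in ``[0, 1]`` on an extra ``support`` attribute of internal
nodes; Newick integers 0-100 are divided by 100 on read.  Two input
dialects are accepted: support as an internal-node label
(``(A:1,B:1)90:2``) and support in a bracketed comment (``(A:1,B:1)[90]:2``).
Output always uses the internal-label dialect.
"""

from __future__ import annotations

import io
import itertools
import math
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .errors import TreeError

__all__ = [
    "PhyloTree",
    "read_newick",
    "write_newick",
    "midpoint_root",
    "outgroup_root",
    "patristic_distances",
    "prune_one_per_species",
]


class PhyloTree:
    """A phylogeny with branch lengths and internal-edge support values.

    Attributes
    ----------
    dtree : dendropy.Tree
        Backing tree structure.  Internal nodes may carry a ``support``
        attribute (fraction in [0, 1]); tips never do.
    rooted : bool
        True when the tree has a designated root with exactly two children.
    """

    def __init__(self, dtree: dendropy.Tree, rooted: bool | None = None):
        self.dtree = dtree
        if rooted is None:
            rooted = len(dtree.seed_node.child_nodes()) == 2
        self.rooted = rooted
        self._validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        newick = newick.strip()
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
                extract_comment_metadata=False,
            )
        except (dendropy.utility.error.DataParseError, ValueError) as exc:
            msg = str(exc)
            if "duplicate" in msg.lower() or "multiple occurrences" in msg.lower():
                raise TreeError(f"duplicate tip labels: {msg}") from exc
            raise TreeError(f"malformed Newick: {msg}") from exc
        tree = cls.__new__(cls)
        tree.dtree = dtree
        tree.rooted = len(dtree.seed_node.child_nodes()) == 2
        tree._absorb_support_labels()
        tree._validate()
        return tree

    def _absorb_support_labels(self) -> None:
        for node in self.dtree.preorder_node_iter():
            support = None
            if not node.is_leaf():
                raw = node.label
                if raw is None and node.comments:
                    raw = str(node.comments[0]).strip("[]& ")
                if raw is not None:
                    raw = str(raw).strip()
                    try:
                        support = float(raw)
                    except ValueError:
                        support = None
                    else:
                        node.label = None
                if support is not None:
                    # integers are percents (0-100); decimals <= 1 are
                    # already fractions
                    if "." not in raw or support > 1.0:
                        support = support / 100.0
                    if not (0.0 <= support <= 1.0):
                        raise TreeError(f"support value out of range: {raw}")
            node.comments = []
            if support is not None:
                node.support = support

    def _validate(self) -> None:
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for node in self.dtree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise TreeError(
                    f"negative branch length on edge above {node_name(node)}"
                )

    # -- basic queries -----------------------------------------------------
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def is_binary(self) -> bool:
        for node in self.dtree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                return False
        return True

    def has_branch_lengths(self) -> bool:
        return all(
            node.edge.length is not None
            for node in self.dtree.preorder_node_iter()
            if node.parent_node is not None
        )

    def copy(self) -> "PhyloTree":
        clone = self.dtree.clone(depth=1)
        for orig, new in zip(
            self.dtree.preorder_node_iter(), clone.preorder_node_iter()
        ):
            if hasattr(orig, "support"):
                new.support = orig.support
        out = PhyloTree.__new__(PhyloTree)
        out.dtree = clone
        out.rooted = self.rooted
        return out

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits, each as the canonical smaller side.

        A split is represented by the frozenset of tip labels on one side;
        the side chosen is the lexicographically smaller of (side,
        complement) after sorting, making representations comparable across
        differently rooted trees.
        """
        all_tips = frozenset(self.tip_labels())
        out: set[frozenset[str]] = set()
        n = len(all_tips)
        for node in self.dtree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            if 2 <= len(side) <= n - 2:
                out.add(_canonical_split(side, all_tips))
        return out

    def support_by_bipartition(self) -> dict[frozenset[str], float]:
        all_tips = frozenset(self.tip_labels())
        out: dict[frozenset[str], float] = {}
        for node in self.dtree.preorder_internal_node_iter():
            if node.parent_node is None or not hasattr(node, "support"):
                continue
            side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            out[_canonical_split(side, all_tips)] = node.support
        return out

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        return _write_node(self.dtree.seed_node) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {self.n_tips} tips rooted={self.rooted}>"


def _canonical_split(side: frozenset[str], all_tips: frozenset[str]):
    other = all_tips - side
    a, b = sorted(side), sorted(other)
    return side if (len(side), a) <= (len(other), b) else other


def node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return "<internal>"


def _fmt_number(x: float) -> str:
    s = format(x, ".10g")
    return s


def _fmt_support(s: float) -> str:
    pct = s * 100.0
    if abs(pct - round(pct)) < 1e-9:
        return str(int(round(pct)))  # integral percent, e.g. "90"
    return _fmt_number(s)  # otherwise the fraction itself, e.g. "0.755"


def _write_node(node: dendropy.Node) -> str:
    if node.is_leaf():
        body = node.taxon.label if node.taxon else (node.label or "")
    else:
        body = "(" + ",".join(_write_node(c) for c in node.child_nodes()) + ")"
        if hasattr(node, "support"):
            body += _fmt_support(node.support)
        elif node.label:
            body += node.label
    if node.edge.length is not None and node.parent_node is not None:
        body += ":" + _fmt_number(node.edge.length)
    return body


# -- module-level operations ----------------------------------------------

def read_newick(path) -> PhyloTree:
    """Read one Newick tree from ``path``."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise TreeError(f"empty Newick file: {path}")
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Tip-to-tip path-length distances."""
    if not tree.has_branch_lengths():
        raise TreeError("patristic distances need branch lengths on all edges")
    leaves = list(tree.dtree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    # root-to-node depths plus LCA via per-leaf ancestor paths
    depth: dict[int, float] = {}
    parent: dict[int, dendropy.Node] = {}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    ancestors = []
    for lf in leaves:
        path = set()
        node = lf
        while node is not None:
            path.add(id(node))
            node = node.parent_node
        ancestors.append(path)
    node_by_id = {
        id(node): node for node in tree.dtree.preorder_node_iter()
    }
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ancestors[i] & ancestors[j]
            lca_depth = max(depth[k] for k in shared)
            d = depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * lca_depth
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, matrix=mat)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest tip-to-tip path.

    Patristic distances are preserved; support values are re-attached to
    the same unrooted bipartitions they described before rerooting.
    """
    if not tree.has_branch_lengths():
        raise TreeError("midpoint rooting needs branch lengths")
    out = tree.copy()
    supports = out.support_by_bipartition()
    dt = out.dtree
    leaves = list(dt.leaf_node_iter())
    depth: dict[int, float] = {}
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    # longest tip-to-tip path (first pair in leaf order on ties)
    best = (-1.0, None, None)
    for i, a in enumerate(leaves):
        anc_a = {id(x) for x in ancestors(a)}
        for b in leaves[i + 1:]:
            lca = next(x for x in ancestors(b) if id(x) in anc_a)
            d = depth[id(a)] + depth[id(b)] - 2 * depth[id(lca)]
            if d > best[0] + 1e-15:
                best = (d, a, b)
    diameter, a, b = best
    if diameter <= 0:
        out.rooted = True
        return out
    anc_a = {id(x) for x in ancestors(a)}
    lca = next(x for x in ancestors(b) if id(x) in anc_a)
    up = []  # edges from a to lca, each (child node, length)
    node = a
    while node is not lca:
        up.append(node)
        node = node.parent_node
    down = []  # from lca toward b
    node = b
    while node is not lca:
        down.append(node)
        node = node.parent_node
    down.reverse()
    target = diameter / 2.0
    cum = 0.0
    split = None  # (edge child node, dist from head/lower node)
    for node in up:
        if cum + node.edge.length >= target - 1e-12:
            split = (node, target - cum)
            break
        cum += node.edge.length
    if split is None:
        for node in down:
            # walking tail -> head on the b side
            if cum + node.edge.length >= target - 1e-12:
                split = (node, node.edge.length - (target - cum))
                break
            cum += node.edge.length
    child, from_child = split
    length = child.edge.length
    from_child = min(max(from_child, 0.0), length)
    if from_child <= 1e-12 and child.is_leaf() is False:
        dt.reseed_at(child, update_bipartitions=False,
                     collapse_unrooted_basal_bifurcation=False)
        dt.suppress_unifurcations()
    else:
        # dendropy: length1 -> tail side, length2 -> head (child) side
        dt.reroot_at_edge(child.edge, length1=length - from_child,
                          length2=from_child, update_bipartitions=False)
        dt.suppress_unifurcations()
    dt.seed_node.edge.length = None
    _reapply_supports(out, supports)
    out.rooted = True
    return out


def outgroup_root(tree: PhyloTree, outgroup_tips: Sequence[str]) -> PhyloTree:
    """Root on the edge separating the outgroup tips from the ingroup.

    The root is placed halfway along that edge.  Raises ``TreeError`` when
    the outgroup does not form one side of any edge (i.e. is not
    monophyletic in the unrooted sense), naming the offending split.
    """
    og = frozenset(outgroup_tips)
    all_tips = frozenset(tree.tip_labels())
    missing = og - all_tips
    if missing:
        raise TreeError(f"outgroup tips not in tree: {sorted(missing)}")
    if not og or og == all_tips:
        raise TreeError("outgroup must be a proper non-empty tip subset")
    out = tree.copy()
    supports = out.support_by_bipartition()
    target = None
    for node in out.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if side == og or side == all_tips - og:
            target = node
            break
    if target is None:
        raise TreeError(
            f"outgroup {sorted(og)} is not monophyletic: no edge separates "
            f"it from the ingroup {sorted(all_tips - og)}"
        )
    edge = target.edge
    length = edge.length
    if length is not None:
        out.dtree.reroot_at_edge(edge, length1=length / 2.0,
                                 length2=length / 2.0,
                                 update_bipartitions=False)
    else:
        out.dtree.reroot_at_edge(edge, update_bipartitions=False)
    out.dtree.seed_node.edge.length = None
    _reapply_supports(out, supports)
    out.rooted = True
    return out


def _reapply_supports(tree: PhyloTree, supports: Mapping[frozenset, float]):
    all_tips = frozenset(tree.tip_labels())
    for node in tree.dtree.preorder_node_iter():
        if hasattr(node, "support"):
            del node.support
    for node in tree.dtree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        key = _canonical_split(side, all_tips)
        if key in supports:
            node.support = supports[key]


def prune_one_per_species(
    tree: PhyloTree,
    species_of: Mapping[str, str],
    ungapped_lengths: Mapping[str, int] | None = None,
) -> PhyloTree:
    """Keep exactly one tip per species.

    The representative is the tip with the longest ungapped sequence when
    ``ungapped_lengths`` is supplied, ties (and the no-lengths case) broken
    lexicographically by tip id.  Degree-2 nodes left by pruning are
    suppressed with their branch lengths summed, so patristic distances
    among the retained tips are unchanged.
    """
    tips = tree.tip_labels()
    unmapped = [t for t in tips if t not in species_of]
    if unmapped:
        raise TreeError(f"tips with no species mapping: {sorted(unmapped)}")
    by_species: dict[str, list[str]] = {}
    for t in tips:
        by_species.setdefault(species_of[t], []).append(t)

    def rank(tip: str):
        length = (ungapped_lengths or {}).get(tip, 0)
        return (-length, tip)

    keep = {min(members, key=rank) for members in by_species.values()}
    if keep == set(tips):
        return tree.copy()
    out = tree.copy()
    supports = out.support_by_bipartition()
    out.dtree.retain_taxa_with_labels(sorted(keep))
    out.dtree.purge_taxon_namespace()
    root = out.dtree.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        out.dtree.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    _reapply_supports(out, supports)
    out.rooted = len(out.dtree.seed_node.child_nodes()) == 2
    return out


def rename_tips(tree: PhyloTree, mapping: Mapping[str, str]) -> PhyloTree:
    """Return a copy with tip labels substituted via ``mapping``."""
    out = tree.copy()
    for leaf in out.dtree.leaf_node_iter():
        if leaf.taxon.label in mapping:
            leaf.taxon.label = mapping[leaf.taxon.label]
    out._validate()
    return out


def build_tree(newick: str) -> PhyloTree:
    """Shorthand used by tests and examples."""
    return PhyloTree.from_newick(newick)
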