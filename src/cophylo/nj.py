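"""Neighbour-joining tree inference and nonparametric bootstrap support.

Classic Saitou-Nei agglomeration on a distance matrix.  Determinism rules:
ties in the Q criterion are broken by the lexicographically smallest pair
of cluster names (a cluster is named by its smallest member tip); negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling edge so the joined pair's distance is preserved.
"""

from __future__ import annotations

import logging
import warnings

import dendropy
import numpy as np

from .alignment import Alignment
from .distance import DistanceMatrix, k2p_distance
from .errors import DistanceError, TreeError
from .tree import PhyloTree

logger = logging.getLogger(__name__)


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Neighbour-joining tree from a distance matrix.

    Returns an unrooted tree (basal trifurcation) for >= 3 labels, a
    single-edge two-tip tree for 2 labels.
    """
    if np.any(np.isnan(D.matrix)):
        raise DistanceError("NJ input contains NaN")
    n = len(D.labels)
    if n < 2:
        raise DistanceError("NJ needs at least 2 labels")

    taxa = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for label in D.labels:
        taxon = taxa.new_taxon(label)
        nodes[label] = dendropy.Node(taxon=taxon)

    if n == 2:
        a, b = D.labels
        root = dendropy.Node()
        root.add_child(nodes[a])
        root.add_child(nodes[b])
        d = float(D.matrix[0, 1])
        nodes[a].edge.length = d / 2.0
        nodes[b].edge.length = d / 2.0
        dtree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        return PhyloTree(dtree, rooted=False)

    # active clusters: name -> (node, matrix index); name = smallest tip
    dist = {}
    active = {}
    for i, a in enumerate(D.labels):
        active[a] = nodes[a]
        for j, b in enumerate(D.labels):
            if i < j:
                dist[frozenset((a, b))] = float(D.matrix[i, j])

    def d_of(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        names = sorted(active)
        m = len(names)
        r = {a: sum(d_of(a, b) for b in names if b != a) for a in names}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = names[ii], names[jj]
                q = (m - 2) * d_of(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d_of(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        # clamp negatives, moving the deficit to the sibling edge
        if la < 0.0:
            lb += la
            la = 0.0
        if lb < 0.0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)  # also normalizes -0.0
        new = dendropy.Node()
        new.add_child(active[a])
        new.add_child(active[b])
        active[a].edge.length = la
        active[b].edge.length = lb
        for c in names:
            if c in (a, b):
                continue
            dist[frozenset((min(a, b), c))] = 0.5 * (
                d_of(a, c) + d_of(b, c) - dab
            )
        del active[max(a, b)]
        for c in list(dist):
            if max(a, b) in c:
                del dist[c]
        active[min(a, b)] = new

    names = sorted(active)
    root = dendropy.Node()
    if len(names) == 3:
        a, b, c = names
        la = 0.5 * (d_of(a, b) + d_of(a, c) - d_of(b, c))
        lb = 0.5 * (d_of(a, b) + d_of(b, c) - d_of(a, c))
        lc = 0.5 * (d_of(a, c) + d_of(b, c) - d_of(a, b))
        for name, ln in zip((a, b, c), (la, lb, lc)):
            root.add_child(active[name])
            active[name].edge.length = max(ln, 0.0)
    else:  # two clusters remain (possible when n == 3 never; defensive)
        a, b = names
        root.add_child(active[a])
        root.add_child(active[b])
        active[a].edge.length = d_of(a, b) / 2.0
        active[b].edge.length = d_of(a, b) / 2.0
    dtree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    return PhyloTree(dtree, rooted=False)


def bootstrap_support(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    min_length: int | None = None,
) -> PhyloTree:
    """NJ tree from ``aln`` with bootstrap support on internal edges.

    Sites are resampled with replacement ``n_reps`` times; support of each
    internal edge of the full-data tree is the fraction of replicate trees
    containing the same unrooted bipartition.  One pseudo-random stream is
    consumed replicate by replicate, so the first k replicates of a longer
    run coincide with a shorter run under the same seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(k2p_distance(aln))
    if len(aln) < 4:
        warnings.warn(
            "bootstrap support undefined for fewer than 4 sequences; "
            "returning tree without support",
            stacklevel=2,
        )
        return tree
    all_tips = frozenset(aln.ids)
    targets = tree.bipartitions()
    counts = {split: 0 for split in targets}
    rng = np.random.default_rng(seed)
    chars = aln.to_array()
    n_sites = aln.n_sites
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        resampled = Alignment(
            ids=list(aln.ids),
            matrix=["".join(row) for row in chars[:, cols]],
        )
        try:
            with warnings.catch_warnings():
                # saturation in individual replicates is routine
                warnings.simplefilter("ignore", UserWarning)
                rep_tree = nj_tree(k2p_distance(resampled))
        except DistanceError:
            continue  # replicate with an incomparable pair: counts no split
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1
    for node in tree.dtree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        from .tree import _canonical_split

        key = _canonical_split(side, all_tips)
        if key in counts:
            node.support = counts[key] / n_reps
    return tree
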