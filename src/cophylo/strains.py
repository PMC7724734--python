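"""Endosymbiont strain typing from a bootstrap-supported marker tree.

Study sequences are clustered into putative strains by clade support:
maximal study-only clades whose subtending edge reaches the primary
support threshold (default 0.97) become strains; sequences left over are
merged with the members of their smallest enclosing study-only clade when
that clade reaches the secondary threshold (default 0.90), and otherwise
become singleton strains.  Strains are then assigned to supergroups (A/B)
from labelled reference tips, and classified as specialists (one host
species) or generalists (two or more).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .errors import TreeError
from .tables import AssociationMatrix
from .tree import PhyloTree

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UC"


@dataclass
class StrainAssignment:
    """Strain typing result.

    Attributes
    ----------
    strain_of : dict
        sequence id -> strain label ("Wol 1", "Wol 2", ...).
    supergroup_of : dict
        strain -> "A" / "B" / "UC" (filled by :func:`assign_supergroup`).
    hosts_of : dict
        strain -> set of host species (filled by
        :func:`classify_specificity`).
    class_of : dict
        strain -> "specialist" / "generalist".
    """

    strain_of: dict[str, str]
    supergroup_of: dict[str, str] = field(default_factory=dict)
    hosts_of: dict[str, set] = field(default_factory=dict)
    class_of: dict[str, str] = field(default_factory=dict)

    def members(self, strain: str) -> list[str]:
        return sorted(s for s, k in self.strain_of.items() if k == strain)

    @property
    def strains(self) -> list[str]:
        seen: list[str] = []
        for k in self.strain_of.values():
            if k not in seen:
                seen.append(k)
        return sorted(seen, key=_strain_sort_key)


def _strain_sort_key(label: str):
    head, _, num = label.rpartition(" ")
    return (head, int(num)) if num.isdigit() else (label, 0)


def _study_tips(tree: PhyloTree, is_study) -> set[str]:
    return {t for t in tree.tip_labels() if is_study(t)}


def cluster_strains(
    tree: PhyloTree,
    is_study,
    primary_threshold: float = 0.97,
    secondary_threshold: float = 0.90,
    strain_prefix: str = "Wol",
) -> StrainAssignment:
    """Partition study sequences into putative strains by clade support.

    Parameters
    ----------
    tree : PhyloTree
        Supported tree (typically midpoint rooted) containing study and
        reference tips.
    is_study : callable
        Predicate on tip labels separating study sequences from
        references.
    primary_threshold, secondary_threshold : float
        Support fractions for the main clustering rule and the fallback
        merge rule.

    Strains are numbered by preorder traversal order of the tree, so
    numbering is deterministic for a fixed (rooted) input tree.
    """
    has_support = any(
        hasattr(node, "support")
        for node in tree.dtree.preorder_internal_node_iter()
    )
    if not has_support:
        n_internal = sum(
            1 for n in tree.dtree.preorder_internal_node_iter()
            if n.parent_node is not None
        )
        if n_internal:
            raise TreeError("tree has no support values; run bootstrap first")
    study = _study_tips(tree, is_study)
    if not study:
        raise TreeError("no study sequences on the tree")

    assigned: dict[str, int] = {}
    blocks: list[list[str]] = []

    def clade_tips(node) -> list[str]:
        return [leaf.taxon.label for leaf in node.leaf_iter()]

    def support(node) -> float:
        return getattr(node, "support", 0.0)

    # pass 1: maximal study-only clades at the primary threshold, preorder
    def walk(node) -> None:
        tips = clade_tips(node)
        study_only = all(t in study for t in tips)
        if (
            study_only
            and not node.is_leaf()
            and node.parent_node is not None
            and support(node) >= primary_threshold
        ):
            block = [t for t in tips if t not in assigned]
            if block:
                for t in block:
                    assigned[t] = len(blocks)
                blocks.append(block)
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.dtree.seed_node)

    # pass 2: fallback merge for uncaptured study sequences, preorder
    for leaf in tree.dtree.leaf_node_iter():
        t = leaf.taxon.label
        if t not in study or t in assigned:
            continue
        node = leaf.parent_node
        enclosing = None
        while node is not None:
            if all(x in study for x in clade_tips(node)):
                enclosing = node
                break
            node = node.parent_node
        if enclosing is not None and support(enclosing) >= secondary_threshold:
            block = [x for x in clade_tips(enclosing) if x not in assigned]
            for x in block:
                assigned[x] = len(blocks)
            blocks.append(block)
        else:
            assigned[t] = len(blocks)
            blocks.append([t])

    # number blocks by first appearance in preorder tip order
    order: dict[int, int] = {}
    for leaf in tree.dtree.leaf_node_iter():
        t = leaf.taxon.label
        if t in assigned and assigned[t] not in order:
            order[assigned[t]] = len(order) + 1
    strain_of = {
        t: f"{strain_prefix} {order[b]}" for t, b in assigned.items()
    }
    return StrainAssignment(strain_of=strain_of)


def assign_supergroup(
    assignment: StrainAssignment,
    tree: PhyloTree,
    references: Mapping[str, str],
    min_classifiable_length: int = 400,
    ungapped_lengths: Mapping[str, int] | None = None,
    overrides: Mapping[str, str] | None = None,
) -> StrainAssignment:
    """Label each strain with the supergroup of its nearest references.

    A strain inherits supergroup X when the smallest clade that contains
    any of its members together with at least one reference tip contains
    references of supergroup X only.  Strains whose members are all
    shorter than ``min_classifiable_length`` ungapped sites are
    unclassified (``UC``), as are strains whose nearest references mix
    supergroups (with a warning).  ``overrides`` forces labels for named
    strains (the manual escape hatch for alignment-problem cases).
    """
    if not references:
        raise TreeError("no labelled reference tips supplied")
    tips = set(tree.tip_labels())
    missing = [r for r in references if r not in tips]
    if missing:
        raise TreeError(f"reference tips not on tree: {sorted(missing)}")

    leaf_by_label = {
        leaf.taxon.label: leaf for leaf in tree.dtree.leaf_node_iter()
    }
    for strain in assignment.strains:
        if overrides and strain in overrides:
            assignment.supergroup_of[strain] = overrides[strain]
            continue
        members = assignment.members(strain)
        if ungapped_lengths is not None and all(
            ungapped_lengths.get(m, 0) < min_classifiable_length
            for m in members
        ):
            assignment.supergroup_of[strain] = UNCLASSIFIED
            continue
        labels: set[str] = set()
        node = leaf_by_label[members[0]]
        while node is not None:
            clade = {leaf.taxon.label for leaf in node.leaf_iter()}
            refs_here = clade & references.keys()
            if refs_here:
                labels = {references[r] for r in refs_here}
                break
            node = node.parent_node
        if len(labels) == 1:
            assignment.supergroup_of[strain] = labels.pop()
        else:
            assignment.supergroup_of[strain] = UNCLASSIFIED
            warnings.warn(
                f"strain {strain}: nearest reference clade mixes "
                f"supergroups {sorted(labels)}; marked {UNCLASSIFIED}",
                stacklevel=2,
            )
    return assignment


def classify_specificity(
    assignment: StrainAssignment, assoc: AssociationMatrix
) -> StrainAssignment:
    """Mark each strain specialist (one host species) or generalist (>= 2)."""
    for strain in assignment.strains:
        if strain not in assoc.strains:
            raise KeyError(f"strain {strain!r} absent from association matrix")
        hosts = set(assoc.hosts_of(strain))
        assignment.hosts_of[strain] = hosts
        assignment.class_of[strain] = (
            "specialist" if len(hosts) == 1 else "generalist"
        )
    return assignment
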