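"""Event-based cophylogeny reconciliation.

A symbiont tree is mapped onto a host tree under five event types:
cospeciation (host and symbiont speciate together), duplication (symbiont
speciates within a host lineage), duplication with host shift (one
daughter colonizes an incomparable host lineage), loss (the symbiont
fails to establish in one daughter after a host speciation), and failure
to diverge (the host speciates while a single symbiont lineage persists
in both daughters).  The reconstruction minimizes the total event cost
under a :class:`CostScheme` (default 0, 1, 2, 1, 1).

Reconciliation is untimed: a host shift may land on any host lineage that
is neither an ancestor nor a descendant of the source, which rules out
single-event time paradoxes.  Failure to diverge arises only from
symbiont tips observed in more than one host: such a tip is expanded to
cover the spanning host subtree of its hosts, charging one failure to
diverge per covered host speciation and one loss per pruned side.

Three solvers share these semantics: an exact dynamic program over
(symbiont node, host node) states, a pure brute-force enumerator over
placement mappings (the independent oracle), and a population-based
genetic search for instances where enumeration is hopeless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ReconciliationError
from .tables import AssociationMatrix
from .tree import PhyloTree

INF = float("inf")

EVENT_TYPES = (
    "cospeciation",
    "duplication",
    "host_shift",
    "loss",
    "failure_to_diverge",
)


@dataclass(frozen=True)
class CostScheme:
    """Per-event costs; the default mirrors the usual 0/1/2/1/1 regime."""

    cospeciation: float = 0.0
    duplication: float = 1.0
    host_shift: float = 2.0
    loss: float = 1.0
    failure_to_diverge: float = 1.0

    def __post_init__(self) -> None:
        for name in EVENT_TYPES:
            if getattr(self, name) < 0:
                raise ValueError(f"negative cost for {name}")

    def cost_of(self, event: str) -> float:
        return getattr(self, event)

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, e) for e in EVENT_TYPES)


def total_cost(counts: Mapping[str, int], scheme: CostScheme) -> float:
    """Weighted sum of event counts under ``scheme``."""
    unknown = set(counts) - set(EVENT_TYPES)
    if unknown:
        raise KeyError(f"unknown event types: {sorted(unknown)}")
    for event, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {event}")
    return float(sum(scheme.cost_of(e) * n for e, n in counts.items()))


@dataclass
class Reconciliation:
    """A reconciliation: placements, event list, counts, and total cost."""

    placements: dict[str, str]
    events: list[tuple[str, str, str]]  # (event, symbiont node, host node)
    counts: dict[str, int]
    total_cost: float
    optimal: bool
    scheme: CostScheme

    def __post_init__(self) -> None:
        implied = total_cost(self.counts, self.scheme)
        if abs(implied - self.total_cost) > 1e-9:
            raise ReconciliationError(
                f"event counts imply cost {implied}, solver reported "
                f"{self.total_cost}"
            )

    def summary(self) -> str:
        parts = ", ".join(
            f"{e.replace('_', ' ')}: {self.counts.get(e, 0)}"
            for e in EVENT_TYPES
        )
        tag = "exact" if self.optimal else "heuristic"
        return f"[{tag}] {parts}; total cost {self.total_cost:g}"


# -- indexed tree ----------------------------------------------------------


class _IndexedTree:
    """Rooted binary tree flattened to arrays, postorder-indexed."""

    def __init__(self, tree: PhyloTree, name: str):
        if not tree.rooted and tree.n_tips > 1:
            raise ReconciliationError(f"{name} tree must be rooted")
        if not tree.is_binary():
            raise ReconciliationError(f"{name} tree must be binary")
        nodes = list(tree.dtree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.n = len(nodes)
        self.children: list[tuple[int, int] | None] = []
        self.parent = [-1] * self.n
        self.label: list[str] = []
        self.is_leaf = []
        for i, node in enumerate(nodes):
            kids = node.child_nodes()
            if kids:
                ci = (self.index[id(kids[0])], self.index[id(kids[1])])
                self.children.append(ci)
                for c in ci:
                    self.parent[c] = i
                self.is_leaf.append(False)
                self.label.append(node.label or f"{name}_n{i}")
            else:
                self.children.append(None)
                self.is_leaf.append(True)
                self.label.append(node.taxon.label)
        self.root = self.n - 1
        # ancestor-or-self matrix and edge depths
        self.anc = np.zeros((self.n, self.n), dtype=bool)
        self.depth = np.zeros(self.n, dtype=int)
        for i in range(self.n - 1, -1, -1):  # preorder over postorder idx
            self.anc[i, i] = True
            if self.children[i]:
                for c in self.children[i]:
                    self.depth[c] = self.depth[i] + 1
        for i in range(self.n):
            j = i
            while self.parent[j] != -1:
                j = self.parent[j]
                self.anc[j, i] = True
        self.leaf_index = {
            self.label[i]: i for i in range(self.n) if self.is_leaf[i]
        }
        self.postorder = list(range(self.n))

    def incomparable(self, a: int, b: int) -> bool:
        return not (self.anc[a, b] or self.anc[b, a])

    def mrca(self, idxs: Sequence[int]) -> int:
        best = None
        for i in range(self.n):
            if all(self.anc[i, j] for j in idxs):
                if best is None or self.depth[i] > self.depth[best]:
                    best = i
        return best


def _expand_tip(host: _IndexedTree, host_idxs: list[int]):
    """Placement and intrinsic events for a (possibly multi-host) tip.

    Returns ``(mrca, events)`` where events are (type, host index) pairs:
    one failure-to-diverge per spanning-subtree node with both children
    covered, one loss per node with a single covered child.
    """
    if len(host_idxs) == 1:
        return host_idxs[0], []
    m = host.mrca(host_idxs)
    covered = set(host_idxs)
    for h in host_idxs:
        j = h
        while j != m:
            j = host.parent[j]
            covered.add(j)
    events = []
    for u in sorted(covered, key=lambda x: -host.depth[x]):
        if host.is_leaf[u]:
            continue
        kids = host.children[u]
        k_in = sum(1 for c in kids if c in covered)
        if k_in == 2:
            events.append(("failure_to_diverge", u))
        elif k_in == 1:
            events.append(("loss", u))
    return m, events


class _Instance:
    """Shared pre-processing for all three solvers."""

    def __init__(self, host: PhyloTree, symb: PhyloTree,
                 assoc: AssociationMatrix, scheme: CostScheme):
        self.host = _IndexedTree(host, "host")
        self.symb = _IndexedTree(symb, "symbiont")
        self.scheme = scheme
        missing_hosts = [h for h in assoc.hosts
                         if h not in self.host.leaf_index]
        if missing_hosts:
            raise ReconciliationError(
                f"association hosts not on host tree: {missing_hosts}"
            )
        self.tip_place: dict[int, int] = {}
        self.tip_events: dict[int, list] = {}
        for i in range(self.symb.n):
            if not self.symb.is_leaf[i]:
                continue
            label = self.symb.label[i]
            if label not in assoc.strains:
                raise ReconciliationError(
                    f"symbiont tip {label!r} absent from association"
                )
            hosts = assoc.hosts_of(label)
            if not hosts:
                raise ReconciliationError(
                    f"symbiont tip {label!r} has no host"
                )
            idxs = [self.host.leaf_index[h] for h in hosts]
            place, events = _expand_tip(self.host, idxs)
            self.tip_place[i] = place
            self.tip_events[i] = events

    def tip_base_cost(self, i: int) -> float:
        return sum(self.scheme.cost_of(e) for e, _ in self.tip_events[i])

    def internal_nodes(self) -> list[int]:
        return [i for i in self.symb.postorder if not self.symb.is_leaf[i]]

    # -- mapping evaluation (used by brute force and the heuristic) -------
    def mapping_events(self, mapping: Mapping[int, int]):
        """Events implied by a full placement mapping, or None if infeasible.

        ``mapping`` assigns a host node to every internal symbiont node;
        tips sit at their fixed placements.  Each internal node greedily
        takes its cheapest locally feasible event, which is exact because
        the per-node choices are independent given the mapping.
        """
        host, symb, scheme = self.host, self.symb, self.scheme

        def place(i: int) -> int:
            return self.tip_place[i] if symb.is_leaf[i] else mapping[i]

        events: list[tuple[str, int, int]] = []  # (type, symb node, host)
        for i, evs in self.tip_events.items():
            events.extend((e, i, h) for e, h in evs)
        total = 0.0
        for p in self.internal_nodes():
            hp = place(p)
            c1, c2 = symb.children[p]
            h1, h2 = place(c1), place(c2)
            best = None
            # cospeciation: children descend opposite sides of hp
            if not host.is_leaf[hp]:
                ka, kb = host.children[hp]
                for (x, cx), (y, cy) in (((h1, c1), (h2, c2)),
                                         ((h2, c2), (h1, c1))):
                    if host.anc[ka, x] and host.anc[kb, y]:
                        losses = (host.depth[x] - host.depth[ka]
                                  + host.depth[y] - host.depth[kb])
                        cost = scheme.cospeciation + scheme.loss * losses
                        cand = (cost, "cospeciation", losses,
                                ((cx, ka, x), (cy, kb, y)))
                        if best is None or cand[0] < best[0]:
                            best = cand
            # duplication: both children descend from hp itself
            if host.anc[hp, h1] and host.anc[hp, h2]:
                losses = (host.depth[h1] - host.depth[hp]
                          + host.depth[h2] - host.depth[hp])
                cost = scheme.duplication + scheme.loss * losses
                cand = (cost, "duplication", losses,
                        ((c1, hp, h1), (c2, hp, h2)))
                if best is None or cand[0] < best[0]:
                    best = cand
            # host shift: one child stays under hp, the other jumps to an
            # incomparable lineage
            for stay, stay_c, move, move_c in ((h1, c1, h2, c2),
                                               (h2, c2, h1, c1)):
                if host.anc[hp, stay] and host.incomparable(hp, move):
                    losses = host.depth[stay] - host.depth[hp]
                    cost = scheme.host_shift + scheme.loss * losses
                    cand = (cost, "host_shift", losses,
                            ((stay_c, hp, stay),))
                    if best is None or cand[0] < best[0]:
                        best = cand
            if best is None:
                return None, INF
            cost, event, _, descents = best
            events.append((event, p, hp))
            for child, top, bottom in descents:
                j = bottom
                path = []
                while j != top:
                    path.append(host.parent[j])
                    j = host.parent[j]
                for u in path:
                    events.append(("loss", child, u))
            total += cost
        total += sum(self.tip_base_cost(i) for i in self.tip_place)
        return events, total

    def package(self, events, cost, optimal) -> Reconciliation:
        counts = {e: 0 for e in EVENT_TYPES}
        placements = {}
        for event, snode, hnode in events:
            counts[event] += 1
        # placements: internal nodes recorded by the caller via events of
        # non-loss type; tips from the expansion
        for event, snode, hnode in events:
            if event in ("cospeciation", "duplication", "host_shift"):
                placements[self.symb.label[snode]] = self.host.label[hnode]
        for i, h in self.tip_place.items():
            placements[self.symb.label[i]] = self.host.label[h]
        named = [
            (e, self.symb.label[s], self.host.label[h])
            for e, s, h in events
        ]
        counts = {e: n for e, n in counts.items()}
        return Reconciliation(
            placements=placements,
            events=named,
            counts=counts,
            total_cost=float(cost),
            optimal=optimal,
            scheme=self.scheme,
        )


# -- exact dynamic program -------------------------------------------------


def _solve_dp(inst: _Instance):
    host, symb, scheme = inst.host, inst.symb, inst.scheme
    H, S = host.n, symb.n
    c = np.full((S, H), INF)
    in_ = np.full((S, H), INF)
    out = np.full((S, H), INF)
    choice: dict[tuple[int, int], tuple] = {}
    in_choice: dict[tuple[int, int], int] = {}
    out_choice: dict[tuple[int, int], int] = {}

    for p in symb.postorder:
        if symb.is_leaf[p]:
            c[p, inst.tip_place[p]] = inst.tip_base_cost(p)
        else:
            p1, p2 = symb.children[p]
            for h in host.postorder:
                best = (INF, None)
                if not host.is_leaf[h]:
                    k1, k2 = host.children[h]
                    for a, b in ((k1, k2), (k2, k1)):
                        v = (scheme.cospeciation
                             + in_[p1, a] + in_[p2, b])
                        if v < best[0]:
                            best = (v, ("cospeciation", (p1, a), (p2, b)))
                v = scheme.duplication + in_[p1, h] + in_[p2, h]
                if v < best[0]:
                    best = (v, ("duplication", (p1, h), (p2, h)))
                for stay, move in ((p1, p2), (p2, p1)):
                    v = scheme.host_shift + in_[stay, h] + out[move, h]
                    if v < best[0]:
                        best = (v, ("host_shift", (stay, h), (move, h)))
                c[p, h] = best[0]
                if best[1] is not None:
                    choice[(p, h)] = best[1]
        # in_: cheapest placement at-or-below h, charging losses per edge
        for h in host.postorder:
            best_v, best_h = c[p, h], h
            if not host.is_leaf[h]:
                for k in host.children[h]:
                    v = in_[p, k] + scheme.loss
                    if v < best_v:
                        best_v, best_h = v, in_choice.get((p, k), k)
            in_[p, h] = best_v
            in_choice[(p, h)] = best_h
        # out: cheapest placement on a lineage incomparable with h
        for h in host.postorder:
            best_v, best_h = INF, None
            for h2 in host.postorder:
                if host.incomparable(h, h2) and c[p, h2] < best_v:
                    best_v, best_h = c[p, h2], h2
            out[p, h] = best_v
            if best_h is not None:
                out_choice[(p, h)] = best_h

    root = symb.root
    h_opt = int(np.argmin(c[root]))
    best_cost = c[root, h_opt]
    if not np.isfinite(best_cost):
        raise ReconciliationError("no feasible reconciliation")

    events: list[tuple[str, int, int]] = []
    for i, evs in inst.tip_events.items():
        events.extend((e, i, h) for e, h in evs)

    def descend(p: int, top: int) -> int:
        """Resolve an in-chain: losses from ``top`` down to c-placement."""
        bottom = in_choice[(p, top)]
        j = bottom
        while j != top:
            events.append(("loss", p, host.parent[j]))
            j = host.parent[j]
        return bottom

    def backtrack(p: int, h: int) -> None:
        if symb.is_leaf[p]:
            return
        event, (pa, ha), (pb, hb) = choice[(p, h)]
        events.append((event, p, h))
        if event == "host_shift":
            stay_h = descend(pa, ha)
            move_h = out_choice[(pb, hb)]
            backtrack(pa, stay_h)
            backtrack(pb, move_h)
        else:
            a = descend(pa, ha)
            b = descend(pb, hb)
            backtrack(pa, a)
            backtrack(pb, b)

    backtrack(root, h_opt)
    return events, float(best_cost)


# -- brute-force oracle ----------------------------------------------------


def brute_force_reconcile(
    host: PhyloTree,
    symb: PhyloTree,
    assoc: AssociationMatrix,
    scheme: CostScheme = CostScheme(),
) -> Reconciliation:
    """Exhaustive minimum over all placement mappings.

    Enumerates every assignment of internal symbiont nodes to host nodes
    and scores each directly — no dynamic programming — so it serves as an
    independent oracle for :func:`reconcile`.  Exponential in the symbiont
    tree size; intended for small instances only.
    """
    inst = _Instance(host, symb, assoc, scheme)
    internal = inst.internal_nodes()
    best = None
    for combo in itertools.product(range(inst.host.n), repeat=len(internal)):
        mapping = dict(zip(internal, combo))
        events, cost = inst.mapping_events(mapping)
        if events is not None and (best is None or cost < best[1]):
            best = (events, cost)
    if best is None:
        raise ReconciliationError("no feasible reconciliation")
    return inst.package(best[0], best[1], optimal=True)


# -- heuristic genetic search ----------------------------------------------


def _solve_heuristic(inst: _Instance, generations: int, population: int,
                     seed: int):
    rng = np.random.default_rng(seed)
    internal = inst.internal_nodes()
    n_genes = len(internal)
    H = inst.host.n
    if n_genes == 0:
        tip = next(iter(inst.tip_place))
        events, cost = inst.mapping_events({})
        return events, cost

    def score(chrom) -> float:
        _, cost = inst.mapping_events(dict(zip(internal, chrom)))
        return cost

    pop = rng.integers(0, H, size=(population, n_genes))
    pop[0, :] = inst.host.root  # always-feasible seed candidate
    fitness = np.array([score(ch) for ch in pop])
    n_elite = max(1, population // 10)
    for _ in range(generations):
        order = np.argsort(fitness, kind="stable")
        pop = pop[order]
        fitness = fitness[order]
        new_pop = [pop[i].copy() for i in range(n_elite)]
        while len(new_pop) < population:
            # tournament selection, uniform crossover, point mutation
            i1, i2 = rng.integers(0, population, size=2)
            p1 = pop[min(i1, i2)]
            i3, i4 = rng.integers(0, population, size=2)
            p2 = pop[min(i3, i4)]
            mask = rng.random(n_genes) < 0.5
            child = np.where(mask, p1, p2)
            mut = rng.random(n_genes) < (1.0 / n_genes)
            child[mut] = rng.integers(0, H, size=int(mut.sum()))
            new_pop.append(child)
        pop = np.array(new_pop)
        fitness = np.array([score(ch) for ch in pop])
    best = int(np.argmin(fitness))
    events, cost = inst.mapping_events(dict(zip(internal, pop[best])))
    return events, cost


# -- public API ------------------------------------------------------------


def reconcile(
    host: PhyloTree,
    symb: PhyloTree,
    assoc: AssociationMatrix,
    scheme: CostScheme = CostScheme(),
    mode: str = "exact",
    generations: int = 100,
    population: int = 300,
    seed: int = 0,
) -> Reconciliation:
    """Least-cost reconciliation of ``symb`` onto ``host``.

    ``mode="exact"`` runs the dynamic program over (symbiont node, host
    node) states and returns a provably minimal-cost reconciliation;
    ``mode="heuristic"`` runs the genetic search (``population``
    candidates, ``generations`` rounds, 10% elitism) and returns the best
    found with ``optimal=False``.
    """
    inst = _Instance(host, symb, assoc, scheme)
    if mode == "exact":
        events, cost = _solve_dp(inst)
        return inst.package(events, cost, optimal=True)
    if mode == "heuristic":
        events, cost = _solve_heuristic(inst, generations, population, seed)
        if events is None:
            raise ReconciliationError("heuristic found no feasible solution")
        return inst.package(events, cost, optimal=False)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class RandomTipMappingResult:
    """Randomization test of the observed reconciliation cost."""

    observed_cost: float
    random_costs: list[float]
    fraction_lower: float
    n_iter: int
    seed: int

    def supports_cospeciation(self, alpha: float = 0.05) -> bool:
        """True when at most ``alpha`` of random mappings beat the observed
        cost (the conventional support criterion)."""
        return self.fraction_lower <= alpha


def random_tip_mapping_test(
    host: PhyloTree,
    symb: PhyloTree,
    assoc: AssociationMatrix,
    scheme: CostScheme = CostScheme(),
    n_iter: int = 50,
    seed: int = 0,
    mode: str = "exact",
) -> RandomTipMappingResult:
    """Compare the observed cost with costs under randomized associations.

    Each iteration redraws every symbiont tip's host set (same size,
    hosts sampled uniformly without replacement) and reconciles.  Returns
    the fraction of randomized mappings with strictly lower cost.
    """
    observed = reconcile(host, symb, assoc, scheme, mode=mode, seed=seed)
    rng = np.random.default_rng(seed)
    hosts = [h for h in host.tip_labels()]
    costs = []
    lower = 0
    for _ in range(n_iter):
        links = []
        for strain in assoc.strains:
            k = len(assoc.hosts_of(strain))
            picked = rng.choice(len(hosts), size=k, replace=False)
            links.extend((hosts[i], strain) for i in picked)
        rnd_assoc = AssociationMatrix.from_links(
            links, hosts=assoc.hosts, strains=assoc.strains
        )
        res = reconcile(host, symb, rnd_assoc, scheme, mode=mode,
                        seed=seed + 1)
        costs.append(res.total_cost)
        if res.total_cost < observed.total_cost - 1e-12:
            lower += 1
    return RandomTipMappingResult(
        observed_cost=observed.total_cost,
        random_costs=costs,
        fraction_lower=lower / n_iter,
        n_iter=n_iter,
        seed=seed,
    )
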