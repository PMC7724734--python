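"""Synthetic-data generators with known ground truth.

Three generators cover the pipeline's inputs:

* :func:`simulate_cophylogeny` grows a Yule host tree and runs an explicit
  event process for the symbiont lineages riding it (cospeciation /
  one-sided loss / failure to diverge at each host speciation, plus
  independent duplication and host-shift opportunities), returning both
  trees, the realized association matrix, and the full event log.
* :func:`simulate_sequences` evolves nucleotide sequences along a tree
  under the two-parameter (transition/transversion) substitution model,
  so K2P distances are consistent estimates of patristic distances.
* :func:`simulate_specimens` draws individual screening records with
  species-level prevalence, a multiplicative sex effect on the infection
  odds, and tissue-tropism probabilities (reproductive >> gut ~ leg).

All generators are reproducible bit-for-bit for a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reconcile import CostScheme, total_cost
from .tables import AssociationMatrix, SpecimenTable
from .tree import PhyloTree


# -- joint host/symbiont history -------------------------------------------


@dataclass(frozen=True)
class EventRates:
    """Per-host-speciation event probabilities for a resident symbiont.

    ``cospeciation``, ``loss`` and ``failure_to_diverge`` are the
    probabilities of the three possible responses of a resident lineage
    to its host's speciation (they must sum to 1).  ``duplication`` and
    ``host_shift`` are independent per-lineage opportunity probabilities
    drawn at every host speciation epoch.  The defaults echo a
    loss-dominated history with rare cospeciation and recurrent host
    shifts, the regime reported for *Wolbachia* in wild mosquito
    communities.
    """

    cospeciation: float = 0.05
    loss: float = 0.75
    failure_to_diverge: float = 0.20
    duplication: float = 0.05
    host_shift: float = 0.15

    def __post_init__(self) -> None:
        trio = self.cospeciation + self.loss + self.failure_to_diverge
        if abs(trio - 1.0) > 1e-9:
            raise ValueError(
                "cospeciation + loss + failure_to_diverge must sum to 1"
            )
        for name in ("cospeciation", "loss", "failure_to_diverge",
                     "duplication", "host_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass
class CophylogenySim:
    """A simulated joint history: trees, associations, and the truth."""

    host_tree: PhyloTree
    symbiont_tree: PhyloTree
    association: AssociationMatrix
    event_log: list[tuple[str, str]]  # (event type, host lineage label)
    event_counts: dict[str, int]
    rates: EventRates
    seed: int

    def true_cost(self, scheme: CostScheme = CostScheme()) -> float:
        """Cost of the generating event log under ``scheme``."""
        counts = {
            k: v for k, v in self.event_counts.items()
            if k in ("cospeciation", "duplication", "host_shift", "loss",
                     "failure_to_diverge")
        }
        return total_cost(counts, scheme)


class _Lineage:
    __slots__ = ("lid", "birth", "parent", "children", "hosts")

    def __init__(self, lid, birth, parent):
        self.lid = lid
        self.birth = birth
        self.parent = parent
        self.children = []
        self.hosts: set[int] = set()


def simulate_cophylogeny(
    n_host_tips: int = 16,
    rates: EventRates = EventRates(),
    seed: int = 0,
    max_retries: int = 20,
) -> CophylogenySim:
    """Grow a host tree (Yule, rate 1) with symbionts tracked along it.

    One symbiont lineage starts on the root host lineage.  At each host
    speciation every resident symbiont copy responds: a single-copy
    lineage cospeciates, tracks one daughter (charging a loss), or fails
    to diverge (spreading over both daughters); a lineage already spread
    over several hosts only tracks/loses or spreads further, so the
    symbiont genealogy stays strictly binary and multi-host tips carry
    exactly the failure-to-diverge semantics the reconciler assumes.
    Duplication and host-shift opportunities are drawn independently for
    every single-copy lineage at each speciation epoch.
    """
    if n_host_tips < 2:
        raise ValueError("need at least 2 host tips")
    last_error = None
    for retry in range(max_retries):
        rng = np.random.default_rng((seed + 1_000_003 * retry) % 2**31)
        sim = _run_cophylogeny(n_host_tips, rates, rng, seed)
        if sim is not None:
            return sim
        last_error = "all symbiont lineages extinct"
    raise RuntimeError(f"simulation failed after {max_retries} tries: "
                       f"{last_error}")


def _run_cophylogeny(n_host_tips, rates, rng, seed):
    # host nodes: id -> dict(birth, parent, children)
    host_nodes = {0: {"birth": 0.0, "parent": None, "children": []}}
    active_hosts = [0]
    next_host = 1
    t = 0.0

    lineages = {0: _Lineage(0, 0.0, None)}
    lineages[0].hosts = {0}
    copies: dict[int, set[int]] = {0: {0}}  # host id -> resident lineage ids
    next_lid = 1
    log: list[tuple[str, str]] = []
    counts = {k: 0 for k in ("cospeciation", "duplication", "host_shift",
                             "loss", "failure_to_diverge")}

    def n_copies(lid: int) -> int:
        return len(lineages[lid].hosts)

    def diverge(lid: int, when: float) -> tuple[int, int]:
        nonlocal next_lid
        a = _Lineage(next_lid, when, lid)
        b = _Lineage(next_lid + 1, when, lid)
        next_lid += 2
        lineages[a.lid] = a
        lineages[b.lid] = b
        lineages[lid].children = [a.lid, b.lid]
        return a.lid, b.lid

    while len(active_hosts) < n_host_tips:
        t += rng.exponential(1.0 / len(active_hosts))
        h = active_hosts[rng.integers(len(active_hosts))]
        hlab = f"hl{h}"
        d1, d2 = next_host, next_host + 1
        next_host += 2
        for d in (d1, d2):
            host_nodes[d] = {"birth": t, "parent": h, "children": []}
            host_nodes[h]["children"].append(d)
            copies[d] = set()
        active_hosts.remove(h)
        active_hosts.extend([d1, d2])

        residents = sorted(copies.pop(h, set()))
        for lid in residents:
            lin = lineages[lid]
            lin.hosts.discard(h)
            multi = n_copies(lid) > 0  # other copies elsewhere already
            if multi:
                # spread lineage: only track-one-side or spread further
                p_ftd = rates.failure_to_diverge
                p_loss = rates.loss + rates.cospeciation
                u = rng.random() * (p_ftd + p_loss)
                if u < p_ftd:
                    log.append(("failure_to_diverge", hlab))
                    counts["failure_to_diverge"] += 1
                    targets = (d1, d2)
                else:
                    log.append(("loss", hlab))
                    counts["loss"] += 1
                    targets = ((d1,) if rng.random() < 0.5 else (d2,))
                for d in targets:
                    lin.hosts.add(d)
                    copies[d].add(lid)
                continue
            u = rng.random()
            if u < rates.cospeciation:
                log.append(("cospeciation", hlab))
                counts["cospeciation"] += 1
                a, b = diverge(lid, t)
                lineages[a].hosts = {d1}
                lineages[b].hosts = {d2}
                copies[d1].add(a)
                copies[d2].add(b)
            elif u < rates.cospeciation + rates.loss:
                log.append(("loss", hlab))
                counts["loss"] += 1
                d = d1 if rng.random() < 0.5 else d2
                lin.hosts.add(d)
                copies[d].add(lid)
            else:
                log.append(("failure_to_diverge", hlab))
                counts["failure_to_diverge"] += 1
                for d in (d1, d2):
                    lin.hosts.add(d)
                    copies[d].add(lid)

        # independent duplication / host-shift opportunities for every
        # extant single-copy lineage
        extant = sorted({lid for c in copies.values() for lid in c})
        for lid in extant:
            lin = lineages[lid]
            if lin.children or n_copies(lid) != 1:
                continue
            home = next(iter(lin.hosts))
            if rng.random() < rates.duplication:
                log.append(("duplication", f"hl{home}"))
                counts["duplication"] += 1
                a, b = diverge(lid, t)
                lineages[a].hosts = {home}
                lineages[b].hosts = {home}
                copies[home].discard(lid)
                copies[home].update((a, b))
                continue
            others = [x for x in active_hosts if x != home]
            if others and rng.random() < rates.host_shift:
                target = others[rng.integers(len(others))]
                log.append(("host_shift", f"hl{home}"))
                counts["host_shift"] += 1
                a, b = diverge(lid, t)
                lineages[a].hosts = {home}
                lineages[b].hosts = {target}
                copies[home].discard(lid)
                copies[home].add(a)
                copies[target].add(b)

    present = t + rng.exponential(1.0 / len(active_hosts))

    # host tree newick
    host_label = {h: f"H{i+1}" for i, h in enumerate(sorted(active_hosts))}

    def host_newick(h) -> str:
        node = host_nodes[h]
        end = (present if not node["children"]
               else host_nodes[node["children"][0]]["birth"])
        length = end - node["birth"]
        if node["children"]:
            inner = ",".join(host_newick(c) for c in node["children"])
            return f"({inner}):{length:.10g}"
        return f"{host_label[h]}:{length:.10g}"

    host_tree = PhyloTree.from_newick(host_newick(0) + ";")

    extant_lids = sorted({lid for c in copies.values() for lid in c})
    if not extant_lids:
        return None
    symb_label = {lid: f"S{i+1}" for i, lid in enumerate(extant_lids)}

    def symb_newick(lid) -> str:
        lin = lineages[lid]
        if lin.children:
            end = lineages[lin.children[0]].birth
            inner = ",".join(symb_newick(c) for c in lin.children)
            return f"({inner}):{end - lin.birth:.10g}"
        return f"{symb_label[lid]}:{present - lin.birth:.10g}"

    # the symbiont root lineage may itself be a tip
    symb_tree = PhyloTree.from_newick(symb_newick(0) + ";")

    links = []
    for lid in extant_lids:
        for h in lineages[lid].hosts:
            links.append((host_label[h], symb_label[lid]))
    assoc = AssociationMatrix.from_links(
        links,
        hosts=[host_label[h] for h in sorted(active_hosts)],
        strains=[symb_label[lid] for lid in extant_lids],
    )
    return CophylogenySim(
        host_tree=host_tree,
        symbiont_tree=symb_tree,
        association=assoc,
        event_log=log,
        event_counts=counts,
        rates=rates,
        seed=seed,
    )


# -- sequence evolution ----------------------------------------------------

_BASES = np.array(list("ACGT"))
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T


def _k2p_probs(length: float, alpha: float, beta: float) -> np.ndarray:
    """4x4 substitution probability matrix for one branch.

    ``length`` is in expected substitutions/site; ``alpha`` and ``beta``
    are the transition and (per-target) transversion rates, so time is
    rescaled by the total rate ``alpha + 2 beta``.
    """
    rate = alpha + 2.0 * beta
    t = length / rate if rate > 0 else 0.0
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    p_same = 1.0 - p_ts - 2.0 * p_tv
    P = np.full((4, 4), p_tv)
    for i in range(4):
        P[i, i] = p_same
        P[i, _TRANSITION_PARTNER[i]] = p_ts
    return P


def simulate_sequences(
    tree: PhyloTree,
    n_sites: int = 1000,
    transition_rate: float = 0.5,
    transversion_rate: float = 0.25,
    seed: int = 0,
) -> "Alignment":
    """Evolve sequences along ``tree`` under the two-parameter model.

    The root sequence is uniform over {A, C, G, T}; each site evolves
    independently along every branch with the transition/transversion
    rate pair (defaults give total rate 1, kappa = 2, so expected K2P
    distance between tips equals their patristic distance).
    """
    from .alignment import Alignment

    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not tree.has_branch_lengths():
        raise ValueError("sequence simulation needs branch lengths")
    rng = np.random.default_rng(seed)
    root = tree.dtree.seed_node
    seqs: dict[int, np.ndarray] = {
        id(root): rng.integers(0, 4, size=n_sites)
    }
    ids, rows = [], []
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is not None:
            parent_seq = seqs[id(node.parent_node)]
            P = _k2p_probs(node.edge.length, transition_rate,
                           transversion_rate)
            cum = P.cumsum(axis=1)[parent_seq]
            u = rng.random(n_sites)
            seqs[id(node)] = (u[:, None] > cum).sum(axis=1)
        if node.is_leaf():
            ids.append(node.taxon.label)
            rows.append("".join(_BASES[seqs[id(node)]]))
    return Alignment(ids=ids, matrix=rows)


# -- specimen tables -------------------------------------------------------


@dataclass
class SpecimenSimParams:
    """Parameters of the specimen-table generator.

    Defaults mirror the screening survey the pipeline targets: overall
    prevalence around 0.44, a male/female infection odds ratio of 0.434,
    reproductive-tissue tropism far above gut and leg (0.95 / 0.12 /
    0.07 conditional on infection), and an internal-control failure rate
    of 0.41 (159 of 271 screened individuals passed).
    """

    prevalence: dict[str, float] = field(
        default_factory=lambda: {f"sp{i+1}": p for i, p in enumerate(
            [0.0, 0.1, 0.2, 0.3, 0.45, 0.55, 0.6, 0.7, 0.85, 0.9])}
    )
    n_per_species: dict[str, int] | int = 25
    locality_of: dict[str, str] | None = None
    sex_odds_ratio: float = 0.434
    p_reproductive: float = 0.95
    p_gut: float = 0.12
    p_leg: float = 0.07
    control_failure_rate: float = 0.41

    def __post_init__(self) -> None:
        for name in ("p_reproductive", "p_gut", "p_leg",
                     "control_failure_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for sp, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{sp!r}] must be a probability")
        if self.sex_odds_ratio <= 0:
            raise ValueError("sex odds ratio must be positive")

    def sample_size(self, species: str) -> int:
        if isinstance(self.n_per_species, int):
            return self.n_per_species
        return self.n_per_species[species]


def _logit(p: float) -> float:
    return np.log(p / (1.0 - p))


def simulate_specimens(
    params: SpecimenSimParams = None, seed: int = 0
) -> SpecimenTable:
    """Draw a specimen table from the generative screening model.

    Per specimen: sex ~ Bernoulli(1/2); infection ~ Bernoulli with
    log-odds ``logit(prevalence) + male * ln(OR)``; tissue calls drawn
    conditional on infection status (uninfected specimens are negative in
    every tissue); internal-control failures injected independently.
    """
    if params is None:
        params = SpecimenSimParams()
    rng = np.random.default_rng(seed)
    tissue_p = {
        "reproductive": params.p_reproductive,
        "gut": params.p_gut,
        "leg": params.p_leg,
    }
    rows = []
    for species in params.prevalence:
        n = params.sample_size(species)
        prev = params.prevalence[species]
        locality = (params.locality_of or {}).get(species, "L1")
        for i in range(n):
            male = rng.random() < 0.5
            if prev <= 0.0:
                infected = False
            elif prev >= 1.0:
                infected = True
            else:
                logodds = _logit(prev) + (
                    np.log(params.sex_odds_ratio) if male else 0.0
                )
                infected = rng.random() < 1.0 / (1.0 + np.exp(-logodds))
            calls = {}
            for tissue, p in tissue_p.items():
                calls[tissue] = (
                    "positive" if (infected and rng.random() < p)
                    else "negative"
                )
            rows.append(
                {
                    "specimen_id": f"{species}-{i+1}",
                    "species": species,
                    "locality": locality,
                    "sex": "M" if male else "F",
                    **calls,
                    "control_ok": bool(
                        rng.random() >= params.control_failure_rate
                    ),
                }
            )
    return SpecimenTable(pd.DataFrame(rows))
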