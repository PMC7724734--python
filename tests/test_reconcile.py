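import numpy as np
import pytest

from conftest import random_binary_tree
from cophylo.errors import ReconciliationError
from cophylo.reconcile import (CostScheme, Reconciliation,
                               brute_force_reconcile,
                               random_tip_mapping_test, reconcile,
                               total_cost)
from cophylo.simulate import EventRates, simulate_cophylogeny
from cophylo.tables import AssociationMatrix
from cophylo.tree import PhyloTree

DEFAULT = CostScheme()


def random_instance(rng, max_host=5, max_symb=5):
    nh = int(rng.integers(2, max_host + 1))
    ns = int(rng.integers(1, max_symb + 1))
    host = random_binary_tree(rng, nh, prefix="H")
    symb = (random_binary_tree(rng, ns, prefix="S") if ns > 1
            else PhyloTree.from_newick("S0:1;"))
    links = []
    for stip in symb.tip_labels():
        k = int(rng.integers(1, min(3, nh) + 1))
        hosts = rng.choice(host.tip_labels(), size=k, replace=False)
        links.extend((str(h), stip) for h in hosts)
    assoc = AssociationMatrix.from_links(
        links, hosts=host.tip_labels(), strains=symb.tip_labels())
    return host, symb, assoc


class TestTotalCost:
    def test_reported_event_mix_costs_52(self):
        counts = {"cospeciation": 1, "duplication": 3, "host_shift": 7,
                  "loss": 29, "failure_to_diverge": 6}
        assert total_cost(counts, DEFAULT) == 52

    def test_all_zero(self):
        assert total_cost({e: 0 for e in counts_keys()}, DEFAULT) == 0

    def test_cospeciation_is_free(self):
        assert total_cost({"cospeciation": 5}, DEFAULT) == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            total_cost({"loss": -1}, DEFAULT)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            CostScheme(loss=-0.5)


def counts_keys():
    return ("cospeciation", "duplication", "host_shift", "loss",
            "failure_to_diverge")


class TestExactSolver:
    def test_perfect_congruence_costs_zero(self):
        h = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        s = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assoc = AssociationMatrix.from_links(
            [("A", "a"), ("B", "b"), ("C", "c"), ("D", "d")])
        res = reconcile(h, s, assoc)
        assert res.total_cost == 0
        assert res.counts["cospeciation"] == 3
        assert res.optimal

    def test_single_tip_on_two_hosts_is_one_failure_to_diverge(self):
        h = PhyloTree.from_newick("(A:1,B:1);")
        s = PhyloTree.from_newick("x:1;")
        assoc = AssociationMatrix.from_links([("A", "x"), ("B", "x")])
        res = reconcile(h, s, assoc)
        assert res.counts["failure_to_diverge"] == 1
        assert res.total_cost == 1

    def test_two_strains_on_opposite_cherries(self):
        h = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        s = PhyloTree.from_newick("(s1:1,s2:1);")
        assoc = AssociationMatrix.from_links([("A", "s1"), ("C", "s2")])
        res = reconcile(h, s, assoc)
        assert res.total_cost == 2
        assert res.total_cost == brute_force_reconcile(h, s, assoc).total_cost

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(40):
            host, symb, assoc = random_instance(rng)
            exact = reconcile(host, symb, assoc)
            brute = brute_force_reconcile(host, symb, assoc)
            assert exact.total_cost == pytest.approx(brute.total_cost)

    def test_counts_consistent_with_cost(self, rng):
        for _ in range(20):
            host, symb, assoc = random_instance(rng)
            res = reconcile(host, symb, assoc)
            assert res.total_cost == pytest.approx(
                total_cost(res.counts, DEFAULT))

    def test_unrooted_host_rejected(self):
        h = PhyloTree.from_newick("(A:1,B:1,C:1);")
        s = PhyloTree.from_newick("(a:1,b:1);")
        assoc = AssociationMatrix.from_links([("A", "a"), ("B", "b")])
        with pytest.raises(ReconciliationError, match="rooted"):
            reconcile(h, s, assoc)

    def test_symbiont_without_host_rejected(self):
        h = PhyloTree.from_newick("(A:1,B:1);")
        s = PhyloTree.from_newick("(a:1,b:1);")
        assoc = AssociationMatrix.from_links([("A", "a"), ("B", "b")])
        bad = AssociationMatrix.from_links([("A", "a")],
                                           hosts=["A", "B"], strains=["a"])
        with pytest.raises(ReconciliationError, match="absent"):
            reconcile(h, s, bad)

    def test_mismatched_counts_rejected_by_result_type(self):
        with pytest.raises(ReconciliationError, match="imply cost"):
            Reconciliation(placements={}, events=[],
                           counts={"loss": 3}, total_cost=1.0,
                           optimal=True, scheme=DEFAULT)


class TestHeuristicSolver:
    def test_never_beats_exact(self, rng):
        for i in range(15):
            host, symb, assoc = random_instance(rng)
            exact = reconcile(host, symb, assoc)
            heur = reconcile(host, symb, assoc, mode="heuristic",
                             generations=20, population=40, seed=i)
            assert heur.total_cost >= exact.total_cost - 1e-9
            assert not heur.optimal

    def test_finds_optimum_on_small_instances(self, rng):
        hits = 0
        for i in range(10):
            host, symb, assoc = random_instance(rng, max_host=4,
                                                max_symb=3)
            exact = reconcile(host, symb, assoc)
            heur = reconcile(host, symb, assoc, mode="heuristic",
                             generations=40, population=100, seed=i)
            hits += heur.total_cost == pytest.approx(exact.total_cost)
        assert hits >= 8

    def test_seed_determinism(self, rng):
        host, symb, assoc = random_instance(rng)
        r1 = reconcile(host, symb, assoc, mode="heuristic",
                       generations=10, population=30, seed=5)
        r2 = reconcile(host, symb, assoc, mode="heuristic",
                       generations=10, population=30, seed=5)
        assert r1.total_cost == r2.total_cost
        assert r1.events == r2.events


class TestSimulatedHistories:
    def test_cospeciation_only_reconciles_to_zero(self):
        rates = EventRates(cospeciation=1.0, loss=0.0,
                           failure_to_diverge=0.0, duplication=0.0,
                           host_shift=0.0)
        for seed in range(5):
            sim = simulate_cophylogeny(n_host_tips=8, rates=rates,
                                       seed=seed)
            res = reconcile(sim.host_tree, sim.symbiont_tree,
                            sim.association)
            assert res.total_cost == 0
            n_internal = sim.symbiont_tree.n_tips - 1
            assert res.counts["cospeciation"] == n_internal

    def test_reconstructed_cost_never_exceeds_true_cost(self):
        for seed in range(8):
            sim = simulate_cophylogeny(n_host_tips=10, seed=seed)
            res = reconcile(sim.host_tree, sim.symbiont_tree,
                            sim.association)
            assert res.total_cost <= sim.true_cost() + 1e-9


class TestRandomTipMapping:
    def test_congruent_system_fraction_zero(self):
        h = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        s = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assoc = AssociationMatrix.from_links(
            [("A", "a"), ("B", "b"), ("C", "c"), ("D", "d")])
        res = random_tip_mapping_test(h, s, assoc, n_iter=20, seed=0)
        assert res.fraction_lower == 0.0
        assert res.supports_cospeciation()

    def test_random_association_fraction_moderate(self, rng):
        host = random_binary_tree(rng, 8, prefix="H")
        symb = random_binary_tree(rng, 5, prefix="S")
        links = [(host.tip_labels()[i], s)
                 for i, s in enumerate(symb.tip_labels())]
        assoc = AssociationMatrix.from_links(
            links, hosts=host.tip_labels(), strains=symb.tip_labels())
        res = random_tip_mapping_test(host, symb, assoc, n_iter=50, seed=1)
        # observed cost is itself a draw from the null: rank not extreme
        assert 0.0 <= res.fraction_lower <= 0.9

    def test_threshold_boolean(self):
        h = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        s = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assoc = AssociationMatrix.from_links(
            [("A", "a"), ("B", "b"), ("C", "c"), ("D", "d")])
        res = random_tip_mapping_test(h, s, assoc, n_iter=10, seed=0)
        # a 14% fraction would not support cospeciation at the 5% rule
        assert not type(res)(observed_cost=res.observed_cost,
                             random_costs=res.random_costs,
                             fraction_lower=0.14, n_iter=50,
                             seed=0).supports_cospeciation()
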