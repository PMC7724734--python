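import shutil
import subprocess

import numpy as np
import pytest

from conftest import random_binary_tree
from cophylo.distance import DistanceMatrix
from cophylo.errors import CophyloError
from cophylo.parafit import (cailliez_constant, parafit_global,
                             parafit_links, pcoa_cailliez)
from cophylo.tables import AssociationMatrix
from cophylo.tree import PhyloTree, patristic_distances

NON_EUCLIDEAN = np.array(
    [[0, 2, 2, 1.1], [2, 0, 2, 1.1], [2, 2, 0, 1.1], [1.1, 1.1, 1.1, 0]]
)


def dm(matrix, prefix="x"):
    return DistanceMatrix(
        labels=[f"{prefix}{i}" for i in range(matrix.shape[0])],
        matrix=matrix,
    )


class TestPcoaCailliez:
    def test_points_on_a_line_need_no_correction(self):
        pts = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(pts[:, None] - pts[None, :])
        coords, c = pcoa_cailliez(dm(D))
        assert c == 0.0
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2)
                      .sum(-1))
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_correction_removes_negative_eigenvalues(self):
        coords, c = pcoa_cailliez(dm(NON_EUCLIDEAN))
        assert c > 0
        corrected = NON_EUCLIDEAN + c
        np.fill_diagonal(corrected, 0.0)
        n = corrected.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (corrected**2) @ J
        assert np.linalg.eigvalsh(G).min() > -1e-8

    def test_scaling_property(self):
        c1 = cailliez_constant(NON_EUCLIDEAN)
        c2 = cailliez_constant(2 * NON_EUCLIDEAN)
        assert c2 == pytest.approx(2 * c1)
        coords1, _ = pcoa_cailliez(dm(NON_EUCLIDEAN))
        coords2, _ = pcoa_cailliez(dm(2 * NON_EUCLIDEAN))
        d1 = np.sqrt(((coords1[:, None] - coords1[None]) ** 2).sum(-1))
        d2 = np.sqrt(((coords2[:, None] - coords2[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-8)

    def test_all_zero_matrix(self):
        coords, c = pcoa_cailliez(dm(np.zeros((3, 3))))
        assert c == 0.0
        np.testing.assert_array_equal(coords, np.zeros((3, 1)))


def congruent_system(rng, n=8):
    host = random_binary_tree(rng, n, prefix="h")
    symb = PhyloTree.from_newick(
        host.to_newick().replace("h", "s"))
    links = [(f"h{i}", f"s{i}") for i in range(n)]
    assoc = AssociationMatrix.from_links(
        links, hosts=host.tip_labels(), strains=symb.tip_labels())
    return (patristic_distances(host), patristic_distances(symb), assoc)


class TestParafitGlobal:
    def test_single_link_equals_its_own_contribution(self, rng):
        hD, sD, _ = congruent_system(rng, 4)
        assoc = AssociationMatrix.from_links(
            [("h0", "s0")], hosts=hD.labels, strains=["s0"])
        sD1 = sD.submatrix(["s0"])
        res = parafit_links(hD, sD1, assoc, n_perm=99, seed=0)
        assert len(res.links) == 1
        assert res.links[0].statistic == pytest.approx(res.global_stat)

    def test_congruent_trees_significant(self, rng):
        hD, sD, assoc = congruent_system(rng, 8)
        res = parafit_global(hD, sD, assoc, n_perm=999, seed=1)
        assert res.global_p <= 0.05

    def test_trace_form_equals_brute_force_double_sum(self, rng):
        """Global statistic recomputed element-by-element from the
        fourth-corner product, without matrix algebra."""
        hD, sD, assoc = congruent_system(rng, 6)
        B, _ = pcoa_cailliez(hD)
        C, _ = pcoa_cailliez(sD)
        A = np.zeros((len(sD.labels), len(hD.labels)))
        for host, strain in assoc.links():
            A[sD.labels.index(strain), hD.labels.index(host)] = 1
        brute = 0.0
        for k in range(C.shape[1]):
            for m in range(B.shape[1]):
                term = 0.0
                for i in range(A.shape[0]):
                    for j in range(A.shape[1]):
                        term += C[i, k] * A[i, j] * B[j, m]
                brute += term**2
        res = parafit_global(hD, sD, assoc, n_perm=9, seed=0)
        assert res.global_stat == pytest.approx(brute)

    def test_relabelling_invariance(self, rng):
        hD, sD, assoc = congruent_system(rng, 6)
        stat1 = parafit_global(hD, sD, assoc, n_perm=9, seed=0).global_stat
        # permute host rows consistently in D and A
        perm = list(rng.permutation(len(hD.labels)))
        labels2 = [hD.labels[i] for i in perm]
        hD2 = hD.submatrix(labels2)
        stat2 = parafit_global(hD2, sD, assoc, n_perm=9, seed=0).global_stat
        assert stat2 == pytest.approx(stat1)

    def test_seed_determinism(self, rng):
        hD, sD, assoc = congruent_system(rng, 6)
        r1 = parafit_links(hD, sD, assoc, n_perm=199, seed=7)
        r2 = parafit_links(hD, sD, assoc, n_perm=199, seed=7)
        assert r1.global_p == r2.global_p
        assert [l.p_value for l in r1.links] == [l.p_value for l in r2.links]

    def test_empty_association_rejected(self, rng):
        hD, sD, assoc = congruent_system(rng, 4)
        bad = AssociationMatrix.from_links(
            [("h9", "s0")], hosts=["h9"], strains=["s0"])
        with pytest.raises(CophyloError):
            parafit_global(hD, sD, bad, n_perm=9, seed=0)


class TestParafitLinks:
    def test_congruent_links_all_positive(self, rng):
        hD, sD, assoc = congruent_system(rng, 8)
        res = parafit_links(hD, sD, assoc, n_perm=99, seed=0)
        assert all(l.statistic > 0 for l in res.links)

    def test_incongruent_extra_link_has_smallest_contribution(self):
        # balanced congruent system plus one link crossing the deep split
        nwk = ("(((h0:1,h1:1):1,(h2:1,h3:1):1):2,"
               "((h4:1,h5:1):1,(h6:1,h7:1):1):2);")
        host = PhyloTree.from_newick(nwk)
        symb = PhyloTree.from_newick(nwk.replace("h", "s"))
        hD, sD = patristic_distances(host), patristic_distances(symb)
        links = [(f"h{i}", f"s{i}") for i in range(8)] + [("h7", "s0")]
        assoc2 = AssociationMatrix.from_links(
            links, hosts=host.tip_labels(), strains=symb.tip_labels())
        res = parafit_links(hD, sD, assoc2, n_perm=99, seed=0)
        stats = {(l.host, l.strain): l.statistic for l in res.links}
        assert min(stats, key=stats.get) == ("h7", "s0")

    def test_single_host_link_flagged_undefined_with_statistic(self, rng):
        hD, sD, assoc = congruent_system(rng, 4)
        res = parafit_links(hD, sD, assoc, n_perm=99, seed=0)
        assert all(l.undefined for l in res.links)
        assert all(np.isfinite(l.statistic) for l in res.links)


class TestAgainstApe:
    """ape::parafit as an independent oracle on tiny fixtures."""

    @pytest.mark.parametrize("needs_correction", [False, True])
    def test_global_statistic_matches_ape(self, tmp_path, needs_correction):
        if needs_correction:
            Dh = NON_EUCLIDEAN
        else:
            pts = np.array([0.0, 1.0, 3.0, 6.0])
            Dh = np.abs(pts[:, None] - pts[None, :])
        Ds = np.array([[0, 1, 4], [1, 0, 4.5], [4, 4.5, 0]])
        hD = dm(Dh, "h")
        sD = dm(Ds, "s")
        assoc = AssociationMatrix.from_links(
            [("h0", "s0"), ("h1", "s1"), ("h2", "s2"), ("h3", "s2")],
            hosts=hD.labels, strains=sD.labels)
        ours = parafit_global(hD, sD, assoc, n_perm=9, seed=0).global_stat

        def save(mat, labels, name):
            import pandas as pd

            pd.DataFrame(mat, index=labels, columns=labels).to_csv(
                tmp_path / name)

        save(Dh, hD.labels, "hD.csv")
        save(Ds, sD.labels, "sD.csv")
        import pandas as pd

        pd.DataFrame(assoc.matrix, index=assoc.hosts,
                     columns=assoc.strains).to_csv(tmp_path / "hp.csv")
        script = (
            'suppressMessages(library(ape));'
            f'hD <- as.matrix(read.csv("{tmp_path}/hD.csv", row.names=1));'
            f'sD <- as.matrix(read.csv("{tmp_path}/sD.csv", row.names=1));'
            f'hp <- as.matrix(read.csv("{tmp_path}/hp.csv", row.names=1));'
            'res <- parafit(hD, sD, hp, nperm=9, correction="cailliez",'
            ' silent=TRUE);'
            'cat(sprintf("%.10f", res$ParaFitGlobal))'
        )
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        assert ours == pytest.approx(float(out.stdout.strip()), rel=1e-6)
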