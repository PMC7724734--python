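"""Phylogenetic host specificity of generalist endosymbiont strains.

The host-specificity score PS of a strain is the mean patristic distance
between all pairs of host species it infects.  The standardized score

    SPS = (PS - mean(PS_null)) / sd(PS_null)

compares PS with a permutation null in which the same number of host
species is drawn uniformly without replacement from the host-tree tips
(a richness-preserving label shuffle).  The rank P-value is lower-tailed
with the add-one convention: small PS (phylogenetically clustered hosts,
low host flexibility) gives small P; P > 0.95 flags phylogenetically
overdispersed (highly flexible) strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .distance import DistanceMatrix
from .errors import CophyloError
from .tables import AssociationMatrix
from .tree import PhyloTree, patristic_distances


@dataclass(frozen=True)
class SpsResult:
    """Standardized phylogenetic host-specificity of one strain."""

    strain: str
    n_hosts: int
    ps: float
    null_mean: float
    null_sd: float
    sps: float
    p_value: float
    n_null: int
    seed: int
    degenerate: bool = False

    def summary(self) -> str:
        flag = " (degenerate null)" if self.degenerate else ""
        return (
            f"{self.strain}: n={self.n_hosts} PS={self.ps:.4g} "
            f"SPS={self.sps:.3g} P={self.p_value:.3g}{flag}"
        )


def ps_score(host_tree: PhyloTree, hosts: Sequence[str]) -> float:
    """Mean pairwise patristic distance among ``hosts`` on ``host_tree``."""
    hosts = list(hosts)
    if len(set(hosts)) != len(hosts):
        raise ValueError("duplicate host labels")
    if len(hosts) < 2:
        raise ValueError("PS needs at least two hosts")
    tips = set(host_tree.tip_labels())
    missing = [h for h in hosts if h not in tips]
    if missing:
        raise KeyError(f"hosts not on tree: {missing}")
    D = patristic_distances(host_tree)
    idx = [D.labels.index(h) for h in hosts]
    pairs = [(i, j) for i, j in combinations(idx, 2)]
    return float(np.mean([D.matrix[i, j] for i, j in pairs]))


def _mean_pairwise(matrix: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Mean pairwise distance for each row of index-subsets ``idx``."""
    k = idx.shape[1]
    ii, jj = np.triu_indices(k, 1)
    sub = matrix[idx[:, ii], idx[:, jj]]
    return sub.mean(axis=1)


def sps_score(
    host_tree: PhyloTree,
    assoc: AssociationMatrix,
    strain: str,
    n_null: int = 999,
    null_model: str = "uniform",
    seed: int = 0,
) -> SpsResult:
    """SPS of one generalist strain against the permutation null.

    ``null_model``: ``"uniform"`` draws host sets uniformly from the tree
    tips; ``"tipshuffle"`` shuffles tip labels and keeps the strain's
    (shuffled) hosts — marginally equivalent, both richness-preserving.
    """
    if null_model not in ("uniform", "tipshuffle"):
        raise ValueError(f"unknown null model {null_model!r}")
    hosts = assoc.hosts_of(strain)
    if len(hosts) < 2:
        raise CophyloError(
            f"strain {strain!r} is a specialist; SPS needs >= 2 hosts"
        )
    D = patristic_distances(host_tree)
    tips = D.labels
    missing = [h for h in hosts if h not in tips]
    if missing:
        raise KeyError(f"hosts not on tree: {missing}")
    k = len(hosts)
    obs_idx = np.array([[tips.index(h) for h in hosts]])
    ps = float(_mean_pairwise(D.matrix, obs_idx)[0])

    rng = np.random.default_rng(seed)
    n_tips = len(tips)
    draws = np.empty((n_null, k), dtype=int)
    for r in range(n_null):
        draws[r] = rng.choice(n_tips, size=k, replace=False)
    null_ps = _mean_pairwise(D.matrix, draws)

    null_mean = float(null_ps.mean())
    null_sd = float(null_ps.std(ddof=1))
    degenerate = null_sd <= 1e-12
    sps = float("nan") if degenerate else (ps - null_mean) / null_sd
    p = (int(np.sum(null_ps <= ps + 1e-12)) + 1) / (n_null + 1)
    return SpsResult(
        strain=strain,
        n_hosts=k,
        ps=ps,
        null_mean=null_mean,
        null_sd=null_sd,
        sps=sps,
        p_value=p,
        n_null=n_null,
        seed=seed,
        degenerate=degenerate,
    )


def sps_table(
    host_tree: PhyloTree,
    assoc: AssociationMatrix,
    n_null: int = 999,
    null_model: str = "uniform",
    seed: int = 0,
) -> list[SpsResult]:
    """SPS for every generalist strain in the association matrix."""
    out = []
    for j, strain in enumerate(assoc.strains):
        if assoc.matrix[:, j].sum() >= 2:
            out.append(
                sps_score(
                    host_tree,
                    assoc,
                    strain,
                    n_null=n_null,
                    null_model=null_model,
                    seed=seed + j,
                )
            )
    return out
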