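"""ParaFit tests of host-symbiont phylogenetic congruence.

The global statistic is built from principal coordinates of the two
distance matrices (after the Cailliez correction whenever classical
scaling produces negative eigenvalues): with B the host coordinates, C
the symbiont coordinates, and A the symbiont x host incidence matrix, the
fourth-corner cross-product is D = C' A B and the global statistic is
trace(D'D) = sum of squared entries.  Significance comes from permuting,
independently within each symbiont row of A, its host incidences.  The
per-link statistic is the contribution form: the global statistic minus
the global statistic with that link removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .distance import DistanceMatrix
from .errors import CophyloError
from .tables import AssociationMatrix

EIGEN_RTOL = 1e-8


@dataclass(frozen=True)
class LinkTest:
    host: str
    strain: str
    statistic: float
    p_value: float | None
    undefined: bool = False


@dataclass(frozen=True)
class ParafitResult:
    """Global and per-link ParaFit test results."""

    global_stat: float
    global_p: float
    links: list[LinkTest]
    n_perm: int
    cailliez_host: float
    cailliez_symb: float
    seed: int

    def summary(self) -> str:
        lines = [
            f"ParaFitGlobal = {self.global_stat:.6g}, "
            f"P = {self.global_p:.4g} ({self.n_perm} permutations)"
        ]
        for link in self.links:
            if link.undefined:
                lines.append(f"  {link.host} -- {link.strain}: undefined "
                             "(removal leaves strain hostless)")
            else:
                lines.append(
                    f"  {link.host} -- {link.strain}: "
                    f"stat = {link.statistic:.6g}, P = {link.p_value:.4g}"
                )
        return "\n".join(lines)


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making ``D`` Euclidean.

    Largest real eigenvalue of the 2n x 2n block matrix
    ``[[0, 2*G1], [-I, -4*G2]]`` where G1 and G2 are the Gower-centered
    forms of -D^2/2 and -D/2 (Cailliez's construction).
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G1 = -0.5 * J @ (D**2) @ J
    G2 = -0.5 * J @ D @ J
    upper = np.hstack([np.zeros((n, n)), 2.0 * G1])
    lower = np.hstack([-np.eye(n), -4.0 * G2])
    eigvals = scipy.linalg.eigvals(np.vstack([upper, lower]))
    real = eigvals.real[np.abs(eigvals.imag) < 1e-8]
    c = float(real.max()) if real.size else 0.0
    return max(c, 0.0)


def pcoa_cailliez(D: DistanceMatrix) -> tuple[np.ndarray, float]:
    """Principal coordinates of ``D`` after Cailliez correction.

    Returns ``(coords, c)``: the coordinates on axes with positive
    eigenvalues (scaled by sqrt(eigenvalue), classical scaling) and the
    additive constant ``c`` applied to off-diagonal distances (0 when the
    configuration is already Euclidean).
    """
    mat = np.asarray(D.matrix, dtype=float)
    n = mat.shape[0]
    if n == 1 or np.allclose(mat, 0.0):
        return np.zeros((n, 1)), 0.0

    def gower_eig(dm):
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (dm**2) @ J
        vals, vecs = np.linalg.eigh(G)
        return vals[::-1], vecs[:, ::-1]

    vals, vecs = gower_eig(mat)
    c = 0.0
    tol = EIGEN_RTOL * max(abs(vals[0]), 1.0)
    if vals.min() < -tol:
        c = cailliez_constant(mat)
        corrected = mat + c
        np.fill_diagonal(corrected, 0.0)
        vals, vecs = gower_eig(corrected)
        tol = EIGEN_RTOL * max(abs(vals[0]), 1.0)
    keep = vals > tol
    if not keep.any():
        return np.zeros((n, 1)), c
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return coords, c


def _global_stat(C: np.ndarray, A: np.ndarray, B: np.ndarray) -> float:
    D4 = C.T @ A @ B
    return float(np.sum(D4 * D4))


def _row_permutations(rng, n_perm: int, n_symb: int, n_hosts: int):
    perms = np.empty((n_perm, n_symb, n_hosts), dtype=np.intp)
    for r in range(n_perm):
        for s in range(n_symb):
            perms[r, s] = rng.permutation(n_hosts)
    return perms


def _stacked_global_stats(C, B, stacked_A) -> np.ndarray:
    """Global statistic for each association matrix in ``stacked_A``."""
    D4 = np.einsum("sk,rsh,hm->rkm", C, stacked_A, B, optimize=True)
    return np.sum(D4 * D4, axis=(1, 2))


def _align_assoc(
    host_D: DistanceMatrix, symb_D: DistanceMatrix, assoc: AssociationMatrix
) -> np.ndarray:
    if set(assoc.hosts) != set(host_D.labels):
        raise CophyloError(
            "association hosts do not match host distance labels"
        )
    if set(assoc.strains) != set(symb_D.labels):
        raise CophyloError(
            "association strains do not match symbiont distance labels"
        )
    hi = [assoc.hosts.index(h) for h in host_D.labels]
    si = [assoc.strains.index(s) for s in symb_D.labels]
    # A is symbionts x hosts
    return assoc.matrix[np.ix_(hi, si)].T.astype(float)


def parafit_global(
    host_D: DistanceMatrix,
    symb_D: DistanceMatrix,
    assoc: AssociationMatrix,
    n_perm: int = 5000,
    seed: int = 0,
) -> ParafitResult:
    """Global ParaFit test (no per-link tests; see :func:`parafit_links`)."""
    A = _align_assoc(host_D, symb_D, assoc)
    if A.sum() == 0:
        raise CophyloError("empty association matrix")
    B, c_host = pcoa_cailliez(host_D)
    C, c_symb = pcoa_cailliez(symb_D)
    stat = _global_stat(C, A, B)
    rng = np.random.default_rng(seed)
    n_symb, n_hosts = A.shape
    perms = _row_permutations(rng, n_perm, n_symb, n_hosts)
    perm_A = np.take_along_axis(
        np.broadcast_to(A, (n_perm, n_symb, n_hosts)), perms, axis=2
    )
    perm_stats = _stacked_global_stats(C, B, perm_A)
    p = (int(np.sum(perm_stats >= stat - 1e-12)) + 1) / (n_perm + 1)
    return ParafitResult(
        global_stat=stat,
        global_p=p,
        links=[],
        n_perm=n_perm,
        cailliez_host=c_host,
        cailliez_symb=c_symb,
        seed=seed,
    )


def parafit_links(
    host_D: DistanceMatrix,
    symb_D: DistanceMatrix,
    assoc: AssociationMatrix,
    n_perm: int = 5000,
    seed: int = 0,
) -> ParafitResult:
    """Global test plus the per-link contribution tests.

    Each link's statistic is ``global - global_without_link``; its
    permutation P-value uses the same row-wise permutation scheme, with
    the link's own row permuted as well.  A link whose removal would
    leave its strain with no hosts is reported undefined.
    """
    A = _align_assoc(host_D, symb_D, assoc)
    if A.sum() == 0:
        raise CophyloError("empty association matrix")
    B, c_host = pcoa_cailliez(host_D)
    C, c_symb = pcoa_cailliez(symb_D)
    stat = _global_stat(C, A, B)
    rng = np.random.default_rng(seed)
    n_symb, n_hosts = A.shape
    perms = _row_permutations(rng, n_perm, n_symb, n_hosts)
    perm_A = np.take_along_axis(
        np.broadcast_to(A, (n_perm, n_symb, n_hosts)), perms, axis=2
    ).astype(float)
    perm_global = _stacked_global_stats(C, B, perm_A)
    p_global = (int(np.sum(perm_global >= stat - 1e-12)) + 1) / (n_perm + 1)

    host_idx = {h: i for i, h in enumerate(host_D.labels)}
    symb_idx = {s: i for i, s in enumerate(symb_D.labels)}
    links: list[LinkTest] = []
    for host, strain in assoc.links():
        i = symb_idx[strain]
        j = host_idx[host]
        A0 = A.copy()
        A0[i, j] = 0.0
        link_stat = stat - _global_stat(C, A0, B)
        if A[i].sum() <= 1:
            # removal leaves the strain hostless: the contribution is still
            # reported but the permutation test is undefined
            links.append(
                LinkTest(host=host, strain=strain, statistic=link_stat,
                         p_value=None, undefined=True)
            )
            continue
        # each permuted matrix carries the permuted image of this link at
        # column jp with perms[r, i, jp] == j; remove it there
        jp = np.argmax(perms[:, i, :] == j, axis=1)
        perm_A0 = perm_A.copy()
        perm_A0[np.arange(n_perm), i, jp] = 0.0
        perm_link = perm_global - _stacked_global_stats(C, B, perm_A0)
        count = int(np.sum(perm_link >= link_stat - 1e-12))
        p_link = (count + 1) / (n_perm + 1)
        links.append(
            LinkTest(host=host, strain=strain, statistic=link_stat,
                     p_value=p_link)
        )
    return ParafitResult(
        global_stat=stat,
        global_p=p_global,
        links=links,
        n_perm=n_perm,
        cailliez_host=c_host,
        cailliez_symb=c_symb,
        seed=seed,
    )
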