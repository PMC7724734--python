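"""Pairwise distance matrices and the Kimura two-parameter estimator.

The K2P distance between two aligned sequences is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

with P and Q the proportions of transition- and transversion-differing
sites among the columns compared.  Column handling follows the usual
marker-gene convention: terminal gaps and ``?`` are missing data (the
column is dropped for that pair), internal gaps are indels (dropped from
the P/Q counts but tallied separately per pair).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .errors import DistanceError

# integer codes: A C G T gap missing
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "?": 5}
_GAP, _MISSING = 4, 5
_IS_PURINE = np.array([True, False, True, False, False, False])


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with per-pair bookkeeping.

    Attributes
    ----------
    labels : list of str
    matrix : (n, n) float array, symmetric, zero diagonal
    n_sites : (n, n) int array or None
        Effective (compared) site count per pair.
    indel_columns : (n, n) int array or None
        Internal-gap columns excluded from the P/Q counts, per pair.
    saturated : set of (i, j) label pairs
        Pairs whose K2P logarithm argument was non-positive; their entry
        is a sentinel (twice the largest finite distance).
    """

    labels: list[str]
    matrix: np.ndarray
    n_sites: np.ndarray | None = None
    indel_columns: np.ndarray | None = None
    saturated: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise DistanceError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n} labels"
            )
        if np.any(np.isnan(self.matrix)):
            raise DistanceError("distance matrix contains NaN")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise DistanceError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise DistanceError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(x) for x in labels]
        return DistanceMatrix(
            labels=list(labels), matrix=self.matrix[np.ix_(idx, idx)]
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels,
                            columns=self.labels)


def _encode(aln: Alignment) -> np.ndarray:
    lut = np.zeros(128, dtype=np.int8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    out = np.empty((len(aln), aln.n_sites), dtype=np.int8)
    for i, s in enumerate(aln.matrix):
        out[i] = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
    return out


def _terminal_range(seq: str) -> tuple[int, int]:
    """[start, stop) of the region between the terminal gap runs."""
    start = 0
    stop = len(seq)
    while start < stop and seq[start] == "-":
        start += 1
    while stop > start and seq[stop - 1] == "-":
        stop -= 1
    return start, stop


def k2p_distance(
    aln: Alignment, gap_policy: str = "internal-as-indel"
) -> DistanceMatrix:
    """Kimura two-parameter distances for every sequence pair.

    ``gap_policy`` names the column-handling rule; the implemented value,
    ``"internal-as-indel"``, treats internal gaps as indels (excluded from
    substitution counts, tallied per pair) and terminal gaps as missing.
    Saturated pairs (log argument <= 0) receive a sentinel of twice the
    largest finite distance and are listed in ``DistanceMatrix.saturated``.

    Raises ``DistanceError`` when a pair shares no comparable column.
    """
    if gap_policy not in ("internal-as-indel", "terminal-as-missing"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    n = len(aln)
    if n < 2:
        raise DistanceError("need at least two sequences")
    codes = _encode(aln)
    ranges = [_terminal_range(s) for s in aln.matrix]
    mat = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    indels = np.zeros((n, n), dtype=int)
    saturated = set()
    for i in range(n):
        sites[i, i] = aln.n_sites
        for j in range(i + 1, n):
            lo = max(ranges[i][0], ranges[j][0])
            hi = min(ranges[i][1], ranges[j][1])
            a = codes[i, lo:hi]
            b = codes[j, lo:hi]
            missing = (a == _MISSING) | (b == _MISSING)
            gap = ((a == _GAP) | (b == _GAP)) & ~missing
            comp = ~missing & ~gap
            n_comp = int(comp.sum())
            if n_comp == 0:
                raise DistanceError(
                    f"{aln.ids[i]} vs {aln.ids[j]}: no comparable columns"
                )
            diff = comp & (a != b)
            ts = int((diff & (_IS_PURINE[a] == _IS_PURINE[b])).sum())
            tv = int(diff.sum()) - ts
            P = ts / n_comp
            Q = tv / n_comp
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            if w1 <= 0.0 or w2 <= 0.0:
                d = np.inf
                saturated.add((aln.ids[i], aln.ids[j]))
            else:
                d = max(-0.5 * np.log(w1) - 0.25 * np.log(w2), 0.0)
            mat[i, j] = mat[j, i] = d
            sites[i, j] = sites[j, i] = n_comp
            indels[i, j] = indels[j, i] = int(gap.sum())
    if saturated:
        off = ~np.eye(n, dtype=bool)
        finite = mat[off & np.isfinite(mat)]
        sentinel = (2.0 * finite.max()
                    if finite.size and finite.max() > 0 else 1.0)
        mat[~np.isfinite(mat)] = sentinel
        warnings.warn(
            f"{len(saturated)} saturated pair(s) set to sentinel "
            f"{sentinel:.4g}",
            stacklevel=2,
        )
    return DistanceMatrix(
        labels=list(aln.ids),
        matrix=mat,
        n_sites=sites,
        indel_columns=indels,
        saturated=saturated,
    )
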