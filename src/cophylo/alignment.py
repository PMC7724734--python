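"""Aligned nucleotide sequence sets.

Sequences are stored as equal-length strings over the alphabet
``{A, C, G, T, -, ?}``.  On input, lowercase is uppercased, ``U`` becomes
``T`` and every IUPAC ambiguity code is mapped to ``?`` (missing).  Terminal
gap runs keep the ``-`` character; the distinction between terminal and
internal gaps is made positionally when distances are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, EmptyAlignmentError

logger = logging.getLogger(__name__)

_VALID = set("ACGT-?")
_AMBIGUITY = set("RYSWKMBDHVN")


def normalize_sequence(seq: str) -> str:
    """Normalize one sequence: uppercase, U->T, ambiguity codes -> '?'."""
    out = []
    for ch in seq.upper():
        if ch == "U":
            ch = "T"
        elif ch in _AMBIGUITY:
            ch = "?"
        elif ch == ".":
            ch = "-"
        if ch not in _VALID:
            raise AlignmentError(f"invalid character {ch!r} in sequence")
        out.append(ch)
    return "".join(out)


def ungapped_length(seq: str) -> int:
    """Number of non-gap, non-missing sites in a (normalized) sequence."""
    return sum(1 for ch in seq if ch not in "-?")


@dataclass
class Alignment:
    """An aligned set of nucleotide sequences.

    Parameters
    ----------
    ids : list of str
        Unique sequence identifiers, in input order.
    matrix : list of str
        One normalized string per id, all of equal length.
    metadata : dict, optional
        Per-sequence labels, e.g. ``{"seqX": {"role": "reference",
        "supergroup": "A"}}``.  Used by strain typing to separate study
        sequences from labelled references.
    excluded : list of (id, ungapped_length) pairs
        Sequences dropped by the minimum-length filter on read.
    """

    ids: list[str]
    matrix: list[str]
    metadata: dict[str, dict] = field(default_factory=dict)
    excluded: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.matrix):
            raise AlignmentError("ids and matrix length mismatch")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.matrix}
        if len(lengths) > 1:
            raise AlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        self.matrix = [normalize_sequence(s) for s in self.matrix]

    # -- container conveniences -------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    def sequence(self, seq_id: str) -> str:
        try:
            return self.matrix[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(seq_id) from None

    def ungapped_lengths(self) -> dict[str, int]:
        return {i: ungapped_length(s) for i, s in zip(self.ids, self.matrix)}

    def to_array(self) -> np.ndarray:
        """Sequences as a (n, sites) array of single-byte characters."""
        return np.array([list(s) for s in self.matrix], dtype="U1")

    def subset(self, ids: Sequence[str]) -> "Alignment":
        keep = list(ids)
        missing = [i for i in keep if i not in self.ids]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Alignment(
            ids=keep,
            matrix=[self.sequence(i) for i in keep],
            metadata={i: self.metadata[i] for i in keep if i in self.metadata},
        )


def read_alignment(
    path,
    min_length: int = 500,
    metadata: Mapping[str, dict] | None = None,
) -> Alignment:
    """Read a pre-aligned FASTA file, dropping short sequences.

    Sequences whose ungapped length is below ``min_length`` sites are
    excluded (the conventional cutoff for short, unreliable marker reads is
    500 bp) and reported both in the log and on ``Alignment.excluded``.

    Raises
    ------
    AlignmentError
        If rows are of unequal length (the file is not an alignment).
    EmptyAlignmentError
        If the filter removes every sequence.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs.append(normalize_sequence(str(record.seq)))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(
            f"sequences are not aligned: row lengths {sorted(lengths)}"
        )
    excluded = []
    keep_ids, keep_seqs = [], []
    for i, s in zip(ids, seqs):
        n = ungapped_length(s)
        if n < min_length:
            excluded.append((i, n))
            logger.info("excluding %s: %d ungapped sites < %d", i, n, min_length)
        else:
            keep_ids.append(i)
            keep_seqs.append(s)
    if not keep_ids:
        raise EmptyAlignmentError(
            f"all {len(ids)} sequences shorter than {min_length} ungapped sites"
        )
    meta = {k: dict(v) for k, v in (metadata or {}).items() if k in keep_ids}
    aln = Alignment(ids=keep_ids, matrix=keep_seqs, metadata=meta)
    aln.excluded = excluded
    return aln


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(aln.ids, aln.matrix):
            fh.write(f">{i}\n{s}\n")
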