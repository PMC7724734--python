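"""Tabular inputs: per-specimen screening records and the binary
host x strain association matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TableError

TISSUES = ("leg", "gut", "reproductive")
CALLS = ("positive", "negative", "not-assessed")
SPECIMEN_COLUMNS = (
    "specimen_id",
    "species",
    "locality",
    "sex",
    "leg",
    "gut",
    "reproductive",
    "control_ok",
)


@dataclass
class SpecimenTable:
    """Per-individual infection screening records.

    Each record carries the specimen id, species, locality code, sex
    (``F``/``M``), one infection call per tissue (``positive`` /
    ``negative`` / ``not-assessed``), and whether the internal PCR control
    amplified.  The overall infection call is derived: positive iff any
    tissue call is positive.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
        if missing:
            raise TableError(f"specimen table missing columns: {missing}")
        if df["specimen_id"].duplicated().any():
            dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"]
            raise TableError(f"duplicate specimen ids: {sorted(set(dupes))}")
        bad_sex = df.loc[~df["sex"].isin(["F", "M"])]
        if len(bad_sex):
            row = bad_sex.iloc[0]
            raise TableError(
                f"invalid sex {row['sex']!r} for specimen "
                f"{row['specimen_id']!r}"
            )
        for tissue in TISSUES:
            bad = df.loc[~df[tissue].isin(CALLS)]
            if len(bad):
                row = bad.iloc[0]
                raise TableError(
                    f"invalid {tissue} call {row[tissue]!r} for specimen "
                    f"{row['specimen_id']!r}"
                )
        if df["control_ok"].dtype != bool:
            mapped = df["control_ok"].map(
                {True: True, False: False, "true": True, "false": False,
                 "True": True, "False": False, 1: True, 0: False,
                 "1": True, "0": False}
            )
            if mapped.isna().any():
                raise TableError("control_ok must be boolean")
            df = df.assign(control_ok=mapped.astype(bool))
        df = df.assign(
            infected=(df[list(TISSUES)] == "positive").any(axis=1)
        )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    def passing_control(self) -> "SpecimenTable":
        """Records whose internal control amplified."""
        return SpecimenTable(self.df.loc[self.df["control_ok"]].copy())

    def tissue_matrix(self, require_complete: bool = True) -> pd.DataFrame:
        """Binary specimens x tissues matrix for the paired-tissue tests.

        Only control-passing records are eligible; with
        ``require_complete`` records with any ``not-assessed`` call are
        dropped.
        """
        df = self.df.loc[self.df["control_ok"], ["specimen_id", *TISSUES]]
        if require_complete:
            complete = (df[list(TISSUES)] != "not-assessed").all(axis=1)
            df = df.loc[complete]
        out = (df.set_index("specimen_id")[list(TISSUES)] == "positive")
        return out.astype(int)

    def subset(self, mask) -> "SpecimenTable":
        return SpecimenTable(self.df.loc[mask].copy())


@dataclass
class AssociationMatrix:
    """Binary incidence of symbiont strains (columns) across hosts (rows)."""

    hosts: list[str]
    strains: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (len(self.hosts), len(self.strains)):
            raise TableError(
                f"association shape {self.matrix.shape} does not match "
                f"{len(self.hosts)} hosts x {len(self.strains)} strains"
            )
        if not np.isin(self.matrix, [0, 1]).all():
            raise TableError("association cells must be 0 or 1")
        empty = [s for j, s in enumerate(self.strains)
                 if self.matrix[:, j].sum() == 0]
        if empty:
            raise TableError(f"strains with no host: {empty}")
        if len(set(self.hosts)) != len(self.hosts):
            raise TableError("duplicate host labels")
        if len(set(self.strains)) != len(self.strains):
            raise TableError("duplicate strain labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def hosts_of(self, strain: str) -> list[str]:
        j = self.strains.index(strain)
        return [h for i, h in enumerate(self.hosts) if self.matrix[i, j]]

    def strains_of(self, host: str) -> list[str]:
        i = self.hosts.index(host)
        return [s for j, s in enumerate(self.strains) if self.matrix[i, j]]

    def links(self) -> list[tuple[str, str]]:
        """(host, strain) pairs in row-major input order."""
        out = []
        for i, h in enumerate(self.hosts):
            for j, s in enumerate(self.strains):
                if self.matrix[i, j]:
                    out.append((h, s))
        return out

    @classmethod
    def from_links(cls, links: Iterable[tuple[str, str]],
                   hosts: Sequence[str] | None = None,
                   strains: Sequence[str] | None = None,
                   ) -> "AssociationMatrix":
        links = list(links)
        if hosts is None:
            hosts = sorted({h for h, _ in links})
        if strains is None:
            strains = sorted({s for _, s in links})
        mat = np.zeros((len(hosts), len(strains)), dtype=int)
        hi = {h: i for i, h in enumerate(hosts)}
        si = {s: j for j, s in enumerate(strains)}
        for h, s in links:
            mat[hi[h], si[s]] = 1
        return cls(hosts=list(hosts), strains=list(strains), matrix=mat)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.hosts,
                            columns=self.strains)


def read_specimen_table(path) -> SpecimenTable:
    """Read a specimen CSV with the declared header columns."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"specimen CSV missing columns: {missing}")
    return SpecimenTable(df)


def write_specimen_table(table: SpecimenTable, path) -> None:
    table.df.drop(columns=["infected"]).to_csv(path, index=False)


def read_association(path) -> AssociationMatrix:
    """Read a hosts x strains TSV with hosts in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.isin(values, [0, 1]).all():
        raise TableError("association cells must be 0 or 1")
    return AssociationMatrix(
        hosts=[str(x) for x in df.index],
        strains=[str(c) for c in df.columns],
        matrix=values.astype(int),
    )


def write_association(assoc: AssociationMatrix, path) -> None:
    assoc.to_dataframe().to_csv(path, sep="\t")
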