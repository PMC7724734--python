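"""Bundled data: per-species, per-locality *Wolbachia* screening counts
from a published field survey of wild mosquitoes across 12 Singapore
localities (271 adults screened by tissue-specific PCR)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tables import SpecimenTable


def survey_counts() -> pd.DataFrame:
    """The survey's infected/screened counts per species and locality."""
    ref = resources.files("cophylo.data") / "singapore_survey_counts.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def specimens_from_counts(counts: pd.DataFrame) -> SpecimenTable:
    """Expand aggregate counts into one record per screened individual.

    Infected individuals are given a positive reproductive-tissue call
    (the survey's dominant infection site); only the overall call matters
    for prevalence tabulation.  Sex is unknown at this aggregation level
    and is filled alternately so both sexes appear.
    """
    rows = []
    for _, rec in counts.iterrows():
        for i in range(int(rec["screened"])):
            infected = i < int(rec["infected"])
            rows.append(
                {
                    "specimen_id": f"{rec['species']}|{rec['locality']}|{i}",
                    "species": rec["species"],
                    "locality": rec["locality"],
                    "sex": "F" if i % 2 == 0 else "M",
                    "leg": "negative",
                    "gut": "negative",
                    "reproductive": "positive" if infected else "negative",
                    "control_ok": True,
                }
            )
    return SpecimenTable(pd.DataFrame(rows))


def survey_specimens() -> SpecimenTable:
    """The bundled survey expanded to individual-level records."""
    return specimens_from_counts(survey_counts())
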