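"""Infection prevalence, tissue tropism, and the sex effect.

Three pieces: (1) prevalence tabulation by species (and optionally
locality) with a totals row; (2) paired-binary tissue-tropism tests —
Cochran's Q across the three tissues with McNemar post hoc pairs; (3) a
binary logistic regression of infection on sex, fitted on the subset of
species with roughly balanced sexes (the minority sex at least 60% of the
majority, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import CophyloError, SeparationError, TableError
from .tables import TISSUES, SpecimenTable


def percent(infected: int, screened: int) -> float:
    """Prevalence percentage rounded to one decimal (e.g. 119/271 -> 43.9)."""
    if screened <= 0:
        raise ValueError("screened count must be positive")
    return round(100.0 * infected / screened, 1)


@dataclass
class PrevalenceTable:
    """Per-group infection counts with a totals row."""

    rows: pd.DataFrame  # index: group key(s); columns infected, screened, pct
    by: tuple[str, ...]

    @property
    def totals(self) -> tuple[int, int, float]:
        infected = int(self.rows["infected"].sum())
        screened = int(self.rows["screened"].sum())
        return infected, screened, percent(infected, screened)

    def positive_groups(self) -> list:
        return list(self.rows.index[self.rows["infected"] > 0])

    def summary(self) -> str:
        infected, screened, pct = self.totals
        return (
            self.rows.to_string()
            + f"\nTotal: {infected}/{screened} ({pct}%)"
        )


def prevalence_table(
    table: SpecimenTable, by: str | tuple[str, ...] = "species"
) -> PrevalenceTable:
    """Tabulate infected/screened counts and percentages per group.

    ``by`` may be ``"species"`` or ``("species", "locality")``.  Groups
    with zero screened records cannot occur (they simply have no rows).
    """
    keys = (by,) if isinstance(by, str) else tuple(by)
    for key in keys:
        if key not in table.df.columns:
            raise TableError(f"unknown grouping key {key!r}")
    grouped = table.df.groupby(list(keys), observed=True)["infected"].agg(
        infected="sum", screened="count"
    )
    grouped["infected"] = grouped["infected"].astype(int)
    grouped["pct"] = [
        percent(i, s) for i, s in zip(grouped["infected"], grouped["screened"])
    ]
    return PrevalenceTable(rows=grouped, by=keys)


@dataclass(frozen=True)
class TissueTestResult:
    """Cochran's Q over tissues with McNemar post hoc pairs."""

    tissue_counts: dict[str, int]
    n_subjects: int
    n_informative: int
    q: float
    df: int
    p_value: float
    pairwise: dict[tuple[str, str], float]
    pairwise_method: str
    degenerate_pairs: tuple = ()

    def summary(self) -> str:
        counts = ", ".join(
            f"{t}: {c}/{self.n_subjects} "
            f"({percent(c, self.n_subjects)}%)"
            for t, c in self.tissue_counts.items()
        )
        lines = [counts,
                 f"Cochran's Q = {self.q:.4g}, df = {self.df}, "
                 f"P = {self.p_value:.4g}"]
        for (a, b), p in self.pairwise.items():
            lines.append(f"McNemar {a} vs {b} ({self.pairwise_method}): "
                         f"P = {p:.4g}")
        return "\n".join(lines)


def cochran_q(m: np.ndarray | pd.DataFrame) -> tuple[float, int, float, int]:
    """Cochran's Q test on a subjects x conditions binary matrix.

    Returns ``(Q, df, P, n_informative)`` where informative subjects are
    those with a mixed response row (all-0 and all-k rows contribute
    nothing to either the numerator or denominator).  With zero
    informative subjects the conditions are indistinguishable and the
    degenerate convention Q = 0, P = 1 is returned, flagged by
    ``n_informative == 0``.

    Q = (k-1) * [k * sum(C_j^2) - (sum C_j)^2] / [k * sum(R_i) - sum(R_i^2)]
    """
    mat = np.asarray(m, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2 or mat.shape[0] == 0:
        raise ValueError("need a non-empty subjects x (>=2 conditions) matrix")
    if not np.isin(mat, [0, 1]).all():
        raise ValueError("matrix must be binary with no missing cells")
    k = mat.shape[1]
    R = mat.sum(axis=1)
    C = mat.sum(axis=0)
    n_informative = int(np.sum((R > 0) & (R < k)))
    denom = k * R.sum() - np.sum(R**2)
    if denom == 0 or n_informative == 0:
        return 0.0, k - 1, 1.0, 0
    q = (k - 1) * (k * np.sum(C**2) - C.sum() ** 2) / denom
    df = k - 1
    p = float(scipy.stats.chi2.sf(q, df))
    return float(q), df, p, n_informative


def mcnemar_pairwise(
    m: pd.DataFrame,
    correction: str = "exact",
    adjust: str = "none",
) -> tuple[dict[tuple[str, str], float], tuple]:
    """McNemar tests for every unordered pair of conditions.

    ``correction``: ``"exact"`` (two-sided exact binomial on the
    discordant counts, the default), ``"chisq"`` (uncorrected chi-square)
    or ``"chisq-cc"`` (continuity-corrected).  ``adjust`` applies
    ``"bonferroni"`` or ``"holm"`` across the pairs.  Pairs with no
    discordant observations get P = 1 and are listed as degenerate.
    """
    if correction not in ("exact", "chisq", "chisq-cc"):
        raise ValueError(f"unknown correction {correction!r}")
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    cols = list(m.columns)
    raw: dict[tuple[str, str], float] = {}
    degenerate = []
    for a, b in combinations(cols, 2):
        x = np.asarray(m[a], dtype=int)
        y = np.asarray(m[b], dtype=int)
        b10 = int(np.sum((x == 1) & (y == 0)))
        b01 = int(np.sum((x == 0) & (y == 1)))
        if b10 + b01 == 0:
            raw[(a, b)] = 1.0
            degenerate.append((a, b))
            continue
        table = [[0, b10], [b01, 0]]
        res = _sm_mcnemar(
            table,
            exact=(correction == "exact"),
            correction=(correction == "chisq-cc"),
        )
        raw[(a, b)] = min(float(res.pvalue), 1.0)
    if adjust != "none":
        pairs = list(raw)
        pvals = np.array([raw[p] for p in pairs])
        if adjust == "bonferroni":
            adj = np.minimum(pvals * len(pairs), 1.0)
        else:  # holm
            order = np.argsort(pvals)
            adj = np.empty_like(pvals)
            running = 0.0
            for rank, idx in enumerate(order):
                val = min((len(pairs) - rank) * pvals[idx], 1.0)
                running = max(running, val)
                adj[idx] = running
        raw = dict(zip(pairs, adj))
    return raw, tuple(degenerate)


def tissue_tropism_test(
    table: SpecimenTable,
    correction: str = "exact",
    adjust: str = "none",
) -> TissueTestResult:
    """Cochran's Q + McNemar post hoc on the per-tissue infection calls.

    Only internal-control-passing specimens with a call for every tissue
    enter the tests.
    """
    m = table.tissue_matrix(require_complete=True)
    q, df, p, n_inf = cochran_q(m)
    pairwise, degenerate = mcnemar_pairwise(m, correction=correction,
                                            adjust=adjust)
    counts = {t: int(m[t].sum()) for t in m.columns}
    return TissueTestResult(
        tissue_counts=counts,
        n_subjects=len(m),
        n_informative=n_inf,
        q=q,
        df=df,
        p_value=p,
        pairwise=pairwise,
        pairwise_method=correction,
        degenerate_pairs=degenerate,
    )


def sex_balance_subset(
    table: SpecimenTable, min_ratio: float = 0.6
) -> SpecimenTable:
    """Keep species whose minority sex is at least ``min_ratio`` of the
    majority sex (inclusive); species with a single sex are dropped."""
    keep_species = []
    for species, grp in table.df.groupby("species"):
        nf = int((grp["sex"] == "F").sum())
        nm = int((grp["sex"] == "M").sum())
        if nf == 0 or nm == 0:
            continue
        if min(nf, nm) / max(nf, nm) >= min_ratio:
            keep_species.append(species)
    return table.subset(table.df["species"].isin(keep_species))


@dataclass(frozen=True)
class SexEffectResult:
    """Logistic regression of infection on sex (male indicator)."""

    odds_ratio: float
    coef: float
    std_err: float
    z: float
    df: int
    p_value: float
    n: int
    pct_male: float
    species: tuple[str, ...]

    def summary(self) -> str:
        return (
            f"infection ~ sex on {self.n} specimens "
            f"({self.pct_male:.1f}% male, {len(self.species)} species): "
            f"OR(male) = {self.odds_ratio:.3g}, Z = {self.z:.3g}, "
            f"df = {self.df}, P = {self.p_value:.3g}"
        )

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        zcrit = scipy.stats.norm.ppf(1 - alpha / 2)
        return (self.coef - zcrit * self.std_err,
                self.coef + zcrit * self.std_err)


def logistic_sex_effect(table: SpecimenTable) -> SexEffectResult:
    """Fit infection ~ 1 + male by IRLS and report the male odds ratio.

    Raises :class:`SeparationError` on complete separation (one sex all
    infected or all uninfected in a way that sends the estimate to
    infinity).
    """
    df = table.df
    y = df["infected"].astype(int).to_numpy()
    male = (df["sex"] == "M").astype(int).to_numpy()
    if len(np.unique(male)) < 2:
        raise CophyloError("both sexes must be present")
    if len(np.unique(y)) < 2:
        raise CophyloError("both infection outcomes must be present")
    # complete separation in a 2x2 design = an empty cell
    cells = pd.crosstab(male, y)
    if cells.shape != (2, 2) or (cells.to_numpy() == 0).any():
        raise SeparationError(
            "complete separation: a sex-by-outcome cell is empty"
        )
    X = sm.add_constant(male.astype(float))
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=100, tol=1e-8)
    except PerfectSeparationError as exc:  # pragma: no cover - guarded above
        raise SeparationError(str(exc)) from exc
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    z = coef / se
    p = float(2 * scipy.stats.norm.sf(abs(z)))
    return SexEffectResult(
        odds_ratio=float(np.exp(coef)),
        coef=coef,
        std_err=se,
        z=z,
        df=len(y) - 2,
        p_value=p,
        n=len(y),
        pct_male=100.0 * male.mean(),
        species=tuple(sorted(df["species"].unique())),
    )
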