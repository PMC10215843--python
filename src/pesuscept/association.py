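"""Case-control SNP association statistics.

Implements the contingency-table toolkit for biallelic SNP case-control
studies: genotype and allele chi-square tests, carrier tests for two-SNP
genotype combinations, risk-marker r x c tests within the patient group,
a Hardy-Weinberg goodness-of-fit QC test, and odds ratios with Woolf
confidence intervals.

Correction policy: main genotype/allele tests use the uncorrected Pearson
chi-square; the 2x2 carrier tables for genotype combinations apply the
Yates continuity correction exactly when some observed cell is zero, with
the correction capped so no cell contribution goes negative. p-values are
carried at full precision.

Tables are labeled pandas DataFrames so results stay auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "AssociationResult",
    "OddsRatioResult",
    "DegenerateTableError",
    "genotype_counts_from_records",
    "allele_counts",
    "chi_square",
    "genotype_association",
    "allele_association",
    "combined_genotype_association",
    "carrier_test",
    "risk_marker_association",
    "hwe_test",
    "odds_ratio",
]

GROUPS = ("control", "case")


class DegenerateTableError(ValueError):
    """Fewer than 2 informative rows or columns after dropping empties."""


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    haldane: bool = False  # whether the +0.5 zero-cell correction was applied


@dataclass
class AssociationResult:
    """One contingency analysis: statistic, df, p, correction, effect, table."""

    statistic: float
    df: int
    p_value: float
    correction: str  # "none" or "yates"
    table: pd.DataFrame
    effect: OddsRatioResult | None = None
    estimable: bool = True
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "correction": self.correction,
            "estimable": self.estimable,
            "effect": None
            if self.effect is None
            else {
                "odds_ratio": self.effect.estimate,
                "ci95": [self.effect.ci_low, self.effect.ci_high],
                "haldane": self.effect.haldane,
            },
            "table": {
                "rows": list(map(str, self.table.index)),
                "cols": list(map(str, self.table.columns)),
                "cells": self.table.to_numpy().tolist(),
            },
            "notes": list(self.notes),
        }


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-group genotype counts for one biallelic SNP.

    Counts are ordered (hom_ref, het, hom_alt); allele order is fixed by the
    declared ``ref_allele``/``alt_allele`` pair, and genotype strings are
    unordered ("AT" == "TA").
    """

    snp_id: str
    ref_allele: str
    alt_allele: str
    control: tuple  # (hom_ref, het, hom_alt)
    case: tuple

    def __post_init__(self):
        for grp in (self.control, self.case):
            if len(grp) != 3 or any(c < 0 for c in grp):
                raise ValueError("counts must be three non-negative integers")

    def genotype_labels(self):
        r, a = self.ref_allele, self.alt_allele
        return (r + r, r + a, a + a)

    def counts(self, group: str) -> tuple:
        return {"control": self.control, "case": self.case}[group]

    def genotype_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.control, self.case],
            index=list(GROUPS),
            columns=list(self.genotype_labels()),
            dtype=int,
        )

    def normalize_genotype(self, g: str) -> str:
        """Map an unordered genotype string onto the canonical label."""
        labels = self.genotype_labels()
        if g in labels:
            return g
        flipped = g[::-1]
        if flipped in labels:
            return flipped
        raise ValueError(f"unknown genotype {g!r} for SNP {self.snp_id}")


def genotype_counts_from_records(
    records: pd.DataFrame, snp_id: str, ref_allele: str, alt_allele: str
) -> GenotypeCounts:
    """Aggregate subject-level genotype records into per-group counts."""
    labels = (ref_allele * 2, ref_allele + alt_allele, alt_allele * 2)
    out = {}
    for group in GROUPS:
        sub = records.loc[records["status"] == group, snp_id]
        counts = [0, 0, 0]
        for g in sub:
            g = str(g)
            key = g if g in labels else g[::-1]
            if key not in labels:
                raise ValueError(f"unknown genotype {g!r} for SNP {snp_id}")
            counts[labels.index(key)] += 1
        out[group] = tuple(counts)
    return GenotypeCounts(snp_id, ref_allele, alt_allele, out["control"], out["case"])


def allele_counts(gc: GenotypeCounts) -> pd.DataFrame:
    """Per-group allele counts: count(X) = 2*hom_X + het; total = 2*subjects."""
    rows = {}
    for group in GROUPS:
        hom_ref, het, hom_alt = gc.counts(group)
        rows[group] = [2 * hom_ref + het, 2 * hom_alt + het]
    return pd.DataFrame(rows, index=[gc.ref_allele, gc.alt_allele]).T.astype(int)


def _as_table(t) -> pd.DataFrame:
    if isinstance(t, pd.DataFrame):
        tab = t.copy()
    else:
        arr = np.asarray(t)
        tab = pd.DataFrame(arr)
    if (tab.to_numpy() < 0).any():
        raise ValueError("contingency cells must be non-negative")
    return tab


def chi_square(table, correction: str = "none") -> AssociationResult:
    """Pearson chi-square test of independence on an r x c table.

    Empty rows/columns are dropped with a warning; fewer than two remaining
    rows or columns raises :class:`DegenerateTableError`. ``correction=
    "yates"`` (2x2 only) uses ``(max(|O-E|-0.5, 0))^2 / E``. For 2x2 tables
    the odds ratio and Woolf 95% CI are attached when estimable.
    """
    if correction not in ("none", "yates"):
        raise ValueError("correction must be 'none' or 'yates'")
    tab = _as_table(table)
    obs = tab.to_numpy(dtype=float)
    keep_rows = obs.sum(axis=1) > 0
    keep_cols = obs.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping empty rows/columns from contingency table")
        tab = tab.loc[keep_rows, keep_cols]
        obs = tab.to_numpy(dtype=float)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DegenerateTableError(
            f"table has shape {tab.shape} after dropping empty lines"
        )
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    dev = np.abs(obs - expected)
    if correction == "yates":
        if tab.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    effect = None
    notes = []
    if tab.shape == (2, 2):
        try:
            effect = odds_ratio(tab)
        except DegenerateTableError as exc:
            notes.append(f"odds ratio not estimable: {exc}")
    return AssociationResult(
        statistic=statistic,
        df=df,
        p_value=p,
        correction=correction,
        table=tab.astype(int),
        effect=effect,
        notes=notes,
    )


def genotype_association(gc: GenotypeCounts) -> AssociationResult:
    """2 x 3 uncorrected chi-square of genotype frequencies (df = 2)."""
    return chi_square(gc.genotype_table(), correction="none")


def allele_association(gc: GenotypeCounts) -> AssociationResult:
    """2 x 2 uncorrected chi-square of allele frequencies."""
    return chi_square(allele_counts(gc), correction="none")


def combined_genotype_association(
    records: pd.DataFrame, gc1: GenotypeCounts, gc2: GenotypeCounts
) -> dict:
    """Carrier tests for every observed two-SNP genotype combination.

    For each combination (e.g. "TT-AA"), a 2x2 carrier/non-carrier x
    case/control table is tested; the Yates correction is applied exactly
    when any observed cell is zero. Subjects genotyped at only one SNP are
    excluded (count recorded under the ``"_excluded"`` key). Combinations
    absent from both groups yield a non-estimable result.
    """
    cols = [gc1.snp_id, gc2.snp_id]
    complete = records.dropna(subset=cols)
    n_excluded = len(records) - len(complete)
    combos = {}
    for labels1 in gc1.genotype_labels():
        for labels2 in gc2.genotype_labels():
            combos[f"{labels1}-{labels2}"] = (labels1, labels2)
    results = {"_excluded": n_excluded}
    g1 = complete[gc1.snp_id].map(gc1.normalize_genotype)
    g2 = complete[gc2.snp_id].map(gc2.normalize_genotype)
    status = complete["status"]
    for name, (a, b) in combos.items():
        carrier = (g1 == a) & (g2 == b)
        cells = {}
        for group in GROUPS:
            in_group = status == group
            cells[group] = (
                int((carrier & in_group).sum()),
                int((~carrier & in_group).sum()),
            )
        tab = pd.DataFrame(
            [cells["control"], cells["case"]],
            index=list(GROUPS),
            columns=["carrier", "non-carrier"],
        )
        degenerate_note = None
        if tab["carrier"].sum() == 0:
            degenerate_note = "combination absent from both groups"
        elif tab["non-carrier"].sum() == 0:
            degenerate_note = "every subject carries this combination"
        if degenerate_note is not None:
            results[name] = AssociationResult(
                statistic=float("nan"),
                df=1,
                p_value=float("nan"),
                correction="none",
                table=tab,
                estimable=False,
                notes=[degenerate_note],
            )
            continue
        corr = "yates" if (tab.to_numpy() == 0).any() else "none"
        results[name] = chi_square(tab, correction=corr)
    return results


def carrier_test(
    n_carrier_control: int,
    n_control: int,
    n_carrier_case: int,
    n_case: int,
) -> AssociationResult:
    """Carrier/non-carrier 2x2 test from aggregated carrier counts.

    Applies the same correction policy as
    :func:`combined_genotype_association`: Yates when any observed cell is
    zero, uncorrected otherwise.
    """
    tab = pd.DataFrame(
        [
            [n_carrier_control, n_control - n_carrier_control],
            [n_carrier_case, n_case - n_carrier_case],
        ],
        index=list(GROUPS),
        columns=["carrier", "non-carrier"],
    )
    corr = "yates" if (tab.to_numpy() == 0).any() else "none"
    return chi_square(tab, correction=corr)


def risk_marker_association(
    records: pd.DataFrame, marker: str, snp_id: str, gc: GenotypeCounts
) -> AssociationResult:
    """r x c chi-square of a clinical risk marker against genotype, within cases."""
    cases = records.loc[records["status"] == "case"].dropna(subset=[marker, snp_id])
    levels = list(dict.fromkeys(cases[marker]))
    if len(levels) < 2:
        raise DegenerateTableError(
            f"risk marker {marker!r} has a single level among cases"
        )
    geno = cases[snp_id].map(gc.normalize_genotype)
    tab = pd.crosstab(cases[marker], geno).reindex(
        columns=list(gc.genotype_labels()), fill_value=0
    )
    return chi_square(tab, correction="none")


def hwe_test(counts, n_total: int | None = None) -> AssociationResult:
    """Hardy-Weinberg goodness-of-fit chi-square for one group (df = 1).

    ``counts`` is (hom_ref, het, hom_alt). Expected counts come from the
    sample allele frequency; a monomorphic sample is flagged non-estimable.
    """
    hom_ref, het, hom_alt = (int(c) for c in counts)
    n = hom_ref + het + hom_alt
    if n <= 0:
        raise ValueError("empty group")
    q = (2 * hom_alt + het) / (2 * n)
    tab = pd.DataFrame(
        {"observed": [hom_ref, het, hom_alt]}, index=["hom_ref", "het", "hom_alt"]
    )
    if q in (0.0, 1.0):
        return AssociationResult(
            statistic=float("nan"),
            df=1,
            p_value=float("nan"),
            correction="none",
            table=tab,
            estimable=False,
            notes=["monomorphic sample: HWE not estimable"],
        )
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    statistic = float((((np.array([hom_ref, het, hom_alt]) - expected) ** 2) / expected).sum())
    p = float(stats.chi2.sf(statistic, 1))
    tab["expected"] = expected
    return AssociationResult(
        statistic=statistic, df=1, p_value=p, correction="none", table=tab
    )


def odds_ratio(table) -> OddsRatioResult:
    """Odds ratio of a 2x2 table with a Woolf-logit 95% CI.

    When any cell is zero, the Haldane-Anscombe +0.5 correction is added to
    every cell. Two zero cells in one row or column make the OR
    non-estimable (:class:`DegenerateTableError`).
    """
    tab = _as_table(table).to_numpy(dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    zero_lines = ((tab == 0).all(axis=0).any()) or ((tab == 0).all(axis=1).any())
    if zero_lines:
        raise DegenerateTableError("a full row or column of zeros")
    haldane = bool((tab == 0).any())
    if haldane:
        tab = tab + 0.5
    a, b = tab[0]
    c, d = tab[1]
    est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(est) + np.array([-1, 1]) * 1.959963984540054 * se)
    return OddsRatioResult(float(est), float(lo), float(hi), haldane=haldane)
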