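"""Group comparisons between CAD- and CAD+ patients (baseline characteristics).

Categorical traits are compared with the uncorrected Pearson chi-squared
test on the 2x2 table (optionally routed to Fisher's exact test when an
expected cell count is below 5), continuous traits with the Wilcoxon rank
sum test.  The chi-squared statistic deliberately carries no Yates
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DegenerateTableError, PatientRecord, records_to_frame

#: relative tolerance when comparing hypergeometric pmf values (two-sided Fisher)
_FISHER_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows CAD-/CAD+ and columns trait present/absent."""

    a: int  # CAD-, present
    b: int  # CAD-, absent
    c: int  # CAD+, present
    d: int  # CAD+, absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def min_expected(self) -> float:
        r1, r2, c1, c2 = self.margins
        return min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / self.n


@dataclass
class GroupComparison:
    variable: str
    test_used: str  # chi2_uncorrected | fisher_exact | wilcoxon | none
    statistic: float
    p: float
    note: str = ""


def chi2_2x2_uncorrected(
    t: ContingencyTable2x2, variable: str = ""
) -> GroupComparison:
    """Pearson chi-squared on a 2x2 table, 1 df, no continuity correction."""
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError(f"zero margin in table for {variable or 'trait'}")
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    chi2 = num / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return GroupComparison(variable, "chi2_uncorrected", float(chi2), p)


def fisher_exact_2x2(t: ContingencyTable2x2, variable: str = "") -> GroupComparison:
    """Two-sided Fisher exact test by the probability-ordering convention.

    p is the sum of hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (up to a relative tolerance when comparing pmf values).
    """
    r1, _r2, c1, _c2 = t.margins
    n = t.n
    k_min = max(0, r1 + c1 - n)
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n, c1, r1)
    p_obs = pmf[ks == t.a][0]
    p = float(pmf[pmf <= p_obs * (1 + _FISHER_RTOL)].sum())
    return GroupComparison(variable, "fisher_exact", float(t.a), min(p, 1.0))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Wilcoxon/Mann-Whitney rank-sum test with mid-ranks for ties.

    Exact two-sided p by enumeration when the combined sample has at most
    12 observations and no ties; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return GroupComparison(
            variable, "wilcoxon", 0.0, 1.0, note="degenerate: all values identical"
        )
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 12 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return GroupComparison(variable, "wilcoxon", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Table-1 style report
# ---------------------------------------------------------------------------

_CATEGORICAL = (
    "sex_male",
    "hypertension",
    "diabetes",
    "hyperlipidaemia",
    "current_smoking",
    "smoking_history_gt10py",
    "smurfless",
    "family_history",
    "antiplatelet",
    "statin",
    "beta_blocker",
    "ace_arb",
)

# continuous variables with their declared presentation
_CONTINUOUS = {"age": "mean_sd", "bmi": "mean_sd", "gensini": "median_iqr"}


def table_for_variable(df: pd.DataFrame, var: str) -> ContingencyTable2x2:
    cad = df["cad_status"].astype(bool)
    present = df[var].astype(bool)
    return ContingencyTable2x2(
        a=int((~cad & present).sum()),
        b=int((~cad & ~present).sum()),
        c=int((cad & present).sum()),
        d=int((cad & ~present).sum()),
    )


def _summarise_continuous(values: np.ndarray, kind: str) -> str:
    if kind == "mean_sd":
        return f"{np.mean(values):.1f} ({np.std(values, ddof=1):.1f})"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.1f} ({q3 - q1:.1f})"


def build_table1(
    records: Sequence[PatientRecord], rule: str = "chi2_always"
) -> pd.DataFrame:
    """Baseline-characteristics comparison between CAD- and CAD+ groups.

    rule = "chi2_always" applies the uncorrected chi-squared to every
    categorical trait; "paper_footnote" routes traits with any expected
    cell count below 5 to Fisher's exact test instead.
    """
    if rule not in ("chi2_always", "paper_footnote"):
        raise ValueError(f"unknown table1 rule {rule!r}")
    df = records_to_frame(records)
    df["sex_male"] = df["sex"] == "male"
    if not df["cad_status"].nunique() == 2:
        raise ValueError("records must span both CAD groups")
    cad = df["cad_status"].astype(bool)
    rows = []
    for var in _CATEGORICAL:
        t = table_for_variable(df, var)
        n_neg, n_pos = t.a, t.c
        summary = (
            f"{n_neg + n_pos} ({100 * (n_neg + n_pos) / t.n:.0f}%)",
            f"{n_neg} ({100 * n_neg / (t.a + t.b):.0f}%)",
            f"{n_pos} ({100 * n_pos / (t.c + t.d):.0f}%)",
        )
        try:
            if rule == "paper_footnote" and t.min_expected() < 5:
                cmp_ = fisher_exact_2x2(t, var)
            else:
                cmp_ = chi2_2x2_uncorrected(t, var)
            rows.append((var, *summary, cmp_.test_used, cmp_.statistic, cmp_.p, cmp_.note))
        except DegenerateTableError:
            rows.append((var, *summary, "none", math.nan, math.nan, "degenerate table"))
    for var, kind in _CONTINUOUS.items():
        values = df[var].to_numpy(dtype=float)
        ok = ~np.isnan(values)
        if ok.sum() < 4:
            continue
        v_neg, v_pos = values[ok & ~cad.to_numpy()], values[ok & cad.to_numpy()]
        cmp_ = wilcoxon_rank_sum(v_neg, v_pos, var)
        rows.append(
            (
                var,
                _summarise_continuous(values[ok], kind),
                _summarise_continuous(v_neg, kind),
                _summarise_continuous(v_pos, kind),
                cmp_.test_used,
                cmp_.statistic,
                cmp_.p,
                cmp_.note,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["variable", "all", "cad_neg", "cad_pos", "test_used", "statistic", "p", "note"],
    )
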