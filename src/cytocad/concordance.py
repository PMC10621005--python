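"""Cross-cohort replication: fold change of group means and concordance.

For each subset the ratio of the CAD+ group mean to the CAD- group mean is
computed within the discovery and validation cohorts separately; agreement
between the two fold-change vectors is then tested with Pearson's
correlation (two-sided t test, n-2 df).  Also provides the complete-linkage
Euclidean clustering used for the cohort heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .datatypes import PatientRecord, ProportionsMatrix, records_to_frame


@dataclass
class FoldChangeRecord:
    subset_id: str
    fc_discovery: float
    fc_validation: float
    defined: bool = True


@dataclass
class ConcordanceResult:
    n: int
    r: float
    t: float
    p: float
    scale: str = "raw"
    n_excluded: int = 0


def fold_change_of_means(
    matrix: ProportionsMatrix, records: Sequence[PatientRecord]
) -> list[FoldChangeRecord]:
    """Per-subset CAD+/CAD- ratio of arithmetic means, per cohort."""
    df = records_to_frame(records)
    values = matrix.aligned_to(list(df.index)).values
    out = []
    means: dict[str, pd.Series] = {}
    for cohort in ("discovery", "validation"):
        for cad in (False, True):
            mask = (df["cohort"] == cohort) & (df["cad_status"] == cad)
            if mask.sum() == 0:
                raise ValueError(f"empty CAD{'+' if cad else '-'} group in {cohort}")
            means[f"{cohort}_{cad}"] = values.loc[mask.to_numpy()].mean(axis=0)
    for sid in values.columns:
        fcs = {}
        defined = True
        for cohort in ("discovery", "validation"):
            denom = means[f"{cohort}_False"][sid]
            num = means[f"{cohort}_True"][sid]
            if denom == 0:
                defined = False
                fcs[cohort] = np.nan
            else:
                fcs[cohort] = num / denom
        out.append(
            FoldChangeRecord(sid, fcs["discovery"], fcs["validation"], defined)
        )
    return out


def pearson_concordance(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r with its zero-correlation t statistic and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a fold-change vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, *correlation_t_test(r, n)


def correlation_t_test(r: float, n: int) -> tuple[float, float]:
    """t = r*sqrt(n-2)/sqrt(1-r^2) and its two-sided p (n-2 df)."""
    if abs(r) >= 1.0:
        return float(np.inf) * np.sign(r), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(t), float(2 * stats.t.sf(abs(t), df=n - 2))


def concordance_test(
    fc: Sequence[FoldChangeRecord],
    scale: str = "raw",
    subset_ids: Sequence[str] | None = None,
) -> ConcordanceResult:
    """Correlation of discovery vs validation fold changes.

    ``subset_ids`` restricts the test to a named set (by default all usable
    records are included); records with undefined fold change are excluded
    pairwise and counted.
    """
    if subset_ids is not None:
        keep = set(subset_ids)
        fc = [r for r in fc if r.subset_id in keep]
    usable = [r for r in fc if r.defined and np.isfinite(r.fc_discovery)
              and np.isfinite(r.fc_validation)]
    n_excluded = len(fc) - len(usable)
    if len(usable) < 3:
        raise ValueError("need at least 3 usable fold-change records")
    x = np.array([r.fc_discovery for r in usable])
    y = np.array([r.fc_validation for r in usable])
    if scale == "log":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log scale requires positive fold changes")
        x, y = np.log(x), np.log(y)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    r, t, p = pearson_concordance(x, y)
    return ConcordanceResult(len(usable), r, t, p, scale, n_excluded)


@dataclass
class ClusterResult:
    patient_order: list[str]
    subset_order: list[str]
    patient_linkage: np.ndarray
    subset_linkage: np.ndarray


def hierarchical_cluster(values: pd.DataFrame) -> ClusterResult:
    """Agglomerative clustering (Euclidean, complete linkage) on both axes.

    Returns merge heights (scipy linkage matrices) and leaf orders for
    patients (rows) and subsets (columns), as drawn in a clustered heat map.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    lk_rows = linkage(values.to_numpy(dtype=float), method="complete", metric="euclidean")
    order_rows = [values.index[i] for i in leaves_list(lk_rows)]
    if values.shape[1] >= 2:
        lk_cols = linkage(
            values.to_numpy(dtype=float).T, method="complete", metric="euclidean"
        )
        order_cols = [values.columns[i] for i in leaves_list(lk_cols)]
    else:
        lk_cols = np.empty((0, 4))
        order_cols = list(values.columns)
    return ClusterResult(order_rows, order_cols, lk_rows, lk_cols)
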