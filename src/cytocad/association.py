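"""Per-subset logistic regression of CAD status on subset proportion.

For every subset two models are available: proportion only (unadjusted) and
proportion + age + sex (adjusted).  Effects are reported as odds ratios per
one-percentage-point increase with 95% Wald intervals, mirroring the forest
plot presentation: OR = exp(beta), CI = exp(beta +/- 1.959964 * se), and a
significance glyph per tier (deg, *, **, ***).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import (
    AnalysisConfig,
    ConvergenceError,
    PatientRecord,
    ProportionsMatrix,
    SeparationError,
    SubsetCatalog,
    records_to_frame,
)

_Z975 = 1.959964


def fit_logistic(
    y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit; returns (coefficients, covariance).

    ``X`` holds the predictors without an intercept column; an intercept is
    prepended, so coefficients[0] is the intercept.  Covariance is the
    inverse observed information.  Raises SeparationError when the fit
    diverges (|beta| > 20 on standardised predictors) and ConvergenceError
    when Newton iteration fails within 100 steps.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise ValueError(f"constant predictor column: {names[int(np.argmin(sds))]!r}")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-10, disp=0
            )
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular information matrix: {e}") from None
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)):
        raise SeparationError("non-finite coefficients (perfect separation)")
    std_beta = params[1:] * sds
    if np.any(np.abs(std_beta) > 20):
        j = int(np.argmax(np.abs(std_beta)))
        raise SeparationError(
            f"predictor {names[j]!r} separates the outcome (|beta_std| > 20)"
        )
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge in 100 iterations")
    return params, np.asarray(res.cov_params())


def tier_glyph(p: float, tiers: Sequence[float] = (0.1, 0.05, 0.01, 0.001)) -> str:
    """Significance mark: deg for p<0.1, then *, **, *** at 0.05/0.01/0.001."""
    glyphs = ("deg", "*", "**", "***")
    mark = ""
    for threshold, glyph in zip(sorted(tiers, reverse=True), glyphs):
        if p < threshold:
            mark = glyph
    return mark


@dataclass
class AssociationRecord:
    subset_id: str
    model: str  # unadjusted | age_sex_adjusted
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    tier: str
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.note == ""


def _record_from_fit(
    subset_id: str, model: str, beta: float, se: float, tiers: Sequence[float]
) -> AssociationRecord:
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return AssociationRecord(
        subset_id=subset_id,
        model=model,
        beta=float(beta),
        se=float(se),
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        p=p,
        tier=tier_glyph(p, tiers),
    )


def run_panel(
    matrix: ProportionsMatrix,
    records: Sequence[PatientRecord],
    adjust: bool,
    tiers: Sequence[float] = (0.1, 0.05, 0.01, 0.001),
) -> list[AssociationRecord]:
    """One logistic fit per subset; proportion enters on the percent scale.

    When ``adjust`` is set, age (years) and a male indicator are included.
    Subsets with zero variance are flagged untestable rather than dropped.
    """
    df = records_to_frame(records)
    aligned = matrix.aligned_to(list(df.index)).values
    y = df["cad_status"].to_numpy(dtype=float)
    if min((y == 0).sum(), (y == 1).sum()) < 10:
        raise ValueError("need at least 10 patients per outcome class")
    model_name = "age_sex_adjusted" if adjust else "unadjusted"
    covars = (
        np.column_stack(
            [df["age"].to_numpy(float), (df["sex"] == "male").to_numpy(float)]
        )
        if adjust
        else None
    )
    out: list[AssociationRecord] = []
    for sid in aligned.columns:
        x = aligned[sid].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            out.append(
                AssociationRecord(sid, model_name, np.nan, np.nan, np.nan, np.nan,
                                  np.nan, np.nan, "", note="untestable: zero variance")
            )
            continue
        X = np.column_stack([x, covars]) if adjust else x[:, None]
        names = [sid] + (["age", "male"] if adjust else [])
        try:
            params, cov = fit_logistic(y, X, names)
        except (SeparationError, ConvergenceError) as e:
            out.append(
                AssociationRecord(sid, model_name, np.nan, np.nan, np.nan, np.nan,
                                  np.nan, np.nan, "", note=f"untestable: {e}")
            )
            continue
        out.append(
            _record_from_fit(sid, model_name, params[1], np.sqrt(cov[1, 1]), tiers)
        )
    return out


def panel_frame(
    records: Sequence[AssociationRecord], bh_adjust: bool = False
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "subset_id": [r.subset_id for r in records],
            "model": [r.model for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "or": [r.or_ for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "p": [r.p for r in records],
            "tier": [r.tier for r in records],
            "note": [r.note for r in records],
        }
    )
    if bh_adjust:
        ok = df["p"].notna()
        adj = np.full(len(df), np.nan)
        adj[ok.to_numpy()] = sm.stats.multipletests(
            df.loc[ok, "p"].to_numpy(), method="fdr_bh"
        )[1]
        df["p_bh"] = adj
    return df


def forest_table(
    records: Sequence[AssociationRecord], catalog: SubsetCatalog | None = None
) -> pd.DataFrame:
    """Forest-plot-ready table: rows grouped by major population."""
    if not records:
        raise ValueError("no association records")
    df = panel_frame(records)
    if catalog is not None:
        df["major_population"] = [
            catalog[s].major_population if s in catalog else "" for s in df["subset_id"]
        ]
        df["label"] = [
            catalog[s].label if s in catalog else s for s in df["subset_id"]
        ]
        df = df.sort_values(
            ["major_population", "subset_id"], kind="stable"
        ).reset_index(drop=True)
    return df


class SubsetAssociationModel:
    """Differential-proportion analysis over a subset panel.

    Statsmodels-style entry point: construct from the proportion matrix and
    patient records, call :meth:`fit` to obtain
    :class:`AssociationResults` holding both the unadjusted and the
    age/sex-adjusted odds-ratio tables.
    """

    def __init__(
        self,
        matrix: ProportionsMatrix,
        records: Sequence[PatientRecord],
        catalog: SubsetCatalog | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.matrix = matrix
        self.records = list(records)
        self.catalog = catalog
        self.config = config or AnalysisConfig()

    def fit(self, adjust: str = "both") -> "AssociationResults":
        tiers = self.config.alpha_tiers
        panels: dict[str, list[AssociationRecord]] = {}
        if adjust in ("none", "both"):
            panels["unadjusted"] = run_panel(self.matrix, self.records, False, tiers)
        if adjust in ("age_sex", "both"):
            panels["age_sex_adjusted"] = run_panel(self.matrix, self.records, True, tiers)
        if not panels:
            raise ValueError(f"adjust must be none/age_sex/both, got {adjust!r}")
        return AssociationResults(self, panels)


class AssociationResults:
    def __init__(
        self, model: SubsetAssociationModel, panels: dict[str, list[AssociationRecord]]
    ):
        self.model = model
        self.panels = panels

    def frame(self, which: str | None = None, bh_adjust: bool = False) -> pd.DataFrame:
        if which is not None:
            return panel_frame(self.panels[which], bh_adjust)
        return pd.concat(
            [panel_frame(recs, bh_adjust) for recs in self.panels.values()],
            ignore_index=True,
        )

    def forest_table(self, which: str = "unadjusted") -> pd.DataFrame:
        return forest_table(self.panels[which], self.model.catalog)

    def significant_subsets(
        self, which: str = "unadjusted", alpha: float = 0.05
    ) -> list[str]:
        return [r.subset_id for r in self.panels[which] if r.testable and r.p < alpha]

    def summary(self) -> str:
        lines = []
        for which, recs in self.panels.items():
            lines.append(f"== {which} ==")
            lines.append(f"{'subset':28s} {'OR':>7s} {'95% CI':>17s} {'p':>8s} tier")
            for r in recs:
                if not r.testable:
                    lines.append(f"{r.subset_id:28s} {r.note}")
                    continue
                lines.append(
                    f"{r.subset_id:28s} {r.or_:7.3f} "
                    f"[{r.ci_low:7.3f},{r.ci_high:7.3f}] {r.p:8.4f} {r.tier}"
                )
        return "\n".join(lines)
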