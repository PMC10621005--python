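"""Per-patient classifiability under repeated cross-validation.

A lasso logistic model is trained inside a repeated stratified k-fold CV
(default 5 folds x 20 repeats).  In each fold the top-m features are
screened by AUC on the training split only, standardised with training
statistics, and an L1-penalised logistic model (penalty chosen by an inner
5-fold deviance grid) predicts the held-out patients.  Each patient's
classifiability score c_i is the proportion of repeats in which their
held-out prediction was correct; regressing c_i on clinical covariates
identifies modifier variables, and an age cut-off defines the sub-cohort
where the signature is informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .datatypes import PatientRecord, records_to_frame


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with mid-rank ties."""
    y = np.asarray(y, dtype=bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def screen_by_auc(
    X: np.ndarray, y: np.ndarray, m: int, rank_key: str = "distance"
) -> np.ndarray:
    """Indices of the top-m features by per-feature AUC against the label.

    rank_key "distance" ranks by |AUC - 0.5| descending (an AUC of 0.2 is
    as informative as 0.8); "raw" ranks by AUC itself.  Ties break by
    original column order.
    """
    X = np.asarray(X, dtype=float)
    if m > X.shape[1]:
        raise ValueError(f"m={m} exceeds number of features {X.shape[1]}")
    aucs = np.array([rank_auc(X[:, j], y) for j in range(X.shape[1])])
    key = np.abs(aucs - 0.5) if rank_key == "distance" else aucs
    # stable sort on negated key -> descending with original-order tie-break
    order = np.argsort(-key, kind="stable")
    return np.sort(order[:m])


@dataclass
class CVPlan:
    """Fold assignment for repeated k-fold CV: shape (repeats, n_patients)."""

    folds: int
    repeats: int
    stratified: bool
    seed: int
    assignment: np.ndarray

    @classmethod
    def build(
        cls,
        n: int,
        y: np.ndarray | None = None,
        folds: int = 5,
        repeats: int = 20,
        stratified: bool = True,
        seed: int = 0,
    ) -> "CVPlan":
        rng = np.random.default_rng(seed)
        if stratified and y is None:
            raise ValueError("stratified assignment requires labels")
        assignment = np.empty((repeats, n), dtype=int)
        for r in range(repeats):
            assignment[r] = cls._one_repeat(n, y, folds, stratified, rng)
        return cls(folds, repeats, stratified, seed, assignment)

    @staticmethod
    def _one_repeat(
        n: int, y: np.ndarray | None, folds: int, stratified: bool,
        rng: np.random.Generator,
    ) -> np.ndarray:
        out = np.empty(n, dtype=int)
        if stratified:
            for cls_val in np.unique(y):
                idx = np.flatnonzero(np.asarray(y) == cls_val)
                rng.shuffle(idx)
                out[idx] = np.arange(len(idx)) % folds
        else:
            perm = rng.permutation(n)
            out[perm] = np.arange(n) % folds
        return out

    def redraw_repeat(self, r: int, y: np.ndarray | None, rng: np.random.Generator) -> None:
        self.assignment[r] = self._one_repeat(
            self.assignment.shape[1], y, self.folds, self.stratified, rng
        )


def _lasso_logistic(c: float) -> LogisticRegression:
    # large intercept_scaling leaves the intercept effectively unpenalised
    # (the usual lasso convention), so at strong penalty the model falls
    # back to the majority-class fit
    return LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", max_iter=1000, tol=1e-6,
        random_state=0, intercept_scaling=100.0,
    )


def _fit_lasso_cv(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_lambda: int = 50,
    inner_folds: int = 5,
) -> LogisticRegression:
    """L1 logistic fit with penalty chosen by inner-CV mean deviance."""
    cs = np.logspace(-3, 3, n_lambda)
    inner = CVPlan.build(
        len(y), y, folds=inner_folds, repeats=1, stratified=True,
        seed=int(rng.integers(2**31)),
    ).assignment[0]
    deviance = np.zeros(n_lambda)
    for k in range(inner_folds):
        tr, te = inner != k, inner == k
        if len(np.unique(y[tr])) < 2:
            continue
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        with warnings.catch_warnings():
            # extreme penalty-grid endpoints may not converge; they are never
            # selected by the deviance criterion in that case
            warnings.simplefilter("ignore", ConvergenceWarning)
            for i, c in enumerate(cs):
                clf = _lasso_logistic(c)
                clf.fit(Xtr, y[tr])
                p = np.clip(clf.predict_proba(Xte)[:, 1], 1e-12, 1 - 1e-12)
                deviance[i] += -2 * np.sum(
                    y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)
                )
    best = cs[int(np.argmin(deviance))]
    return _lasso_logistic(best)


@dataclass
class ClassifiabilityProfile:
    patient_ids: list[str]
    scores: np.ndarray  # c_i in [0,1]
    n_repeats: int
    predicted: np.ndarray  # (repeats, n) held-out predicted labels
    probabilities: np.ndarray  # (repeats, n) held-out predicted P(CAD)
    y: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        """Overall repeated-CV accuracy (equals the mean of c_i exactly)."""
        return float(self.scores.mean())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_ids, "classifiability": self.scores}
        )


def compute_classifiability(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    m: int = 18,
    rank_key: str = "distance",
    n_lambda: int = 50,
    patient_ids: Sequence[str] | None = None,
) -> ClassifiabilityProfile:
    """Per-patient proportion of correct held-out predictions over repeats."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 25:
        raise ValueError("need at least 25 patients for 5-fold repeated CV")
    m = min(m, X.shape[1])
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 7]))
    predicted = np.zeros((plan.repeats, n), dtype=int)
    probs = np.zeros((plan.repeats, n))
    for r in range(plan.repeats):
        for attempt in range(10):
            folds = plan.assignment[r]
            ok = all(
                len(np.unique(y[folds != k])) == 2 for k in range(plan.folds)
            )
            if ok:
                break
            plan.redraw_repeat(r, y if plan.stratified else None, rng)
        else:
            raise RuntimeError("could not draw folds containing both classes")
        for k in range(plan.folds):
            tr, te = folds != k, folds == k
            if te.sum() == 0:
                continue
            sel = screen_by_auc(X[tr], y[tr], m, rank_key)
            mu = X[np.ix_(tr, sel)].mean(axis=0)
            sd = X[np.ix_(tr, sel)].std(axis=0)
            sd[sd == 0] = 1.0
            clf = _fit_lasso_cv(X[np.ix_(tr, sel)], y[tr], rng, n_lambda)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit((X[np.ix_(tr, sel)] - mu) / sd, y[tr])
            p = clf.predict_proba((X[np.ix_(te, sel)] - mu) / sd)[:, 1]
            probs[r, te] = p
            predicted[r, te] = (p >= 0.5).astype(int)
    scores = (predicted == y[None, :]).mean(axis=0)
    ids = list(patient_ids) if patient_ids is not None else [str(i) for i in range(n)]
    return ClassifiabilityProfile(ids, scores, plan.repeats, predicted, probs, y)


@dataclass
class ModifierResult:
    covariate: str
    coefficient: float
    se: float
    p: float
    note: str = ""


DEFAULT_MODIFIER_COVARIATES = (
    "age",
    "sex_male",
    "hypertension",
    "diabetes",
    "hyperlipidaemia",
    "current_smoking",
    "smoking_history_gt10py",
    "family_history",
    "statin",
    "ace_arb",
    "antiplatelet",
    "beta_blocker",
)


def find_modifiers(
    profile: ClassifiabilityProfile,
    records: Sequence[PatientRecord],
    covariates: Sequence[str] = DEFAULT_MODIFIER_COVARIATES,
) -> list[ModifierResult]:
    """Simple linear regressions of c_i on each clinical covariate.

    Results are ranked by ascending p (two-sided t test of a non-zero
    slope); constant covariates are flagged untestable and sort last.
    """
    df = records_to_frame(records).loc[profile.patient_ids]
    df["sex_male"] = (df["sex"] == "male").astype(float)
    c = profile.scores
    out = []
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate {cov!r} not present in records")
        x = df[cov].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            out.append(ModifierResult(cov, np.nan, np.nan, np.nan, "untestable: constant"))
            continue
        if np.ptp(c) == 0:
            out.append(ModifierResult(cov, 0.0, np.nan, np.nan, "degenerate: c constant"))
            continue
        fit = stats.linregress(x, c)
        out.append(ModifierResult(cov, float(fit.slope), float(fit.stderr), float(fit.pvalue)))
    return sorted(out, key=lambda r: (np.isnan(r.p), r.p))


def select_subcohort(
    records: Sequence[PatientRecord], cutoff: float = 55.0
) -> np.ndarray:
    """Boolean mask of patients with age >= cutoff (boundary inclusive)."""
    ages = np.array([r.age for r in records], dtype=float)
    if not (ages.min() <= cutoff <= ages.max()):
        raise ValueError(
            f"cutoff {cutoff} outside observed age range [{ages.min()}, {ages.max()}]"
        )
    mask = ages >= cutoff
    if not mask.any():
        raise ValueError("empty sub-cohort selection")
    return mask


def scan_age_cutoff(
    profile: ClassifiabilityProfile,
    records: Sequence[PatientRecord],
    candidates: Sequence[float] | None = None,
    min_group: int = 10,
) -> float:
    """Cut-off maximising the between-group difference in mean c_i.

    Scans candidate age cut-offs (default: integer ages spanning the
    observed range) requiring at least ``min_group`` patients on each side.
    """
    ages = np.array([r.age for r in records], dtype=float)
    c = profile.scores
    if candidates is None:
        candidates = np.arange(np.ceil(ages.min()) + 1, np.floor(ages.max()))
    best_cut, best_diff = None, -np.inf
    for cut in candidates:
        hi = ages >= cut
        if hi.sum() < min_group or (~hi).sum() < min_group:
            continue
        diff = c[hi].mean() - c[~hi].mean()
        if diff > best_diff:
            best_cut, best_diff = float(cut), diff
    if best_cut is None:
        raise ValueError("no candidate cut-off satisfies the group-size floor")
    return best_cut


class ClassifiabilityModel:
    """Repeated-CV classifiability analysis in Model/Results form."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        patient_ids: Sequence[str] | None = None,
        records: Sequence[PatientRecord] | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.patient_ids = patient_ids
        self.records = records

    @classmethod
    def from_cohort(cls, matrix, records) -> "ClassifiabilityModel":
        df = records_to_frame(records)
        values = matrix.aligned_to(list(df.index)).values
        return cls(
            values.to_numpy(float),
            df["cad_status"].to_numpy(int),
            list(values.index),
            list(records),
        )

    def fit(
        self,
        folds: int = 5,
        repeats: int = 20,
        m: int = 18,
        seed: int = 0,
        rank_key: str = "distance",
        n_lambda: int = 50,
    ) -> "ClassifiabilityResults":
        plan = CVPlan.build(
            len(self.y), self.y, folds=folds, repeats=repeats, seed=seed
        )
        profile = compute_classifiability(
            self.X, self.y, plan, m=m, rank_key=rank_key, n_lambda=n_lambda,
            patient_ids=self.patient_ids,
        )
        return ClassifiabilityResults(self, plan, profile)


class ClassifiabilityResults:
    def __init__(self, model, plan: CVPlan, profile: ClassifiabilityProfile):
        self.model = model
        self.plan = plan
        self.profile = profile

    def modifiers(self, covariates=DEFAULT_MODIFIER_COVARIATES) -> list[ModifierResult]:
        if self.model.records is None:
            raise ValueError("model was built without patient records")
        return find_modifiers(self.profile, self.model.records, covariates)

    def summary(self) -> str:
        lines = [
            f"Repeated CV: {self.plan.folds}-fold x {self.plan.repeats} repeats",
            f"Mean classifiability (overall CV accuracy): {self.profile.mean_accuracy:.3f}",
        ]
        if self.model.records is not None:
            lines.append(f"{'covariate':24s} {'slope':>9s} {'se':>9s} {'p':>8s}")
            for m in self.modifiers():
                if m.note:
                    lines.append(f"{m.covariate:24s} {m.note}")
                else:
                    lines.append(
                        f"{m.covariate:24s} {m.coefficient:9.4f} {m.se:9.4f} {m.p:8.4f}"
                    )
        return "\n".join(lines)
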