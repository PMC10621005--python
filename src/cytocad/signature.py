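"""Radial-kernel SVM immune signature on the age-selected sub-cohort.

Within the discovery sub-cohort the signature is evaluated by repeated
5-fold CV: per fold, features are screened by AUC on the training split,
standardised with training statistics, an RBF-kernel SVM is fitted and
held-out samples are scored by the signed decision value.  Per-fold ROC
curves are averaged vertically (mean TPR at a fixed FPR grid) and the mean
AUC is the arithmetic mean of per-fold rank AUCs.  A model trained on the
whole discovery sub-cohort with a fixed 18-subset list is evaluated on the
validation sub-cohort, and the decision boundary is visualised in the plane
of the first two discovery principal components, back-mapped to feature
space with a small neural network (with an exact rank-2 linear fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC

from .classifiability import CVPlan, rank_auc, screen_by_auc
from .datatypes import SchemaError

FPR_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


def roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC by threshold sweep over unique scores; returns (fpr, tpr).

    Curves start at (0,0) and end at (1,1); tied scores move the operating
    point diagonally in one step.
    """
    y = np.asarray(y, dtype=bool)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    ys = y[order]
    ss = np.asarray(scores, dtype=float)[order]
    n1, n0 = int(y.sum()), int((~y).sum())
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # keep only the last point of each tied-score run
    last = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tps[last] / n1]
    fpr = np.r_[0.0, fps[last] / n0]
    return fpr, tpr


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def tpr_at_grid(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray = FPR_GRID) -> np.ndarray:
    """Linear interpolation of a fold ROC onto the shared FPR grid."""
    return np.interp(grid, fpr, tpr)


@dataclass
class SignatureReport:
    feature_set: str
    fold_aucs: list[float]
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    validation_auc: float | None = None
    validation_roc: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def summary(self) -> str:
        lines = [
            f"feature set: {self.feature_set}",
            f"mean CV AUC over {len(self.fold_aucs)} folds: {self.mean_auc:.3f}",
        ]
        if self.validation_auc is not None:
            lines.append(f"validation AUC: {self.validation_auc:.3f}")
        return "\n".join(lines)


def _standardise(train: np.ndarray, *others: np.ndarray):
    mu, sd = train.mean(axis=0), train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return ((train - mu) / sd, *[(o - mu) / sd for o in others], mu, sd)


def default_svm(cost: float = 1.0) -> SVC:
    # gamma="scale" = 1 / (p * var) on the standardised features
    return SVC(kernel="rbf", C=cost, gamma="scale")


def cv_signature_auc(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    m: int = 18,
    screen: bool = True,
    extra: np.ndarray | None = None,
    feature_set: str = "cytof_18",
    cost: float = 1.0,
    rank_key: str = "distance",
) -> SignatureReport:
    """Repeated-CV ROC/AUC of the RBF-SVM signature.

    ``extra`` columns (e.g. age, sex) bypass the AUC screen and are always
    included; with ``screen=False`` and no subset columns the model runs on
    ``extra`` alone.
    """
    X = np.asarray(X, dtype=float) if X is not None else None
    y = np.asarray(y, dtype=int)
    n = len(y)
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 11]))
    fold_aucs: list[float] = []
    tprs: list[np.ndarray] = []
    for r in range(plan.repeats):
        for _ in range(10):
            folds = plan.assignment[r]
            if all(len(np.unique(y[folds != k])) == 2
                   and len(np.unique(y[folds == k])) == 2 for k in range(plan.folds)):
                break
            plan.redraw_repeat(r, y if plan.stratified else None, rng)
        else:
            raise RuntimeError("could not draw folds containing both classes")
        for k in range(plan.folds):
            tr, te = folds != k, folds == k
            blocks_tr, blocks_te = [], []
            if X is not None and X.shape[1] > 0:
                sel = (
                    screen_by_auc(X[tr], y[tr], min(m, X.shape[1]), rank_key)
                    if screen
                    else np.arange(X.shape[1])
                )
                blocks_tr.append(X[np.ix_(tr, sel)])
                blocks_te.append(X[np.ix_(te, sel)])
            if extra is not None:
                blocks_tr.append(extra[tr])
                blocks_te.append(extra[te])
            Xtr = np.column_stack(blocks_tr)
            Xte = np.column_stack(blocks_te)
            Xtr_s, Xte_s, *_ = _standardise(Xtr, Xte)
            clf = default_svm(cost)
            clf.fit(Xtr_s, y[tr])
            scores = clf.decision_function(Xte_s)
            fold_aucs.append(rank_auc(scores, y[te]))
            fpr, tpr = roc_points(scores, y[te])
            tprs.append(tpr_at_grid(fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    return SignatureReport(feature_set, fold_aucs, FPR_GRID.copy(), mean_tpr)


def train_validate(
    Xd: np.ndarray,
    yd: np.ndarray,
    Xv: np.ndarray,
    yv: np.ndarray,
    feature_names: Sequence[str] | None = None,
    validation_names: Sequence[str] | None = None,
    cost: float = 1.0,
) -> tuple[SignatureReport, SVC, tuple[np.ndarray, np.ndarray]]:
    """Train on all discovery samples, evaluate ROC/AUC on validation.

    Standardisation parameters are learned on discovery only.  Returns the
    report, the fitted SVM and the (mu, sd) standardisation pair.
    """
    if feature_names is not None and validation_names is not None:
        missing = [f for f in feature_names if f not in set(validation_names)]
        if missing:
            raise SchemaError(f"features missing in validation cohort: {missing}")
    Xd_s, Xv_s, mu, sd = _standardise(np.asarray(Xd, float), np.asarray(Xv, float))
    clf = default_svm(cost)
    clf.fit(Xd_s, np.asarray(yd, int))
    scores = clf.decision_function(Xv_s)
    auc = rank_auc(scores, yv)
    fpr, tpr = roc_points(scores, yv)
    report = SignatureReport(
        "cytof_18", [auc], FPR_GRID.copy(), tpr_at_grid(fpr, tpr),
        validation_auc=auc, validation_roc=(fpr, tpr),
    )
    return report, clf, (mu, sd)


def compare_feature_sets(
    Xd: np.ndarray,
    yd: np.ndarray,
    age: np.ndarray,
    male: np.ndarray,
    plan: CVPlan,
    m: int = 18,
    cost: float = 1.0,
) -> dict[str, SignatureReport]:
    """CV reports for cytof_18, age_sex and combined under one shared plan."""
    demo = np.column_stack([np.asarray(age, float), np.asarray(male, float)])
    reports = {}
    for name, X, extra in (
        ("cytof_18", Xd, None),
        ("age_sex", None, demo),
        ("combined", Xd, demo),
    ):
        p = CVPlan(plan.folds, plan.repeats, plan.stratified, plan.seed,
                   plan.assignment.copy())
        reports[name] = cv_signature_auc(
            X, yd, p, m=m, extra=extra, feature_set=name, cost=cost
        )
    return reports


# ---------------------------------------------------------------------------
# PCA projection and decision-boundary back-mapping
# ---------------------------------------------------------------------------


@dataclass
class PCAProjection:
    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray  # (2, n_features)
    scores_discovery: np.ndarray
    scores_validation: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ((np.asarray(X, float) - self.mean) / self.sd) @ self.loadings.T


def fit_pca_project(Xd: np.ndarray, Xv: np.ndarray | None = None) -> PCAProjection:
    """First two PCs of the standardised discovery data; validation is
    projected with the discovery loadings and standardisation only."""
    Xd = np.asarray(Xd, dtype=float)
    if Xd.shape[0] < 3:
        raise ValueError("need at least 3 discovery samples")
    if np.any(np.ptp(Xd, axis=0) == 0):
        j = int(np.argmin(np.ptp(Xd, axis=0)))
        raise ValueError(f"zero-variance feature at column {j}")
    sd = Xd.std(axis=0)
    mu = Xd.mean(axis=0)
    Z = (Xd - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:2].copy()
    for i in range(2):  # sign convention: largest-|loading| entry positive
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
    proj = PCAProjection(mu, sd, loadings, Z @ loadings.T)
    if Xv is not None:
        proj.scores_validation = proj.transform(Xv)
    return proj


@dataclass
class BoundaryMap:
    grid_pc1: np.ndarray
    grid_pc2: np.ndarray
    predicted: np.ndarray  # (n2, n1) class grid
    mapped_features: np.ndarray  # (n2*n1, n_features), standardised units
    scores_discovery: np.ndarray
    scores_validation: np.ndarray | None
    backmap_method: str  # "neural_net" | "linear"


def _linear_backmap(loadings: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    return lambda pcs: pcs @ loadings


def backmap_decision_boundary(
    svm: SVC,
    pca: PCAProjection,
    Xd_std: np.ndarray,
    grid_size: int = 200,
    margin: float = 0.05,
    seed: int = 0,
    hidden: int = 16,
    max_iter: int = 2000,
) -> BoundaryMap:
    """Classify a PC1-PC2 grid back-mapped to feature space.

    ``Xd_std`` are the standardised discovery features the SVM was trained
    on.  A feed-forward net (2 -> ``hidden`` tanh -> n_features linear) is
    trained on the discovery (PC1, PC2) -> standardised-feature pairs by
    least squares.  If its training loss fails to come within 1.5x the
    exact rank-2 linear reconstruction's, the linear inverse (loadings^T)
    is used instead.  The grid covers all projected points with a margin.
    """
    pcs_d = pca.scores_discovery
    all_pcs = (
        np.vstack([pcs_d, pca.scores_validation])
        if pca.scores_validation is not None
        else pcs_d
    )
    lo = all_pcs.min(axis=0)
    hi = all_pcs.max(axis=0)
    span = hi - lo
    lo, hi = lo - margin * span, hi + margin * span
    g1 = np.linspace(lo[0], hi[0], grid_size)
    g2 = np.linspace(lo[1], hi[1], grid_size)
    G1, G2 = np.meshgrid(g1, g2)
    grid_pcs = np.column_stack([G1.ravel(), G2.ravel()])

    linear = _linear_backmap(pca.loadings)
    baseline_mse = float(np.mean((linear(pcs_d) - Xd_std) ** 2))
    method = "neural_net"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = MLPRegressor(
            hidden_layer_sizes=(hidden,),
            activation="tanh",
            solver="lbfgs",
            max_iter=max_iter,
            random_state=seed,
        )
        net.fit(pcs_d, Xd_std)
        net_mse = float(np.mean((net.predict(pcs_d) - Xd_std) ** 2))
    if net_mse > max(baseline_mse, 1e-12) * 1.5:
        warnings.warn(
            "back-mapping net did not reach the rank-2 linear baseline; "
            "falling back to the exact linear inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        mapped = linear(grid_pcs)
        method = "linear"
    else:
        mapped = net.predict(grid_pcs)
    predicted = svm.predict(mapped).reshape(grid_size, grid_size)
    return BoundaryMap(
        g1, g2, predicted, mapped, pcs_d, pca.scores_validation, method
    )


class SignatureSVMModel:
    """RBF-SVM immune-signature analysis in Model/Results form."""

    def __init__(
        self,
        Xd: np.ndarray,
        yd: np.ndarray,
        Xv: np.ndarray | None = None,
        yv: np.ndarray | None = None,
        feature_names: Sequence[str] | None = None,
        cost: float = 1.0,
    ):
        self.Xd = np.asarray(Xd, float)
        self.yd = np.asarray(yd, int)
        self.Xv = None if Xv is None else np.asarray(Xv, float)
        self.yv = None if yv is None else np.asarray(yv, int)
        self.feature_names = feature_names
        self.cost = cost

    def fit(
        self,
        folds: int = 5,
        repeats: int = 20,
        m: int = 18,
        seed: int = 0,
        grid_size: int = 200,
    ) -> "SignatureResults":
        plan = CVPlan.build(len(self.yd), self.yd, folds=folds, repeats=repeats, seed=seed)
        cv_report = cv_signature_auc(self.Xd, self.yd, plan, m=m, cost=self.cost)
        val_report = svm = scaler = pca = boundary = None
        if self.Xv is not None and self.yv is not None:
            val_report, svm, scaler = train_validate(
                self.Xd, self.yd, self.Xv, self.yv,
                self.feature_names, self.feature_names, cost=self.cost,
            )
            pca = fit_pca_project(self.Xd, self.Xv)
            Xd_std = (self.Xd - scaler[0]) / scaler[1]
            boundary = backmap_decision_boundary(
                svm, pca, Xd_std, grid_size=grid_size, seed=seed
            )
        return SignatureResults(self, plan, cv_report, val_report, pca, boundary)


class SignatureResults:
    def __init__(self, model, plan, cv_report, val_report, pca, boundary):
        self.model = model
        self.plan = plan
        self.cv_report: SignatureReport = cv_report
        self.validation_report: SignatureReport | None = val_report
        self.pca: PCAProjection | None = pca
        self.boundary: BoundaryMap | None = boundary

    @property
    def mean_auc(self) -> float:
        return self.cv_report.mean_auc

    def summary(self) -> str:
        lines = [self.cv_report.summary()]
        if self.validation_report is not None:
            lines.append(
                f"validation AUC (trained on all discovery): "
                f"{self.validation_report.validation_auc:.3f}"
            )
        if self.boundary is not None:
            lines.append(f"decision-boundary back-map: {self.boundary.backmap_method}")
        return "\n".join(lines)
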