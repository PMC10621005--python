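"""SVM signature: ROC identities, PCA projection, boundary back-mapping."""

import numpy as np
import pytest

from cytocad.classifiability import CVPlan, rank_auc
from cytocad.datatypes import SchemaError
from cytocad.signature import (
    FPR_GRID,
    backmap_decision_boundary,
    compare_feature_sets,
    cv_signature_auc,
    default_svm,
    fit_pca_project,
    roc_points,
    train_validate,
    trapezoid_auc,
    SignatureSVMModel,
)


def _signal_problem(rng, n=80, p=20, informative=5, shift=1.5, prevalence=0.7):
    y = (rng.random(n) < prevalence).astype(int)
    if y.sum() in (0, n):
        y[:2] = [0, 1]
    X = rng.normal(size=(n, p))
    X[:, :informative] += shift * y[:, None]
    return X, y


# ---------------------------------------------------------------------------
# ROC / AUC identities
# ---------------------------------------------------------------------------


def test_rank_auc_equals_trapezoid_area(rng):
    """The Mann-Whitney AUC equals the trapezoidal area under the
    threshold-sweep ROC to 1e-10, including with tied scores."""
    for _ in range(30):
        y = rng.integers(0, 2, 60)
        if y.sum() in (0, 60):
            continue
        s = np.round(rng.normal(size=60), 1)
        fpr, tpr = roc_points(s, y)
        assert rank_auc(s, y) == pytest.approx(trapezoid_auc(fpr, tpr), abs=1e-10)


def test_roc_endpoints_and_monotonicity(rng):
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    s = rng.normal(size=50)
    fpr, tpr = roc_points(s, y)
    assert fpr[0] == 0 and tpr[0] == 0
    assert fpr[-1] == 1 and tpr[-1] == 1
    assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    s = rng.normal(size=40)
    base = rank_auc(s, y)
    for f in (np.exp, np.tanh, lambda v: 3 * v + 7):
        assert rank_auc(f(s), y) == pytest.approx(base, abs=1e-12)


def test_roc_matches_sklearn_reference(rng):
    from sklearn.metrics import roc_curve

    y = rng.integers(0, 2, 80)
    y[:2] = [0, 1]
    s = np.round(rng.normal(size=80), 1)
    fpr, tpr = roc_points(s, y)
    ref_fpr, ref_tpr, _ = roc_curve(y, s, drop_intermediate=False)
    assert fpr == pytest.approx(ref_fpr, abs=1e-12)
    assert tpr == pytest.approx(ref_tpr, abs=1e-12)


# ---------------------------------------------------------------------------
# CV signature
# ---------------------------------------------------------------------------


def test_separable_feature_gives_auc_one(rng):
    X, y = _signal_problem(rng, n=60, p=5, informative=0)
    X[:, 0] = y * 10.0
    plan = CVPlan.build(60, y, repeats=2, seed=1)
    rep = cv_signature_auc(X, y, plan, m=3)
    assert rep.mean_auc == pytest.approx(1.0)
    assert rep.mean_tpr[0] >= 0.999  # passes through (0, 1)


def test_mean_auc_is_mean_of_fold_aucs(rng):
    X, y = _signal_problem(rng)
    plan = CVPlan.build(len(y), y, repeats=2, seed=2)
    rep = cv_signature_auc(X, y, plan, m=5)
    assert rep.mean_auc == pytest.approx(float(np.mean(rep.fold_aucs)), abs=1e-15)
    assert len(rep.fold_aucs) == plan.folds * plan.repeats


def test_mean_roc_monotone_with_unit_endpoints(rng):
    X, y = _signal_problem(rng)
    plan = CVPlan.build(len(y), y, repeats=2, seed=3)
    rep = cv_signature_auc(X, y, plan, m=5)
    assert np.all(np.diff(rep.mean_tpr) >= -1e-12)
    assert rep.mean_tpr[0] == pytest.approx(0.0, abs=1e-9) or rep.mean_tpr[0] >= 0
    assert rep.mean_tpr[-1] == pytest.approx(1.0)


def test_null_signature_auc_near_half():
    """All-noise features: mean CV AUC sits in the Monte-Carlo band of 0.5."""
    rng = np.random.default_rng(19)
    aucs = []
    for seed in range(10):
        y = (rng.random(100) < 0.5).astype(int)
        if y.sum() in (0, 100):
            continue
        X = rng.normal(size=(100, 20))
        plan = CVPlan.build(100, y, repeats=2, seed=seed)
        aucs.append(cv_signature_auc(X, y, plan, m=5).mean_auc)
    mc_se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 0.5) < max(3 * mc_se, 0.05)


# ---------------------------------------------------------------------------
# train / validate
# ---------------------------------------------------------------------------


def test_validation_identical_to_discovery_separable(rng):
    X, y = _signal_problem(rng, n=50, p=4, informative=0)
    X[:, 1] = y * 5.0
    rep, _, _ = train_validate(X, y, X, y)
    assert rep.validation_auc == pytest.approx(1.0)


def test_validation_feature_mismatch_is_schema_error(rng):
    X, y = _signal_problem(rng, n=40, p=3, informative=1)
    with pytest.raises(SchemaError, match="c"):
        train_validate(X, y, X, y, feature_names=["a", "b", "c"],
                       validation_names=["a", "b"])


def test_permuted_validation_labels_auc_near_half():
    rng = np.random.default_rng(29)
    aucs = []
    for _ in range(20):
        Xd, yd = _signal_problem(rng, n=88, p=18, informative=6)
        Xv, yv = _signal_problem(rng, n=41, p=18, informative=6)
        yv_perm = rng.permutation(yv)
        if yv_perm.sum() in (0, len(yv_perm)):
            continue
        rep, _, _ = train_validate(Xd, yd, Xv, yv_perm)
        aucs.append(rep.validation_auc)
    assert abs(np.mean(aucs) - 0.5) < 0.07


def test_simulated_validation_auc_beats_chance():
    """Planted signal with a batch shift: validation AUC > 0.5 in nearly
    every replicate at study-like sizes."""
    from cytocad.datatypes import records_to_frame
    from cytocad.simulate import HEADLINE_SUBSETS, SimConfig, generate_cohort

    hits = n_ok = 0
    for seed in range(15):
        co = generate_cohort(SimConfig(seed=300 + seed))
        df = records_to_frame(co.records)
        feats = list(HEADLINE_SUBSETS)
        d = df[df.cohort == "discovery"]
        v = df[df.cohort == "validation"]
        sd, sv = (d.age >= 55).to_numpy(), (v.age >= 55).to_numpy()
        yv = v.cad_status.to_numpy(int)[sv]
        if len(np.unique(yv)) < 2:
            continue
        rep, _, _ = train_validate(
            co.proportions.values.loc[d.index, feats].to_numpy(float)[sd],
            d.cad_status.to_numpy(int)[sd],
            co.proportions.values.loc[v.index, feats].to_numpy(float)[sv],
            yv,
        )
        n_ok += 1
        hits += rep.validation_auc > 0.5
    assert hits >= int(0.95 * n_ok)


def test_compare_feature_sets_shared_folds_and_ordering():
    """The three feature sets share fold assignments; when subsets carry
    signal beyond age/sex the combined model is not dominated."""
    rng = np.random.default_rng(37)
    wins = 0
    n_rep = 8
    for seed in range(n_rep):
        n = 90
        age = rng.uniform(55, 85, n)
        male = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.02 * (age - 65)))).astype(int)
        if y.sum() in (0, n):
            continue
        X = rng.normal(size=(n, 20))
        X[:, :6] += 1.2 * y[:, None]
        plan = CVPlan.build(n, y, repeats=2, seed=seed)
        reports = compare_feature_sets(X, y, age, male, plan, m=6)
        assert set(reports) == {"cytof_18", "age_sex", "combined"}
        wins += (
            reports["combined"].mean_auc >= reports["age_sex"].mean_auc - 0.02
            and reports["cytof_18"].mean_auc > reports["age_sex"].mean_auc
        )
    assert wins >= n_rep // 2


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _rank2_data(rng, n=40, p=18):
    scores = rng.normal(size=(n, 2)) * [3.0, 1.5]
    basis, _ = np.linalg.qr(rng.normal(size=(p, 2)))
    X = scores @ basis.T
    return X + rng.normal(size=p) * 0  # exactly rank 2 before standardising


def test_rank2_reconstruction_exact(rng):
    X = _rank2_data(rng)
    pca = fit_pca_project(X)
    Z = (X - pca.mean) / pca.sd
    recon = pca.scores_discovery @ pca.loadings
    assert np.max(np.abs(recon - Z)) < 1e-8


def test_pca_two_route_agreement(rng):
    """SVD-route loadings/scores match the eigendecomposition of the
    correlation matrix (independent algorithm) to 1e-8, up to the shared
    sign convention."""
    X = rng.normal(size=(50, 8))
    pca = fit_pca_project(X)
    Z = (X - pca.mean) / pca.sd
    evals, evecs = np.linalg.eigh(Z.T @ Z)
    order = np.argsort(evals)[::-1]
    ref = evecs[:, order[:2]].T.copy()
    for i in range(2):
        j = int(np.argmax(np.abs(ref[i])))
        if ref[i, j] < 0:
            ref[i] *= -1
    assert pca.loadings == pytest.approx(ref, abs=1e-8)
    assert pca.scores_discovery == pytest.approx(Z @ ref.T, abs=1e-8)


def test_projection_equivariant_under_row_permutation(rng):
    X = rng.normal(size=(30, 6))
    perm = rng.permutation(30)
    pca = fit_pca_project(X)
    assert pca.transform(X[perm]) == pytest.approx(pca.scores_discovery[perm])


def test_zero_variance_feature_rejected(rng):
    X = rng.normal(size=(20, 4))
    X[:, 2] = 3.3
    with pytest.raises(ValueError, match="2"):
        fit_pca_project(X)


def test_validation_uses_discovery_loadings(rng):
    Xd = rng.normal(size=(40, 6))
    Xv = rng.normal(size=(15, 6)) + 2.0
    pca = fit_pca_project(Xd, Xv)
    assert pca.scores_validation == pytest.approx(
        ((Xv - pca.mean) / pca.sd) @ pca.loadings.T
    )


# ---------------------------------------------------------------------------
# decision-boundary back-mapping
# ---------------------------------------------------------------------------


def test_rank2_backmap_matches_linear_inverse(rng):
    """On exactly rank-2 data the back-mapped grid equals the closed-form
    rank-2 inverse (the net cannot beat an exact linear baseline and the
    fallback engages)."""
    X = _rank2_data(rng)
    y = (X[:, 0] > np.median(X[:, 0])).astype(int)
    Xs = (X - X.mean(0)) / X.std(0)
    clf = default_svm()
    clf.fit(Xs, y)
    pca = fit_pca_project(X)
    with pytest.warns(RuntimeWarning, match="linear"):
        bm = backmap_decision_boundary(clf, pca, Xs, grid_size=25, seed=0)
    assert bm.backmap_method == "linear"
    G1, G2 = np.meshgrid(bm.grid_pc1, bm.grid_pc2)
    grid = np.column_stack([G1.ravel(), G2.ravel()])
    exact = grid @ pca.loadings
    rmse = np.sqrt(np.mean((bm.mapped_features - exact) ** 2))
    assert rmse < 1e-3


def test_boundary_separates_predicted_regions(rng):
    """A separable direction in PC space yields both predicted classes on
    the grid with a contiguous split."""
    X, y = _signal_problem(rng, n=70, p=10, informative=4, shift=3.0)
    Xs = (X - X.mean(0)) / X.std(0)
    clf = default_svm()
    clf.fit(Xs, y)
    pca = fit_pca_project(X)
    bm = backmap_decision_boundary(clf, pca, Xs, grid_size=40, seed=1)
    assert set(np.unique(bm.predicted)) == {0, 1}


def test_boundary_deterministic(rng):
    X, y = _signal_problem(rng, n=50, p=8)
    Xs = (X - X.mean(0)) / X.std(0)
    clf = default_svm()
    clf.fit(Xs, y)
    pca = fit_pca_project(X)
    a = backmap_decision_boundary(clf, pca, Xs, grid_size=20, seed=5)
    b = backmap_decision_boundary(clf, pca, Xs, grid_size=20, seed=5)
    assert np.array_equal(a.predicted, b.predicted)
    assert a.mapped_features == pytest.approx(b.mapped_features, abs=0)


def test_grid_covers_projections_with_margin(rng):
    X, y = _signal_problem(rng, n=50, p=8)
    Xs = (X - X.mean(0)) / X.std(0)
    clf = default_svm()
    clf.fit(Xs, y)
    pca = fit_pca_project(X, X + 0.5)
    bm = backmap_decision_boundary(clf, pca, Xs, grid_size=20, seed=2)
    pts = np.vstack([bm.scores_discovery, bm.scores_validation])
    assert bm.grid_pc1.min() < pts[:, 0].min() and bm.grid_pc1.max() > pts[:, 0].max()
    assert bm.grid_pc2.min() < pts[:, 1].min() and bm.grid_pc2.max() > pts[:, 1].max()


def test_model_results_wrapper(rng):
    Xd, yd = _signal_problem(rng, n=60, p=12, informative=4)
    Xv, yv = _signal_problem(rng, n=30, p=12, informative=4)
    res = SignatureSVMModel(Xd, yd, Xv, yv).fit(repeats=2, seed=3, grid_size=25)
    assert 0 <= res.mean_auc <= 1
    assert res.validation_report.validation_auc > 0.5
    assert res.boundary.predicted.shape == (25, 25)
    assert "validation AUC" in res.summary()
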