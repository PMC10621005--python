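"""Classifiability scores, AUC screening, modifier regression, sub-cohorts."""

import numpy as np
import pytest
from scipy import stats

from cytocad.classifiability import (
    CVPlan,
    compute_classifiability,
    find_modifiers,
    rank_auc,
    scan_age_cutoff,
    screen_by_auc,
    select_subcohort,
    ClassifiabilityModel,
    ClassifiabilityProfile,
)
from cytocad.datatypes import PatientRecord


def _noise_problem(rng, n=60, p=30, prevalence=0.5):
    X = rng.normal(size=(n, p))
    y = (rng.random(n) < prevalence).astype(int)
    if y.sum() in (0, n):
        y[:2] = [0, 1]
    return X, y


def _records_with_ages(ages, seed=0):
    rng = np.random.default_rng(seed)
    return [
        PatientRecord(
            patient_id=f"p{i}",
            age=float(a),
            sex="male" if rng.random() < 0.5 else "female",
            hypertension=bool(rng.random() < 0.4),
            diabetes=False,
            hyperlipidaemia=bool(rng.random() < 0.5),
            current_smoking=False,
            smoking_history_gt10py=False,
            family_history=False,
            statin=bool(rng.random() < 0.3),
            ace_arb=False,
            antiplatelet=False,
            beta_blocker=False,
            gensini=float(i % 2) * 5,
        )
        for i, a in enumerate(ages)
    ]


# ---------------------------------------------------------------------------
# AUC screening
# ---------------------------------------------------------------------------


def test_rank_auc_pair_counting_example():
    """pos {0.8, 0.3} vs neg {0.5, 0.1}: 3 of 4 pairs concordant -> 0.75."""
    scores = np.array([0.8, 0.3, 0.5, 0.1])
    y = np.array([1, 1, 0, 0])
    assert rank_auc(scores, y) == pytest.approx(0.75)


def test_rank_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(20):
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            continue
        s = np.round(rng.normal(size=50), 1)  # coarse grid induces ties
        assert rank_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_label_feature_ranked_first(rng):
    y = rng.integers(0, 2, 40)
    y[:4] = [0, 1, 0, 1]
    X = rng.normal(size=(40, 5))
    X[:, 3] = y
    sel = screen_by_auc(X, y, 1)
    assert list(sel) == [3]


def test_distance_key_prefers_informative_low_auc(rng):
    n = 200
    y = np.r_[np.zeros(100, int), np.ones(100, int)]
    X = rng.normal(size=(n, 2))
    X[:, 0] = -y + 0.55 * rng.normal(size=n)  # AUC well below 0.5
    X[:, 1] = y + 2.5 * rng.normal(size=n)  # AUC mildly above 0.5
    a0, a1 = rank_auc(X[:, 0], y), rank_auc(X[:, 1], y)
    assert abs(a0 - 0.5) > abs(a1 - 0.5)
    assert list(screen_by_auc(X, y, 1, "distance")) == [0]
    assert list(screen_by_auc(X, y, 1, "raw")) == [1]


def test_screen_m_too_large_rejected(rng):
    X, y = _noise_problem(rng)
    with pytest.raises(ValueError):
        screen_by_auc(X, y, X.shape[1] + 1)


# ---------------------------------------------------------------------------
# CV plan
# ---------------------------------------------------------------------------


def test_cvplan_partitions_and_stratification():
    rng = np.random.default_rng(0)
    y = (rng.random(60) < 0.7).astype(int)
    plan = CVPlan.build(60, y, folds=5, repeats=4, seed=1)
    for r in range(4):
        folds = plan.assignment[r]
        assert sorted(np.unique(folds)) == [0, 1, 2, 3, 4]
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 2
        for k in range(5):
            assert len(np.unique(y[folds != k])) == 2  # both classes in training


# ---------------------------------------------------------------------------
# classifiability
# ---------------------------------------------------------------------------


def test_separable_feature_gives_all_ones(rng):
    X, y = _noise_problem(rng, n=40, p=6)
    X[:, 2] = y * 2.0 - 1.0
    plan = CVPlan.build(40, y, repeats=2, seed=3)
    prof = compute_classifiability(X, y, plan, m=3, n_lambda=8)
    assert np.all(prof.scores == 1.0)


def test_identical_seed_identical_profile(rng):
    X, y = _noise_problem(rng, n=40, p=10)
    a = compute_classifiability(X, y, CVPlan.build(40, y, repeats=2, seed=5), m=4, n_lambda=5)
    b = compute_classifiability(X, y, CVPlan.build(40, y, repeats=2, seed=5), m=4, n_lambda=5)
    assert np.array_equal(a.scores, b.scores)
    assert np.array_equal(a.probabilities, b.probabilities)


def test_score_identities(rng):
    """c_i lies in [0,1] with at most repeats+1 levels, and its mean equals
    the overall repeated-CV accuracy exactly."""
    X, y = _noise_problem(rng, n=50, p=12, prevalence=0.65)
    plan = CVPlan.build(50, y, repeats=3, seed=2)
    prof = compute_classifiability(X, y, plan, m=5, n_lambda=5)
    assert np.all((prof.scores >= 0) & (prof.scores <= 1))
    assert len(np.unique(prof.scores)) <= plan.repeats + 1
    acc = (prof.predicted == prof.y[None, :]).mean()
    assert prof.mean_accuracy == pytest.approx(acc, abs=1e-12)
    assert prof.scores.mean() == pytest.approx(acc, abs=1e-12)


def test_noise_features_track_majority_baseline():
    """With pure-noise features the mean classifiability tracks the
    majority-class rate from below: screening inside each fold cannot
    inflate accuracy above the baseline, while the screened-in spurious
    features drag it slightly under it."""
    rng = np.random.default_rng(17)
    rates = []
    majority = []
    for _ in range(5):
        n = 117
        y = (rng.random(n) < 0.68).astype(int)
        X = rng.normal(size=(n, 82))
        plan = CVPlan.build(n, y, repeats=4, seed=int(rng.integers(2**31)))
        prof = compute_classifiability(X, y, plan, m=18, n_lambda=8)
        rates.append(prof.mean_accuracy)
        majority.append(max(y.mean(), 1 - y.mean()))
    diff = np.mean(rates) - np.mean(majority)
    assert -0.12 < diff < 0.03


def test_screening_does_not_leak_held_out_labels():
    """Screening on training folds only: a large bank of noise features
    cannot lift accuracy above the majority baseline, which an all-data
    screen would."""
    rng = np.random.default_rng(23)
    n = 60
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, 200))
    plan = CVPlan.build(n, y, repeats=3, seed=9)
    prof = compute_classifiability(X, y, plan, m=10, n_lambda=6)
    majority = max(y.mean(), 1 - y.mean())
    assert prof.mean_accuracy < majority + 0.12


# ---------------------------------------------------------------------------
# modifiers and sub-cohort
# ---------------------------------------------------------------------------


def _profile_from_scores(scores, ids, y=None):
    n = len(scores)
    return ClassifiabilityProfile(
        list(ids), np.asarray(scores, float), 20,
        np.zeros((1, n), int), np.zeros((1, n)), np.zeros(n, int),
    )


def test_planted_age_modifier_ranked_first():
    """c_i = 0.3 + 0.006 (age - 40) + noise: age tops the modifier table
    with a positive slope in nearly every replicate."""
    rng = np.random.default_rng(31)
    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        ages = rng.uniform(40, 80, 117)
        records = _records_with_ages(ages, seed=int(rng.integers(2**31)))
        c = np.clip(0.3 + 0.006 * (ages - 40) + rng.normal(0, 0.05, 117), 0, 1)
        mods = find_modifiers(_profile_from_scores(c, [r.patient_id for r in records]), records)
        hits += mods[0].covariate == "age" and mods[0].coefficient > 0
    assert hits >= int(0.95 * n_rep)


def test_null_modifier_p_uniform():
    """An independent covariate yields uniform p-values (KS at 0.01)."""
    rng = np.random.default_rng(41)
    ps = []
    for _ in range(200):
        ages = rng.uniform(40, 80, 100)
        c = rng.uniform(0.2, 0.9, 100)
        ps.append(stats.linregress(ages, c).pvalue)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_constant_c_flagged_degenerate():
    ages = np.linspace(40, 70, 30)
    records = _records_with_ages(ages)
    prof = _profile_from_scores(np.full(30, 0.8), [r.patient_id for r in records])
    mods = find_modifiers(prof, records, covariates=("age",))
    assert mods[0].note.startswith("degenerate")


def test_constant_covariate_flagged():
    ages = np.linspace(40, 70, 30)
    records = _records_with_ages(ages)
    prof = _profile_from_scores(np.linspace(0.2, 0.9, 30), [r.patient_id for r in records])
    mods = find_modifiers(prof, records, covariates=("diabetes",))
    assert "constant" in mods[0].note


def test_subcohort_boundary_inclusive():
    records = _records_with_ages([54, 55, 56])
    assert select_subcohort(records, 55).sum() == 2


def test_subcohort_cutoff_below_min_selects_all():
    records = _records_with_ages([54, 55, 56])
    assert select_subcohort(records, 54).sum() == 3


def test_subcohort_cutoff_outside_range_rejected():
    records = _records_with_ages([54, 55, 56])
    with pytest.raises(ValueError):
        select_subcohort(records, 80)


def test_scan_recovers_planted_step_at_55():
    """A step increase of c_i at age 55 is recovered by the cut-off scan."""
    rng = np.random.default_rng(53)
    hits = 0
    n_rep = 50
    for _ in range(n_rep):
        ages = rng.uniform(40, 75, 117)
        records = _records_with_ages(ages, seed=int(rng.integers(2**31)))
        c = 0.5 + 0.2 * (ages >= 55) + rng.normal(0, 0.05, 117)
        prof = _profile_from_scores(np.clip(c, 0, 1), [r.patient_id for r in records])
        cut = scan_age_cutoff(prof, records)
        hits += abs(cut - 55) <= 1
    assert hits >= int(0.9 * n_rep)


def test_model_results_wrapper(sim_cohort):
    disc = [r for r in sim_cohort.records if r.cohort == "discovery"]
    matrix = sim_cohort.proportions.aligned_to([r.patient_id for r in disc])
    res = ClassifiabilityModel.from_cohort(matrix, disc).fit(
        repeats=2, seed=4, n_lambda=5
    )
    assert len(res.profile.scores) == len(disc)
    mods = res.modifiers()
    assert {m.covariate for m in mods} >= {"age", "statin"}
    assert "Mean classifiability" in res.summary()
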