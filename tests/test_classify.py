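import numpy as np
import pytest
from scipy.optimize import minimize

from tsnet.classify import (
    CvReport,
    SvmSolution,
    compute_metrics,
    cross_validate,
    dual_objective,
    early_stage_eval,
    kkt_residual,
    knn_select,
    nearest_psd,
    ppi_svm_knn,
    solve_svm_dual,
    svm_predict,
)
from tsnet.config import PipelineConfig
from tsnet.datatypes import Bicluster, PatientProfile
from tsnet.synthetic import generate_benchmark

from conftest import random_profile


def reference_qp(K, y, C):
    """Generic constrained solver as an independent check of the dual."""
    n = len(y)
    res = minimize(
        lambda a: -(a.sum() - 0.5 * (a * y) @ K @ (a * y)),
        np.full(n, min(C, 1.0) / 2),
        jac=lambda a: -(1 - (K @ (a * y)) * y),
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return -res.fun


# ---------------------------------------------------------------------------
# SVM dual


def test_two_point_closed_form():
    sol = solve_svm_dual(np.eye(2), np.array([1, -1]), C=100.0)
    np.testing.assert_allclose(sol.alpha, [1.0, 1.0], atol=1e-10)
    assert sol.b == pytest.approx(0.0, abs=1e-10)
    # decision value of each training point equals its label
    f = np.eye(2) @ (sol.alpha * sol.y) + sol.b
    np.testing.assert_allclose(f, [1.0, -1.0], atol=1e-10)


def test_duplicated_points_opposite_labels_hit_box():
    K = np.ones((2, 2))
    sol = solve_svm_dual(K, np.array([1, -1]), C=0.5)
    np.testing.assert_allclose(sol.alpha, [0.5, 0.5], atol=1e-12)
    assert kkt_residual(sol, K) < 1e-6


def test_dual_matches_reference_solver(rng):
    for _ in range(12):
        n = int(rng.integers(2, 11))
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        y = rng.choice([-1.0, 1.0], n)
        while len(set(y)) < 2:
            y = rng.choice([-1.0, 1.0], n)
        C = float(rng.choice([0.1, 1.0, 10.0]))
        sol = solve_svm_dual(K, y, C)
        Kp = nearest_psd(K)
        assert abs(dual_objective(sol.alpha, y, Kp) - reference_qp(Kp, y, C)) < 1e-6
        assert kkt_residual(sol, K) < 1e-6
        assert np.all(sol.alpha >= -1e-12) and np.all(sol.alpha <= C + 1e-12)
        assert abs(sol.alpha @ y) < 1e-8


def test_single_label_training_set_rejected():
    with pytest.raises(ValueError, match="both labels"):
        solve_svm_dual(np.eye(2), np.array([1, 1]), C=1.0)


def test_predict_agrees_with_direct_evaluation(rng):
    n = 6
    A = rng.normal(size=(n, n))
    K = nearest_psd(A @ A.T / n)
    y = np.array([1, 1, 1, -1, -1, -1], dtype=float)
    sol = solve_svm_dual(K, y, C=1.0)
    for i in range(n):
        direct = float(np.sum(sol.alpha * sol.y * K[i]) + sol.b)
        expected = 1 if direct > 0 else (-1 if direct < 0 else None)
        if expected is not None:
            assert svm_predict(sol, K[i]) == expected


def test_predict_zero_decision_falls_back_to_majority():
    sol = SvmSolution(
        alpha=np.zeros(3), b=0.0, y=np.array([1.0, 1.0, -1.0]), C=1.0
    )
    assert svm_predict(sol, np.zeros(3)) == 1
    sol_neg = SvmSolution(
        alpha=np.zeros(3), b=0.0, y=np.array([-1.0, -1.0, 1.0]), C=1.0
    )
    assert svm_predict(sol_neg, np.zeros(3)) == -1


# ---------------------------------------------------------------------------
# KNN gate


def test_knn_select_all_when_k_equals_train_size(rng):
    test = random_profile(rng, patient_id="T")
    train = [random_profile(rng, patient_id=f"P{i}") for i in range(4)]
    assert sorted(knn_select(test, train, K=4)) == [0, 1, 2, 3]


def test_knn_identical_neighbor_wins(rng):
    from tsnet.similarity import patient_similarity

    test = random_profile(rng, patient_id="T")
    twin = PatientProfile("twin", list(test.biclusters), test.weights.copy())
    other = random_profile(rng, patient_id="x")
    assert patient_similarity(test, other) < 1.0 - 1e-9
    assert knn_select(test, [other, twin], K=1) == [1]


def test_knn_matches_sort_oracle_and_tie_order(rng):
    from tsnet.similarity import patient_similarity

    test = random_profile(rng, patient_id="T")
    train = [random_profile(rng, patient_id=f"P{i}") for i in range(8)]
    # duplicate one training profile to force a similarity tie
    train.append(PatientProfile("dup", list(train[0].biclusters), train[0].weights.copy()))
    sims = [patient_similarity(test, p) for p in train]
    picked = knn_select(test, train, K=5)
    expected = sorted(range(len(train)), key=lambda i: (-sims[i], i))[:5]
    assert picked == expected
    with pytest.raises(ValueError):
        knn_select(test, train, K=0)
    with pytest.raises(ValueError):
        knn_select(test, train, K=10)


def test_unanimous_neighborhood_short_circuits(rng, monkeypatch):
    import tsnet.classify as clf

    test = random_profile(rng, patient_id="T")
    train = [random_profile(rng, patient_id=f"P{i}") for i in range(5)]
    monkeypatch.setattr(
        clf, "solve_svm_dual", lambda *a, **k: pytest.fail("SVM must not run")
    )
    assert ppi_svm_knn(test, train, np.ones(5, dtype=int), K=3, C=1.0) == 1
    assert ppi_svm_knn(test, train, -np.ones(5, dtype=int), K=3, C=1.0) == -1


def test_mixed_pair_predicts_like_nearest(rng):
    pos = random_profile(rng, patient_id="pos")
    neg = random_profile(rng, patient_id="neg")
    test = PatientProfile("T", list(pos.biclusters), pos.weights.copy())
    label = ppi_svm_knn(test, [pos, neg], np.array([1, -1]), K=2, C=10.0)
    assert label == 1


def test_k1_reduces_to_nearest_neighbor(rng):
    train = [random_profile(rng, patient_id=f"P{i}") for i in range(6)]
    labels = np.array([1, -1, 1, -1, 1, -1])
    test = random_profile(rng, patient_id="T")
    nn = knn_select(test, train, K=1)[0]
    assert ppi_svm_knn(test, train, labels, K=1, C=1.0) == labels[nn]


# ---------------------------------------------------------------------------
# metrics


def test_metrics_hand_counts():
    truth = [1, 1, 1, -1, -1]
    pred = [1, 1, -1, 1, -1]  # TP=2 FP=1 FN=1 TN=1
    m = compute_metrics(truth, pred)
    assert m["precision"] == pytest.approx(2 / 3)
    assert m["recall"] == pytest.approx(2 / 3)
    assert m["f_measure"] == pytest.approx(2 / 3)
    assert m["accuracy"] == pytest.approx(3 / 5)


def test_metrics_perfect_and_degenerate():
    assert compute_metrics([1, -1], [1, -1]) == {
        "accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f_measure": 1.0
    }
    m = compute_metrics([1, 1], [-1, -1])
    assert m["precision"] == 0.0 and m["recall"] == 0.0 and m["f_measure"] == 0.0


# ---------------------------------------------------------------------------
# cross-validation harness (small synthetic cohorts)


def small_cohort(seed=3, noise_sd=0.05, identical_classes=False):
    return generate_benchmark(
        seed=seed,
        n_pos=8,
        n_neg=6,
        n_genes=20,
        T=6,
        noise_sd=noise_sd,
        missing_rate=0.05,
        n_disc_modules=2,
        decoy_modules=1,
        module_size=4,
        disc_window=(2, 5),
        identical_classes=identical_classes,
    )


def small_config(**kw):
    base = dict(reps=2, folds=3, K=3, seed=9, em_max_iter=50)
    base.update(kw)
    return PipelineConfig(**base)


def test_separable_synthetic_reaches_perfect_accuracy():
    ds, net, _ = small_cohort(noise_sd=0.05)
    report = cross_validate(ds, net, small_config())
    assert report.mean["accuracy"] == 1.0


def test_cross_validation_deterministic_under_seed():
    ds, net, _ = small_cohort()
    cfg = small_config()
    r1 = cross_validate(ds, net, cfg)
    r2 = cross_validate(ds, net, cfg)
    assert r1.predictions == r2.predictions
    assert r1.mean == r2.mean and r1.sd == r2.sd


def test_early_stage_full_length_equals_full_run():
    ds, net, _ = small_cohort()
    cfg = small_config()
    full = cross_validate(ds, net, cfg)
    staged = early_stage_eval(ds, net, cfg, [ds.n_times])
    assert staged[ds.n_times].predictions == full.predictions


def test_early_stage_skips_overlong_and_rejects_tiny(caplog):
    ds, net, _ = small_cohort()
    cfg = small_config(reps=1)
    reports = early_stage_eval(ds, net, cfg, [ds.n_times + 1])
    assert reports == {}
    with pytest.raises(ValueError, match="n >= 3"):
        early_stage_eval(ds, net, cfg, [2])


def test_parameter_selection_grid_runs():
    ds, net, _ = small_cohort()
    cfg = small_config(reps=1, select_grid={"K": [1, 3], "C": [1.0]})
    report = cross_validate(ds, net, cfg)
    assert 0.0 <= report.mean["accuracy"] <= 1.0
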