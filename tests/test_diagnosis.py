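"""RBF-SVM diagnosis: grid search, double CV, calibration, validation."""

import numpy as np
import pandas as pd
import pytest

from conftest import split_training, split_validation
from mirdiag.cohort import CohortSpec, generate_cohort
from mirdiag.diagnosis import (
    ComparatorSpec,
    DiagnosticModel,
    DoubleCVConfig,
    GridSpec,
    _pairwise_sq_cumulative,
    _svc_fit_precomputed,
    _svm_decision,
    choose_k,
    choose_threshold,
    comparator_diagnosis,
    double_cv,
    fit_final,
    inner_grid_search,
    platt_fit,
    sensitivity_specificity,
    validate,
)
from mirdiag.diffexpr import roc_auc


def _separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, 3))
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    Z[y == 1] += 4.0
    D2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    return Z, y, D2


class TestGridSpec:
    def test_grid_has_the_full_power_of_two_lattice(self):
        grid = GridSpec()
        assert len(grid.gamma_values) == 21
        assert len(grid.cost_values) == 15
        assert grid.n_pairs == 315
        assert grid.gamma_values[0] == 2.0**-10 and grid.gamma_values[-1] == 2.0**10
        assert grid.cost_values[0] == 2.0**-7 and grid.cost_values[-1] == 2.0**7

    def test_positive_values_enforced(self):
        with pytest.raises(ValueError):
            GridSpec(gamma_values=(-1.0,))


class TestFastSvmPath:
    def test_low_level_decision_equals_estimator(self, rng):
        """The libsvm fast path must match SVC.decision_function exactly."""
        for _ in range(25):
            n = int(rng.integers(12, 40))
            Z = rng.standard_normal((n, 4))
            y = (rng.random(n) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                continue
            D2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
            gamma = float(2.0 ** rng.integers(-6, 6))
            cost = float(2.0 ** rng.integers(-5, 5))
            K = np.exp(-gamma * D2)
            K_te = K[: max(3, n // 3)]
            ref = _svc_fit_precomputed(K, y, cost).decision_function(K_te)
            assert np.allclose(_svm_decision(K, y, K_te, cost), ref, atol=1e-12)


class TestPlatt:
    def test_matches_sklearn_sigmoid_calibration(self, rng):
        from sklearn.calibration import _sigmoid_calibration

        for _ in range(10):
            f = rng.standard_normal(60) + np.repeat([1.0, -1.0], 30)
            y = np.repeat([1, 0], 30)
            a, b = platt_fit(f, y)
            a_ref, b_ref = _sigmoid_calibration(f, y)
            assert a == pytest.approx(a_ref, abs=1e-5)
            assert b == pytest.approx(b_ref, abs=1e-5)


class TestInnerGridSearch:
    def test_separable_data_reaches_auc_one(self):
        _, y, D2 = _separable()
        gamma, cost, dec = inner_grid_search(D2, y, GridSpec(), 5, seed=1)
        assert roc_auc(dec, y) == 1.0

    def test_seeded_determinism(self):
        _, y, D2 = _separable(seed=3)
        out1 = inner_grid_search(D2, y, GridSpec(), 5, seed=5)
        out2 = inner_grid_search(D2, y, GridSpec(), 5, seed=5)
        assert out1[0] == out2[0] and out1[1] == out2[1]
        assert np.array_equal(out1[2], out2[2])

    def test_degenerate_inner_fold_rejected(self):
        _, y, D2 = _separable(n=20)
        y = y.copy()
        y[y == 0] = 1
        y[0] = 0  # a 1-sample class cannot be split into 5 folds
        with pytest.raises(ValueError):
            inner_grid_search(D2, y, GridSpec(), 5, seed=1)


class TestChoosers:
    def test_choose_k_constant_curve_returns_smallest(self):
        s = pd.DataFrame({"mean_auc": [0.9, 0.9, 0.9]}, index=pd.Index([2, 5, 8], name="K"))
        assert choose_k(s) == 2

    def test_choose_k_increasing_curve_returns_largest(self):
        s = pd.DataFrame({"mean_auc": [0.7, 0.8, 0.9]}, index=pd.Index([2, 5, 8], name="K"))
        assert choose_k(s) == 8

    def test_choose_k_plateau(self):
        ks = list(range(2, 21))
        auc = [0.7 + 0.02 * min(k, 10) for k in ks]
        s = pd.DataFrame({"mean_auc": auc}, index=pd.Index(ks, name="K"))
        assert choose_k(s) == 10

    def test_choose_threshold_tie_rules(self):
        # separable probabilities: every candidate perfect, tie -> 0.5
        probs = np.array([0.9, 0.9, 0.1, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert choose_threshold(probs, labels) == 0.5
        # all-equal probabilities: all candidates equal, tie -> 0.5
        assert choose_threshold(np.full(4, 0.3), labels) == 0.5

    def test_choose_threshold_dominant_candidate(self):
        """0.55 strictly dominates; exhaustive check over the 5 candidates."""
        probs = np.array([0.58, 0.62, 0.95, 0.52, 0.54, 0.12])
        labels = np.array([1, 1, 1, 0, 0, 0])
        scores = {
            t: sum(sensitivity_specificity(probs, labels, t)) / 2
            for t in (0.5, 0.55, 0.6, 0.65, 0.7)
        }
        assert max(scores, key=scores.get) == 0.55
        assert choose_threshold(probs, labels) == 0.55

    def test_threshold_monotonicity(self, rng):
        """Raising the cutoff never raises sensitivity or lowers specificity."""
        probs = rng.random(200)
        labels = (rng.random(200) < probs).astype(int)
        grid = np.linspace(0.05, 0.95, 19)
        sens = [sensitivity_specificity(probs, labels, t)[0] for t in grid]
        spec = [sensitivity_specificity(probs, labels, t)[1] for t in grid]
        assert all(s2 <= s1 + 1e-12 for s1, s2 in zip(sens, sens[1:]))
        assert all(s2 >= s1 - 1e-12 for s1, s2 in zip(spec, spec[1:]))


class TestDoubleCv:
    def test_accuracy_identity_and_metric_ranges(self, small_cohort):
        _, expression, metadata, truth = small_cohort
        X, y = split_training(expression, metadata)
        ranked = sorted(truth)
        cfg = DoubleCVConfig(n_repeats=1, k_range=(2, 4, 6), seed=11)
        summary, oof = double_cv(X, y, ranked, cfg)
        assert list(summary.index) == [2, 4, 6]
        for col in ("mean_auc", "mean_sensitivity", "mean_specificity", "mean_accuracy"):
            assert summary[col].between(0, 1).all()
        assert len(oof[4]) == len(y)  # each sample scored once per repeat

    def test_k_beyond_available_markers_rejected(self, small_cohort):
        _, expression, metadata, truth = small_cohort
        X, y = split_training(expression, metadata)
        with pytest.raises(ValueError, match="exceeds"):
            double_cv(X, y, sorted(truth), DoubleCVConfig(n_repeats=1, k_range=(50,)))

    def test_full_determinism(self, small_cohort):
        _, expression, metadata, truth = small_cohort
        X, y = split_training(expression, metadata)
        cfg = DoubleCVConfig(n_repeats=1, k_range=(3,), seed=7)
        s1, o1 = double_cv(X, y, sorted(truth), cfg)
        s2, o2 = double_cv(X, y, sorted(truth), cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(o1[3], o2[3])


@pytest.fixture(scope="module")
def fitted(small_cohort):
    _, expression, metadata, truth = small_cohort
    X, y = split_training(expression, metadata)
    model = fit_final(X, y, sorted(truth), gamma=0.1, cost=1.0, threshold=0.55, seed=3)
    return X, y, model


class TestFinalModel:
    def test_probabilities_are_valid_and_informative(self, fitted):
        X, y, model = fitted
        probs = model.predict_proba(X)
        assert np.all((probs >= 0) & (probs <= 1))
        assert roc_auc(probs, y) > 0.9

    def test_json_round_trip_is_exact(self, fitted):
        X, _, model = fitted
        clone = DiagnosticModel.from_json(model.to_json())
        assert np.allclose(model.predict_proba(X), clone.predict_proba(X), atol=1e-12)

    def test_prediction_uses_only_panel_markers(self, fitted, small_cohort):
        _, expression, metadata, truth = small_cohort
        X, y, model = fitted
        X_pert = X.copy()
        others = [f for f in X.index if f not in truth]
        X_pert.loc[others] += 123.0
        assert np.allclose(model.predict_proba(X), model.predict_proba(X_pert))

    def test_vanishing_gamma_approaches_linear_ordering(self, rng):
        """gamma -> 0: RBF decision ordering matches a linear-kernel SVM."""
        from scipy import stats
        from sklearn.svm import SVC

        n = 40
        X = rng.standard_normal((n, 2))
        y = (X[:, 0] + 0.3 * rng.standard_normal(n) > 0).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        expr = pd.DataFrame(X.T, index=["m1", "m2"], columns=[f"s{i}" for i in range(n)])
        model = fit_final(expr, y, ["m1", "m2"], gamma=1e-6, cost=100.0, seed=0)
        Z = (X - model.center) / model.scale
        ref = SVC(kernel="linear", C=100.0).fit(Z, y).decision_function(Z)
        rho = stats.spearmanr(model.decision_function(expr), ref).statistic
        assert rho > 0.99

    def test_single_class_rejected(self, small_cohort):
        _, expression, metadata, truth = small_cohort
        X, _ = split_training(expression, metadata)
        with pytest.raises(ValueError, match="single class"):
            fit_final(X, np.ones(X.shape[1]), sorted(truth), 0.1, 1.0)


@pytest.fixture(scope="module")
def model_and_val(small_cohort):
    _, expression, metadata, truth = small_cohort
    X_tr, y_tr = split_training(expression, metadata)
    X_va, y_va = split_validation(expression, metadata)
    model = fit_final(X_tr, y_tr, sorted(truth), gamma=0.1, cost=1.0,
                      threshold=0.55, seed=3)
    return model, X_va, y_va


class TestValidate:
    def test_report_contract(self, model_and_val):
        model, X_va, y_va = model_and_val
        report = validate(model, X_va, y_va, n_boot=100, seed=1)
        c = report.confusion
        assert c["tp"] + c["fn"] + c["fp"] + c["tn"] == X_va.shape[1]
        assert 0.0 <= report.auc <= 1.0
        assert report.auc_ci[0] <= report.auc_ci[1]
        assert np.all(report.band_lower <= report.band_upper + 1e-12)
        d = report.to_dict()
        assert set(d) >= {"auc", "sensitivity", "specificity", "confusion", "band"}

    def test_training_overlap_rejected(self, model_and_val, small_cohort):
        model, _, _ = model_and_val
        _, expression, metadata, _ = small_cohort
        X_tr, y_tr = split_training(expression, metadata)
        with pytest.raises(ValueError, match="overlap"):
            validate(model, X_tr, y_tr)

    def test_single_class_cohort_warns_with_nan_rate(self, model_and_val, small_cohort):
        model, X_va, y_va = model_and_val
        only_cases = X_va.iloc[:, (y_va == 1).nonzero()[0]]
        with pytest.warns(UserWarning, match="absent"):
            report = validate(model, only_cases, np.ones(only_cases.shape[1], dtype=int))
        assert np.isnan(report.specificity)
        assert report.sensitivity >= 0.0

    def test_permuted_validation_labels_are_chance(self, model_and_val):
        model, X_va, y_va = model_and_val
        rng = np.random.default_rng(9)
        report = validate(model, X_va, rng.permutation(y_va), n_boot=50, seed=2)
        assert 0.35 <= report.auc <= 0.65


class TestComparator:
    def test_all_below_cutoff(self):
        block = comparator_diagnosis(np.full(10, 5.0), np.array([1] * 4 + [0] * 6),
                                     n_boot=10)
        assert block["sensitivity"] == 0.0
        assert block["specificity"] == 1.0

    def test_study_training_table_rates(self):
        """47 of 63 cases above the 37 U/mL cutoff -> sensitivity 0.746."""
        values = np.concatenate([
            np.full(47, 100.0), np.full(16, 10.0),   # cases
            np.full(63, 12.0),                        # controls below cutoff
        ])
        labels = np.array([1] * 63 + [0] * 63)
        block = comparator_diagnosis(values, labels, ComparatorSpec(), n_boot=10)
        assert block["sensitivity"] == pytest.approx(47 / 63, abs=1e-12)
        assert round(block["sensitivity"], 3) == 0.746

    def test_missing_values_counted_negative(self):
        values = np.array([100.0, np.nan, 5.0, np.nan])
        labels = np.array([1, 1, 0, 0])
        block = comparator_diagnosis(values, labels, n_boot=10)
        assert block["n_missing"] == 2
        assert block["confusion"]["fn"] == 1

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            ComparatorSpec(cutoff=0.0)


class TestExpressionModelBeatsComparator:
    def test_strong_expression_signal_outperforms_overlapping_scalar(self):
        """With strong miRNA signal and an overlapping scalar marker, the
        panel model's validation AUC exceeds the comparator's."""
        from mirdiag.cohort import generate_comparator

        spec = CohortSpec(p=80, informative_ids=tuple(range(5)),
                          effect_sizes=(2.0,) * 5, seed=99)
        expression, metadata, truth = generate_cohort(spec)
        metadata = generate_comparator(metadata, (60.0, 1.2), (30.0, 1.2), seed=5)
        X_tr, y_tr = split_training(expression, metadata)
        X_va, y_va = split_validation(expression, metadata)
        model = fit_final(X_tr, y_tr, sorted(truth), gamma=0.1, cost=1.0, seed=1)
        report = validate(model, X_va, y_va, n_boot=50, seed=2)
        va_mask = (metadata["cohort"] == "validation").to_numpy()
        block = comparator_diagnosis(
            metadata.loc[va_mask, "comparator_value"].to_numpy(), y_va, n_boot=50)
        assert report.auc > block["auc"]
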