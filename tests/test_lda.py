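"""Fisher discriminant and stepwise selection: closed-form cases,
brute-force direction/selection oracles, invariants, and LOO behavior."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from vocsense import (FisherLDA, MulticollinearityError, StepwiseLDA,
                      classify, fisher_fit, forward_stepwise_select, loocv,
                      standardize, wilks_lambda)
from vocsense.cohort import Cohort
from vocsense.lda import _stepwise_scan
from vocsense.preprocess import StandardizedProfile

from conftest import small_config


def two_group_data(rng, n0=10, n1=8, p=4, shift=1.5):
    X = rng.standard_normal((n0 + n1, p))
    X[n0:, 0] += shift
    y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
    return X, y


def fisher_criterion(X, y, direction):
    """Between-group over within-group variance of the projection."""
    z = X @ direction
    z0, z1 = z[y == 0], z[y == 1]
    between = (z1.mean() - z0.mean()) ** 2
    within = ((z0 - z0.mean()) ** 2).sum() + ((z1 - z1.mean()) ** 2).sum()
    return between / within


class TestFisherFit:
    def test_one_feature_equal_priors_threshold_at_midpoint(self):
        X = np.array([[-1.0], [0.0], [1.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fisher_fit(X, y)
        # projected midpoint of group means 0 and 2
        assert model.threshold_ / model.coef_[0] == pytest.approx(1.0)
        assert model.coef_[0] > 0

    def test_isotropic_pooled_covariance_direction_is_mean_difference(self):
        # each group's centered points form a symmetric cross, so the
        # pooled covariance is proportional to the identity
        cross = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        mu1 = np.array([2.0, -1.0])
        X = np.vstack([cross, cross + mu1])
        y = np.r_[np.zeros(4, int), np.ones(4, int)]
        model = fisher_fit(X, y)
        np.testing.assert_allclose(model.coef_ / np.linalg.norm(model.coef_),
                                   mu1 / np.linalg.norm(mu1), atol=1e-12)

    def test_direction_matches_dense_search_over_unit_directions(self):
        # maximize the Fisher criterion numerically over angles: the
        # brute-force oracle for the 2-feature discriminant direction
        rng = np.random.default_rng(3)
        X, y = two_group_data(rng, n0=3, n1=3, p=2)
        model = fisher_fit(X, y)
        angles = np.linspace(0, np.pi, 2000, endpoint=False)
        crits = [fisher_criterion(X, y, np.array([np.cos(a), np.sin(a)]))
                 for a in angles]
        a0 = angles[int(np.argmax(crits))]
        res = minimize_scalar(
            lambda a: -fisher_criterion(X, y,
                                        np.array([np.cos(a), np.sin(a)])),
            bounds=(a0 - 0.01, a0 + 0.01), method="bounded",
            options={"xatol": 1e-12})
        best = np.array([np.cos(res.x), np.sin(res.x)])
        w = model.coef_ / np.linalg.norm(model.coef_)
        angular_error = np.arccos(np.clip(abs(best @ w), -1, 1))
        assert angular_error <= 1e-6

    def test_affine_feature_map_preserves_classifications(self):
        rng = np.random.default_rng(7)
        X, y = two_group_data(rng, p=3)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal(3)
        preds = fisher_fit(X, y).predict(X)
        preds_mapped = fisher_fit(X @ A + b, y).predict(X @ A + b)
        np.testing.assert_array_equal(preds, preds_mapped)

    def test_agrees_with_sklearn_lda_predictions(self):
        rng = np.random.default_rng(11)
        X, y = two_group_data(rng, n0=30, n1=20, p=5, shift=1.0)
        ours = fisher_fit(X, y).predict(X)
        theirs = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(
            X, y).predict(X)
        np.testing.assert_array_equal(ours, theirs)

    def test_singular_pooled_covariance_raises_multicollinearity(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0],
                      [3.0, 6.0], [4.0, 8.0], [5.0, 10.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(MulticollinearityError):
            fisher_fit(X, y)


class TestStepwiseSelection:
    def test_duplicate_feature_never_entered(self):
        rng = np.random.default_rng(1)
        X, y = two_group_data(rng, p=3, shift=3.0)
        X = np.hstack([X, X[:, [0]]])  # column 3 duplicates column 0
        sel = _stepwise_scan(X, y, max_features=4, tolerance_floor=1e-3,
                             entry_threshold=0.0)
        assert not {0, 3} <= set(sel.indices)
        assert all(t >= 1e-3 for t in sel.tolerances)

    def test_single_informative_feature_found_first(self):
        # oracle: exhaustive single-feature Wilks'-lambda scan
        rng = np.random.default_rng(2)
        n0, n1, p = 12, 10, 30
        X = rng.standard_normal((n0 + n1, p))
        y = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        X[y == 1, 17] += 3.0
        lambdas = [wilks_lambda(X[:, [j]], y) for j in range(p)]
        assert int(np.argmin(lambdas)) == 17
        sel = _stepwise_scan(X, y, 5, 1e-3, 3.84)
        assert sel.indices[0] == 17

    def test_first_pick_matches_exhaustive_scan_on_cohort(self, small_cohort):
        from vocsense import standardize_cohort

        X = standardize_cohort(small_cohort)
        y = small_cohort.y
        sel = forward_stepwise_select(small_cohort, max_features=5)
        lambdas = np.array([wilks_lambda(X[:, [j]], y)
                            for j in range(X.shape[1])])
        assert sel.indices[0] == int(np.argmin(lambdas)) + 1  # 1-based

    def test_wilks_lambda_non_increasing_along_entry_path(self, small_cohort):
        sel = forward_stepwise_select(small_cohort, max_features=8)
        assert all(b <= a + 1e-12 for a, b in zip(sel.wilks_path,
                                                  sel.wilks_path[1:]))

    def test_selection_capped_by_smallest_group_and_no_duplicates(
            self, small_cohort):
        sel = forward_stepwise_select(small_cohort, max_features=9)
        assert len(sel.indices) <= 9
        assert len(set(sel.indices)) == len(sel.indices)

    def test_max_features_above_group_size_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="smallest"):
            forward_stepwise_select(small_cohort, max_features=200)


def toy_separable_cohort():
    """Four samples, two clearly separated groups, tiny grid."""
    rng = np.random.default_rng(0)
    from vocsense import Chromatogram

    samples = []
    for i in range(4):
        base = rng.uniform(1.0, 1.2, size=30)
        if i < 2:
            base[10] += 5.0  # cancer signature
            group = "cancer"
        else:
            base[20] += 5.0
            group = "control"
        samples.append(Chromatogram(f"s{i}", group, base, i))
    return Cohort(samples)


class TestClassifyAndLoocv:
    def test_profile_at_cancer_mean_labeled_cancer(self, small_cohort):
        from vocsense import group_mean_profile, standardize_cohort

        X = standardize_cohort(small_cohort)
        model = StepwiseLDA(max_features=5).fit(X, small_cohort.y)
        mean_prof = StandardizedProfile(
            "m", group_mean_profile(small_cohort, "cancer"))
        label, score = classify(model, mean_prof)
        assert label == "cancer"
        assert score > 0

    def test_score_tie_breaks_to_control(self):
        X = np.array([[0.0], [0.5], [1.5], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = StepwiseLDA(features=[0]).fit(X, y)
        # threshold sits at the projected-mean midpoint: feature value 1.0
        assert model.predict(np.array([[1.0]]))[0] == 0

    def test_loo_on_separable_toy_cohort_is_perfect(self):
        cm = loocv(toy_separable_cohort(), max_features=1)
        assert cm.fn == cm.fp == 0
        assert cm.n == 4

    def test_confusion_counts_conserve_cohort_size(self, small_cohort):
        cm = loocv(small_cohort, max_features=5)
        assert cm.n == len(small_cohort)

    def test_reselect_protocol_runs_and_conserves_counts(self):
        from vocsense import simulate_cohort

        cohort = simulate_cohort(small_config(seed=6))
        cm = loocv(cohort, protocol="reselect_per_fold", max_features=4)
        assert cm.n == len(cohort)

    def test_unknown_protocol_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="protocol"):
            loocv(small_cohort, protocol="bootstrap")

    def test_within_sample_accuracy_rarely_below_loo(self, replicate_tables):
        # optimism of in-sample fit: expected to hold in >= 90% of replicates
        wins = sum(rep["within"].accuracy >= rep["loo"].accuracy
                   for rep in replicate_tables.values())
        assert wins >= 0.9 * len(replicate_tables)
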