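import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoclust.preprocess import (FeatureMatrix, daily_grid, extract_features,
                                   impute_cohort, iterative_impute, reduce_pca,
                                   rolling_mean_impute, screen_patients, standardize)
from phenoclust.synth import (Cohort, CohortConfig, LabSeries, generate_cohort,
                              inject_missingness)

from conftest import separable_config


def _toy_cohort(empty_variables_per_patient):
    """Cohort with 40 variables; patient i has the given number emptied."""
    cfg = CohortConfig(n_patients=len(empty_variables_per_patient), n_clusters=2,
                       n_lab_variables=40, n_static_continuous=1, n_static_binary=1,
                       mean_measurements_per_variable=2, seed=0)
    cohort = generate_cohort(cfg)
    for p, n_empty in zip(cohort.patients, empty_variables_per_patient):
        for s in p.labs[:n_empty]:
            s.times = np.empty(0)
            s.values = np.empty(0)
    return cohort


class TestScreen:
    def test_ten_percent_boundary(self):
        # 5/40 = 0.125 excluded; 3/40 = 0.075 retained
        cohort = _toy_cohort([5, 3])
        screened, report = screen_patients(cohort, threshold=0.10)
        assert report.excluded_ids == [cohort.patients[0].patient_id]
        assert report.included_ids == [cohort.patients[1].patient_id]
        assert report.missing_fraction[cohort.patients[0].patient_id] == 0.125
        assert report.missing_fraction[cohort.patients[1].patient_id] == 0.075

    def test_threshold_one_keeps_everyone(self):
        cohort = _toy_cohort([40, 10, 0])
        screened, report = screen_patients(cohort, threshold=1.0)
        assert not report.excluded_ids
        assert len(screened) == 3

    def test_threshold_zero_strict_inequality(self):
        cohort = _toy_cohort([1, 0])
        _, report = screen_patients(cohort, threshold=0.0)
        assert report.excluded_ids == [cohort.patients[0].patient_id]
        assert report.included_ids == [cohort.patients[1].patient_id]

    def test_partition_invariant(self):
        cohort = _toy_cohort([0, 2, 4, 6, 8])
        _, report = screen_patients(cohort, threshold=0.10)
        assert sorted(report.included_ids + report.excluded_ids) == sorted(
            cohort.patient_ids)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            screen_patients(Cohort(patients=[], variable_names=["a"]))


class TestRollingMeanImpute:
    def test_gap_filled_with_window_mean(self):
        # observed on days 1,2,4; day 3 missing; window=2 -> mean(1,2)=1.5
        s = LabSeries("x", np.array([0.0, 24.0, 72.0]), np.array([1.0, 2.0, 4.0]))
        out = rolling_mean_impute(s, daily_grid(96.0), window=2, population_mean=0.0)
        assert out.values.tolist() == [1.0, 2.0, 1.5, 4.0]
        assert out.times.tolist() == [0.0, 24.0, 48.0, 72.0]

    def test_no_gaps_unchanged(self):
        s = LabSeries("x", np.array([1.0, 25.0, 49.0]), np.array([5.0, 6.0, 7.0]))
        out = rolling_mean_impute(s, daily_grid(72.0), window=3, population_mean=0.0)
        np.testing.assert_array_equal(out.times, s.times)
        np.testing.assert_array_equal(out.values, s.values)

    def test_empty_series_constant_population_mean(self):
        s = LabSeries("x", np.empty(0), np.empty(0))
        out = rolling_mean_impute(s, daily_grid(72.0), window=3, population_mean=7.0)
        assert np.all(out.values == 7.0)
        assert len(out) == 3

    def test_empty_series_without_population_mean_rejected(self):
        s = LabSeries("x", np.empty(0), np.empty(0))
        with pytest.raises(ValueError):
            rolling_mean_impute(s, daily_grid(48.0), window=3,
                                population_mean=np.nan)

    def test_leading_slots_use_population_mean(self):
        s = LabSeries("x", np.array([50.0]), np.array([4.0]))
        out = rolling_mean_impute(s, daily_grid(72.0), window=2, population_mean=1.0)
        # day 0 and 1 precede the first observation; day 2 holds it
        assert out.values.tolist() == [1.0, 1.0, 4.0]

    def test_imputed_values_propagate_through_window(self):
        s = LabSeries("x", np.array([0.0]), np.array([2.0]))
        out = rolling_mean_impute(s, daily_grid(96.0), window=1, population_mean=9.0)
        # window=1: each gap copies the previous value
        assert out.values.tolist() == [2.0, 2.0, 2.0, 2.0]


class TestIterativeImpute:
    def test_no_missing_identity(self):
        X = np.arange(12, dtype=float).reshape(4, 3)
        np.testing.assert_array_equal(iterative_impute(X), X)

    def test_exact_linear_relation_recovered(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, np.nan], [4.0, 8.0]])
        out = iterative_impute(X, n_iter=10, seed=0)
        assert out[2, 1] == pytest.approx(6.0, abs=1e-6)

    def test_converged_after_ten_iterations(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 5))
        X[:, 4] = X[:, :4] @ np.array([1.0, -2.0, 0.5, 0.3]) + 0.1 * rng.normal(size=80)
        mask = rng.random(X.shape) < 0.05
        X[mask] = np.nan
        X10, info10 = iterative_impute(X, n_iter=10, seed=0, return_info=True)
        X11, info11 = iterative_impute(X, n_iter=11, seed=0, return_info=True)
        # the 10->11 update moves no cell by more than the reported value
        assert np.max(np.abs(X11 - X10)) <= info10["max_last_change"] + 1e-9
        assert info11["max_last_change"] <= info10["max_last_change"] + 1e-9

    def test_all_missing_column_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError):
            iterative_impute(X)


class TestExtractFeatures:
    def test_mean_and_sample_variance(self):
        cfg = CohortConfig(n_patients=2, n_clusters=2, n_lab_variables=1,
                           n_static_continuous=1, n_static_binary=0,
                           mean_measurements_per_variable=3, seed=0)
        cohort = generate_cohort(cfg)
        v = cohort.variable_names[0]
        cohort.patients[0].labs = [
            LabSeries(v, np.array([0.0, 1.0, 2.0]), np.array([2.0, 4.0, 6.0]))]
        cohort.patients[1].labs = [
            LabSeries(v, np.array([0.0]), np.array([5.0]))]
        fm = extract_features(cohort)
        assert fm.column(f"{v}__mean")[0] == pytest.approx(4.0)
        assert fm.column(f"{v}__var")[0] == pytest.approx(4.0)  # divisor n-1
        assert fm.column(f"{v}__mean")[1] == pytest.approx(5.0)
        assert fm.column(f"{v}__var")[1] == 0.0  # single measurement

    def test_constant_series_zero_variance(self):
        cfg = CohortConfig(n_patients=1, n_clusters=1, n_lab_variables=1,
                           n_static_continuous=0, n_static_binary=1,
                           mean_measurements_per_variable=4, seed=0)
        cohort = generate_cohort(cfg)
        v = cohort.variable_names[0]
        cohort.patients[0].labs = [
            LabSeries(v, np.array([0.0, 1.0]), np.array([3.0, 3.0]))]
        fm = extract_features(cohort)
        assert fm.column(f"{v}__var")[0] == 0.0

    def test_column_order_statics_then_roster(self):
        cohort = generate_cohort(separable_config(n_patients=8, seed=0))
        fm = extract_features(impute_cohort(cohort))
        q = len(cohort.static_names)
        assert fm.feature_names[:q] == cohort.static_names
        assert fm.feature_names[q] == f"{cohort.variable_names[0]}__mean"
        assert fm.feature_names[q + 1] == f"{cohort.variable_names[0]}__var"

    def test_variance_features_nonnegative_and_finite(self):
        cohort = generate_cohort(separable_config(n_patients=60, seed=2,
                                                  missing_variable_rate=0.05))
        screened, _ = screen_patients(cohort)
        fm = extract_features(impute_cohort(screened))
        assert np.all(np.isfinite(fm.values))
        var_cols = [i for i, n in enumerate(fm.feature_names) if n.endswith("__var")]
        assert np.all(fm.values[:, var_cols] >= 0)

    def test_pipeline_noop_on_complete_cohort(self):
        cohort = generate_cohort(separable_config(n_patients=25, seed=5))
        direct = extract_features(impute_cohort(cohort))
        screened, report = screen_patients(cohort)
        assert not report.excluded_ids
        via_screen = extract_features(impute_cohort(screened))
        np.testing.assert_allclose(direct.values, via_screen.values)


class TestStandardize:
    def test_two_point_column(self):
        fm = FeatureMatrix(np.array([[0.0], [10.0]]), ["a"], ["p1", "p2"])
        out = standardize(fm)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(rng.normal(size=(50, 4)), list("abcd"),
                           [f"p{i}" for i in range(50)])
        once = standardize(fm)
        twice = standardize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_column_maps_to_zeros(self):
        X = np.column_stack([np.ones(5), np.arange(5, dtype=float)])
        fm = FeatureMatrix(X, ["const", "x"], [f"p{i}" for i in range(5)])
        out = standardize(fm)
        assert np.all(out.values[:, 0] == 0.0)
        assert np.all(np.isfinite(out.values))
        assert out.scaling == "standardized"


class TestReducePCA:
    def test_rank_one_exact(self):
        u = np.arange(1.0, 7.0)[:, None]
        X = u @ np.array([[1.0, 2.0, -1.0]])
        fm = FeatureMatrix(X, list("abc"), [f"p{i}" for i in range(6)])
        out = reduce_pca(fm, 1)
        comp = out.meta["components"]
        recon = out.values @ comp
        Xs = standardize(fm).values
        np.testing.assert_allclose(recon, Xs - Xs.mean(0), atol=1e-10)

    def test_full_rank_preserves_distances(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(rng.normal(size=(12, 4)), list("abcd"),
                           [f"p{i}" for i in range(12)])
        out = reduce_pca(fm, 4)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(
            pdist(out.values), pdist(standardize(fm).values), atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(2)
        fm = FeatureMatrix(rng.normal(size=(10, 4)), list("abcd"),
                           [f"p{i}" for i in range(10)])
        out = reduce_pca(fm, 4)
        Xs = standardize(fm).values
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xs.T)))[::-1]
        np.testing.assert_allclose(
            out.meta["explained_variance_ratio"], eig / eig.sum(), atol=1e-10)

    def test_out_of_range_rejected(self):
        fm = FeatureMatrix(np.eye(3), list("abc"), list("xyz"))
        with pytest.raises(ValueError):
            reduce_pca(fm, 5)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_extracted_features_always_finite(seed):
    cfg = CohortConfig(n_patients=12, n_clusters=2, n_lab_variables=4,
                       n_static_continuous=2, n_static_binary=2,
                       mean_measurements_per_variable=3,
                       missing_variable_rate=0.1, seed=seed)
    cohort = generate_cohort(cfg)
    screened, _ = screen_patients(cohort)
    if not screened.patients:
        return
    fm = extract_features(impute_cohort(screened))
    assert np.all(np.isfinite(fm.values))
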