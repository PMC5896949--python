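import math
import warnings

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from photoanthro.estimators import measure_photo
from photoanthro.regression_eval import (
    EvaluationError,
    ManualMeasurements,
    ObservationMatrix,
    ViewSet,
    acceptable_r,
    adequacy,
    all_view_subsets,
    assemble_observations,
    feature_table,
    fit_regression,
    loocv_predict,
    mad_mapd,
    predict,
    reliability,
    sweep_view_combinations,
    tem,
)


def make_obs(X, y, units, target="height_ld", views=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    views = views or tuple(range(1, X.shape[1] + 1))
    sessions = []
    counts = {}
    for u in units:
        counts[u] = counts.get(u, 0) + 1
        sessions.append(counts[u])
    return ObservationMatrix(
        view_set=ViewSet(views),
        target=target,
        unit_ids=tuple(units),
        session_ids=tuple(sessions),
        X=X,
        x_ref=np.asarray(y, dtype=float),
    )


class TestViewSet:
    def test_sorted_deduplicated(self):
        assert ViewSet((3, 1, 3)).members == (1, 3)

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(EvaluationError):
            ViewSet(())
        with pytest.raises(EvaluationError):
            ViewSet((0, 1))

    def test_thirty_one_subsets(self):
        subsets = all_view_subsets()
        assert len(subsets) == 31
        assert len(set(s.members for s in subsets)) == 31


class TestAssembly:
    def test_single_view_height_matrix_shape(self, default_records):
        recs = [r for r in default_records if r.backend == "calibration"]
        manual = {f"P{i:03d}": 1700.0 for i in range(31)}
        obs = assemble_observations(recs, "height_ld", ViewSet((1,)), manual)
        assert obs.X.shape == (93, 1)  # 31 participants x 3 sessions
        assert len(obs.units) == 31

    def test_muac_pair_matrix_counts_arm_units(self, default_records):
        recs = [r for r in default_records if r.backend == "calibration"]
        manual = {(f"P{i:03d}", s): 290.0 for i in range(31) for s in ("left", "right")}
        obs = assemble_observations(recs, "muac", ViewSet((1, 3)), manual)
        assert obs.X.shape == (186, 2)  # 62 arms x 3 sessions
        assert len(obs.units) == 62

    def test_height_feature_averages_the_two_arm_side_photos(self, default_bundle):
        recs = [measure_photo(p.noisy, "calibration") for p in default_bundle.photos]
        feats = feature_table(recs, "height_ld")
        pid = default_bundle.participants[0].participant_id
        per_photo = [
            r.H_LD for r in recs if r.participant_id == pid and r.session_id == 1 and r.view == 2
        ]
        assert len(per_photo) == 2
        assert feats[pid][1][2] == pytest.approx(np.mean(per_photo))

    def test_missing_view_is_reported(self, default_records):
        recs = [
            r
            for r in default_records
            if r.backend == "calibration" and not (r.participant_id == "P000" and r.view == 4)
        ]
        manual = {f"P{i:03d}": 1700.0 for i in range(31)}
        with pytest.raises(EvaluationError, match="P000.*view 4"):
            assemble_observations(recs, "height_ld", ViewSet((1, 4)), manual)


class TestFitRegression:
    def test_exact_linear_data_recovered(self):
        f = np.arange(10.0)
        obs = make_obs(f[:, None], 2.0 * f + 3.0, units=[f"u{i}" for i in range(10)])
        model = fit_regression(obs)
        assert model.weights[1] == pytest.approx(2.0, abs=1e-9)
        assert model.bias == pytest.approx(3.0, abs=1e-9)
        assert np.allclose(predict(model, obs), obs.x_ref, atol=1e-9)

    def test_constant_feature_warns_and_returns_minimum_norm(self):
        obs = make_obs(np.ones((8, 1)), np.full(8, 5.0), units=[f"u{i}" for i in range(8)])
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            model = fit_regression(obs)
        assert np.allclose(predict(model, obs), 5.0, atol=1e-9)

    def test_too_few_rows_rejected(self):
        obs = make_obs(np.arange(2.0)[:, None], [1.0, 2.0], units=["a", "b"])
        with pytest.raises(EvaluationError):
            fit_regression(obs)

    def test_noisy_recovery_within_three_standard_errors(self):
        """OLS on n=93 with sigma=2 mm noise recovers (w, b) = (1, 0) reliably."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            f = rng.uniform(1500.0, 1900.0, 93)
            y = f + rng.normal(0.0, 2.0, 93)
            obs = make_obs(f[:, None], y, units=[f"u{i}" for i in range(93)])
            model = fit_regression(obs)
            X = np.column_stack([f, np.ones(93)])
            resid = y - predict(model, obs)
            sigma2 = resid @ resid / (93 - 2)
            cov = sigma2 * np.linalg.inv(X.T @ X)
            se_w, se_b = np.sqrt(np.diag(cov))
            if abs(model.weights[1] - 1.0) < 3 * se_w and abs(model.bias) < 3 * se_b:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_matches_sklearn_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        obs = make_obs(X, y, units=[f"u{i}" for i in range(40)], views=(1, 3, 5))
        model = fit_regression(obs)
        sk = LinearRegression().fit(X, y)
        assert np.allclose([model.weights[v] for v in (1, 3, 5)], sk.coef_, atol=1e-9)
        assert model.bias == pytest.approx(sk.intercept_, abs=1e-9)


class TestLOOCV:
    def _random_obs(self, seed=0, n_units=8, n_sessions=3, k=2):
        rng = np.random.default_rng(seed)
        units = [f"u{i}" for i in range(n_units) for _ in range(n_sessions)]
        X = rng.uniform(100.0, 200.0, (len(units), k))
        y = X @ rng.uniform(0.5, 1.5, k) + rng.normal(0.0, 3.0, len(units))
        return make_obs(X, y, units=units, views=tuple(range(1, k + 1)))

    def test_exact_on_noiseless_linear_data(self):
        f = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        obs = make_obs(f[:, None], 4.0 * f - 1.0, units=["a", "a", "b", "b", "c", "c"])
        assert np.allclose(loocv_predict(obs), obs.x_ref, atol=1e-9)

    def test_left_out_unit_reference_cannot_leak(self):
        obs = self._random_obs(seed=1)
        preds = loocv_predict(obs)
        y2 = obs.x_ref.copy()
        held = np.array([u == "u3" for u in obs.unit_ids])
        y2[held] += 500.0  # corrupt only the held-out unit's reference
        obs2 = make_obs(obs.X, y2, units=list(obs.unit_ids), views=obs.view_set.members)
        preds2 = loocv_predict(obs2)
        assert np.allclose(preds[held], preds2[held], atol=1e-12)
        assert not np.allclose(preds[~held], preds2[~held])

    def test_matches_naive_refit_oracle(self):
        for seed in range(5):
            obs = self._random_obs(seed=seed)
            preds = loocv_predict(obs)
            for unit in obs.units:
                held = np.array([u == unit for u in obs.unit_ids])
                sk = LinearRegression().fit(obs.X[~held], obs.x_ref[~held])
                assert np.allclose(preds[held], sk.predict(obs.X[held]), atol=1e-9)

    def test_too_few_units_rejected(self):
        obs = make_obs(np.arange(4.0)[:, None], np.arange(4.0), units=["a", "a", "b", "b"])
        with pytest.raises(EvaluationError):
            loocv_predict(obs)

    def test_adding_a_view_never_increases_in_sample_rss(self, default_records):
        recs = [r for r in default_records if r.backend == "reference"]
        manual = {f"P{i:03d}": 1700.0 + 3 * i for i in range(31)}
        rss = {}
        for vs in all_view_subsets():
            obs = assemble_observations(recs, "height_ld", vs, manual)
            model = fit_regression(obs)
            resid = obs.x_ref - predict(model, obs)
            rss[vs.members] = resid @ resid
        for members, value in rss.items():
            for smaller in rss:
                if set(smaller) < set(members):
                    assert value <= rss[smaller] + 1e-6


class TestMetrics:
    def test_mad_mapd_hand_example(self):
        mad, mapd = mad_mapd(100.0, [98.0, 104.0])
        assert mad == pytest.approx(3.0)
        assert mapd == pytest.approx(3.0)

    def test_mad_mapd_exact_and_single(self):
        assert mad_mapd(150.0, [150.0, 150.0]) == (0.0, 0.0)
        mad, mapd = mad_mapd(200.0, [205.0])
        assert (mad, mapd) == (5.0, pytest.approx(2.5))

    def test_mad_requires_estimates_and_positive_reference(self):
        with pytest.raises(EvaluationError):
            mad_mapd(100.0, [])
        with pytest.raises(EvaluationError):
            mad_mapd(0.0, [1.0])

    def test_tem_worked_example_sqrt5(self):
        assert tem([[100.0, 102.0], [200.0, 196.0]]) == pytest.approx(math.sqrt(5.0), abs=1e-12)

    def test_tem_identical_repeats_zero(self):
        assert tem([[5.0, 5.0, 5.0], [9.0, 9.0, 9.0]]) == 0.0

    def test_tem_matches_brute_force_variance_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(500):
            m, n = rng.integers(2, 8), rng.integers(2, 5)
            groups = rng.normal(150.0, 30.0, (m, n))
            expected = math.sqrt(np.mean([np.var(g, ddof=1) for g in groups]))
            assert tem(list(groups)) == pytest.approx(expected, abs=1e-10)

    def test_tem_rejects_unequal_or_single_repeats(self):
        with pytest.raises(EvaluationError):
            tem([[1.0, 2.0], [1.0, 2.0, 3.0]])
        with pytest.raises(EvaluationError):
            tem([[1.0], [2.0]])

    def test_reliability_limits_and_worked_example(self):
        pooled = [100.0, 102.0, 200.0, 196.0]
        s2 = np.var(pooled, ddof=1)
        assert reliability(0.0, pooled) == 1.0
        assert reliability(math.sqrt(s2), pooled) == 0.0
        r = reliability(math.sqrt(5.0), pooled)
        assert r == pytest.approx(1.0 - 5.0 / s2, abs=1e-12)
        assert r == pytest.approx(0.998, abs=5e-4)

    def test_reliability_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            reliability(1.0, [5.0, 5.0, 5.0])

    def test_adequacy_band(self):
        assert adequacy(2.24, 2.24)
        assert not adequacy(10.0, 2.24)  # |7.76| > 2.8 * 2.24 = 6.272
        assert adequacy(0.0, 1.0)

    def test_acceptable_r_strict_threshold(self):
        assert acceptable_r(0.96)
        assert not acceptable_r(0.95)
        assert acceptable_r(1.0)


class TestSweep:
    @pytest.fixture()
    def manual(self, default_bundle):
        return default_bundle.manual

    def test_row_structure(self, default_records, manual):
        height = sweep_view_combinations(default_records, manual, "height_ld", "calibration")
        assert len(height[height.method == "linear_distance"]) == 5
        assert len(height[height.method == "linear_distance_regression"]) == 31
        muac = sweep_view_combinations(default_records, manual, "muac", "reference")
        assert len(muac[muac.method == "shape_circle"]) == 5
        assert len(muac[muac.method == "shape_ellipse"]) == 10
        assert len(muac[muac.method == "shape_ellipse_rectangle"]) == 10
        assert len(muac[muac.method == "radius_regression"]) == 31
        bb = sweep_view_combinations(default_records, manual, "height_bb", "calibration")
        assert len(bb) == 31

    def test_one_optimal_row_per_method(self, default_records, manual):
        table = sweep_view_combinations(default_records, manual, "muac", "calibration")
        for _, block in table.groupby("method"):
            assert block.optimal.sum() == 1
            best = block[block.optimal].iloc[0]
            assert best.mad_mean_mm == block.mad_mean_mm.min()

    def test_metrics_are_nonnegative_and_r_clamped(self, default_records, manual):
        table = sweep_view_combinations(default_records, manual, "height_ld", "reference")
        assert (table.mad_mean_mm >= 0).all()
        assert (table.tem_mm >= 0).all()
        assert table.r.between(0.0, 1.0).all()

    def test_deterministic_given_fixed_inputs(self, default_records, manual):
        t1 = sweep_view_combinations(default_records, manual, "height_bb", "reference")
        t2 = sweep_view_combinations(default_records, manual, "height_bb", "reference")
        assert t1.to_csv(index=False) == t2.to_csv(index=False)


def test_manual_measurements_means_and_tem():
    manual = ManualMeasurements(
        height={"a": [100.0, 102.0, 101.0]},
        muac={("a", "left"): [250.0, 252.0], ("a", "right"): [260.0, 258.0]},
    )
    assert manual.means("height")["a"] == pytest.approx(101.0)
    assert manual.tem("muac") == pytest.approx(math.sqrt(2.0))
    with pytest.raises(EvaluationError):
        ManualMeasurements().means("height")
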