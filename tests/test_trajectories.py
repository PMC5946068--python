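"""Softmax age-trajectory model, peak alignment and odds-ratio tests."""

import itertools

import numpy as np
import pytest

from dogyears.simulate import simulate_causes
from dogyears.trajectories import (
    AgeScale,
    MultinomialAgeModel,
    compute_age_scale,
    confidence_band,
    find_peak_age,
    fit_cause_trajectory,
    log2_odds_ratio,
    odds_ratio_curve,
    predict_proportions,
)


def constant_model(labels, scores):
    """Age-independent softmax model with the given per-cause scores."""
    K = len(labels)
    coef = np.zeros((K, 5))
    coef[:, 0] = scores
    return MultinomialAgeModel(labels=tuple(labels), coef=coef,
                               age_center=50.0, age_scale=20.0)


def quadratic_two_cause_model(vertex, curvature=0.01, height=1.0,
                              center=50.0, scale=20.0):
    """Cause 'a' has a concave-quadratic raw-age logit peaking at ``vertex``;
    cause 'b' (reference) is flat, so the proportion peak is exactly the
    vertex."""
    raw = np.array([
        [height - curvature * vertex**2, 2 * curvature * vertex, -curvature, 0, 0],
        [0, 0, 0, 0, 0],
    ])
    return MultinomialAgeModel.from_raw_polynomials(
        ["a", "b"], raw, age_center=center, age_scale=scale)


class TestPredictProportions:
    def test_zero_parameters_give_uniform(self):
        m = constant_model(["a", "b", "c", "d"], [0, 0, 0, 0])
        np.testing.assert_allclose(predict_proportions(m, 30.0), 0.25)

    def test_softmax_of_zero_one(self):
        m = constant_model(["a", "b"], [0.0, 1.0])
        p = predict_proportions(m, 10.0)
        np.testing.assert_allclose(p, [0.26894142137, 0.73105857863], atol=1e-10)

    def test_shift_invariance(self):
        m1 = constant_model(["a", "b", "c"], [0.0, 1.0, -0.5])
        m2 = constant_model(["a", "b", "c"], [3.0, 4.0, 2.5])
        np.testing.assert_allclose(
            predict_proportions(m1, 5.0), predict_proportions(m2, 5.0), atol=1e-12)

    def test_sums_to_one_for_random_models_and_ages(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            K = rng.integers(2, 6)
            m = MultinomialAgeModel(
                labels=tuple(f"c{i}" for i in range(K)),
                coef=rng.normal(0, 1, (K, 5)),
                age_center=rng.uniform(5, 60),
                age_scale=rng.uniform(1, 30),
            )
            ages = rng.uniform(0, 100, 50)
            P = predict_proportions(m, ages)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0)


class TestSimplexInvariantsHypothesis:
    from hypothesis import given, settings, strategies as st

    @given(
        scores=st.lists(st.floats(-30, 30), min_size=2, max_size=6),
        age=st.floats(0, 120),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_constant_model_predictions_form_a_simplex(self, scores, age):
        m = constant_model([f"c{i}" for i in range(len(scores))], scores)
        p = predict_proportions(m, float(age))
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @given(ph=st.floats(1e-4, 1 - 1e-4), pd_=st.floats(1e-4, 1 - 1e-4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_odds_ratio_sign_tracks_which_cohort_is_likelier(self, ph, pd_):
        human = constant_model(["a", "b"], [np.log(ph / (1 - ph)), 0.0])
        dog = constant_model(["a", "b"], [np.log(pd_ / (1 - pd_)), 0.0])
        val = log2_odds_ratio(human, dog, AgeScale(1.0, 1.0), "a", 10.0)
        assert val == pytest.approx(
            np.log2(ph / (1 - ph)) - np.log2(pd_ / (1 - pd_)), abs=1e-7)


class TestFitCauseTrajectory:
    def test_age_independent_causes_give_flat_half_half(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(0, 20, 10000)
        causes = np.where(rng.random(10000) < 0.5, "a", "b")
        m = fit_cause_trajectory(ages, causes)
        P = predict_proportions(m, np.linspace(1, 19, 10))
        assert np.all(np.abs(P[:, 0] - 0.5) < 0.03)
        assert np.max(np.abs(m.coef[1, 1:])) < 0.2

    def test_beats_coarse_grid_oracle_on_toy_data(self):
        # 12 deaths, 3 causes, degree-1 model: brute-force the coefficients
        ages = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12])
        causes = np.array(list("aabbabbcbccc"), dtype=object)
        m = fit_cause_trajectory(ages, causes, degree=1, _warn_small=0)
        z = (ages - ages.mean()) / ages.std()
        X = np.column_stack([np.ones(12), z])
        y = np.array([{"a": 0, "b": 1, "c": 2}[c] for c in causes])
        best = -np.inf
        grid = np.linspace(-3, 3, 13)
        for b10, b11, b20, b21 in itertools.product(grid, repeat=4):
            eta = np.zeros((12, 3))
            eta[:, 1] = X @ [b10, b11]
            eta[:, 2] = X @ [b20, b21]
            ll = (eta[np.arange(12), y]
                  - np.log(np.exp(eta).sum(axis=1))).sum()
            best = max(best, ll)
        assert m.log_likelihood >= best - 1e-9

    def test_simulation_recovery_of_probability_curves(self):
        truth = quadratic_two_cause_model(vertex=40.0, curvature=0.002,
                                          height=0.5)
        rng = np.random.default_rng(2)
        ages = rng.uniform(0, 90, 40000)
        causes = simulate_causes(truth, ages, rng)
        m = fit_cause_trajectory(ages, causes)
        grid = np.linspace(5, 85, 50)
        p_true = predict_proportions(truth, grid)[:, 0]
        p_hat = predict_proportions(m, grid)[:, m.index("a")]
        assert np.max(np.abs(p_hat - p_true)) < 0.015

    def test_multi_start_reaches_the_same_optimum(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(0, 20, 2000)
        causes = np.where(rng.random(2000) < 0.3 + 0.02 * ages, "a", "b")
        base = fit_cause_trajectory(ages, causes)
        for s in range(10):
            start = np.random.default_rng(s).normal(0, 0.5, 5)
            alt = fit_cause_trajectory(ages, causes, start=start)
            assert abs(alt.log_likelihood - base.log_likelihood) < 1e-6

    def test_single_cause_is_an_error(self):
        with pytest.raises(ValueError):
            fit_cause_trajectory(np.arange(100.0), np.repeat("a", 100))

    def test_reference_row_is_zero_and_labels_sorted(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(0, 20, 500)
        causes = rng.choice(["zeta", "alpha", "mid"], 500)
        m = fit_cause_trajectory(ages, causes)
        assert m.labels == ("alpha", "mid", "zeta")
        np.testing.assert_array_equal(m.coef[0], 0.0)


class TestConfidenceBand:
    @staticmethod
    def _data(n, seed):
        truth = quadratic_two_cause_model(vertex=10.0, curvature=0.02,
                                          height=0.3, center=10.0, scale=5.0)
        rng = np.random.default_rng(seed)
        ages = rng.uniform(0, 20, n)
        return ages, simulate_causes(truth, ages, rng)

    def test_bands_contain_point_estimate_and_shrink_with_n(self):
        grid = np.array([5.0, 10.0, 15.0])
        widths = {}
        for n in (800, 8000):
            ages, causes = self._data(n, seed=5)
            m = fit_cause_trajectory(ages, causes, degree=2)
            lo, hi = confidence_band(m, ages, causes, "a", grid, B=60, seed=11)
            p = predict_proportions(m, grid)[:, m.index("a")]
            assert np.all((lo <= p + 1e-9) & (p <= hi + 1e-9))
            widths[n] = np.mean(hi - lo)
        assert widths[8000] < widths[800]

    def test_bands_depend_on_replicates(self):
        ages, causes = self._data(600, seed=6)
        m = fit_cause_trajectory(ages, causes, degree=2)
        grid = np.array([10.0])
        b50 = confidence_band(m, ages, causes, "a", grid, B=50, seed=7)
        b51 = confidence_band(m, ages, causes, "a", grid, B=51, seed=7)
        assert b50 != b51

    def test_too_few_replicates_rejected(self):
        ages, causes = self._data(200, seed=8)
        m = fit_cause_trajectory(ages, causes, degree=2)
        with pytest.raises(ValueError):
            confidence_band(m, ages, causes, "a", np.array([5.0]), B=10)


class TestFindPeakAge:
    def test_constructed_parabola_vertex(self):
        m = quadratic_two_cause_model(vertex=40.0)
        pk = find_peak_age(m, "a", (0.0, 90.0))
        assert pk.age == pytest.approx(40.0, abs=0.1)
        assert not pk.at_boundary

    def test_monotone_trajectory_flags_boundary(self):
        raw = np.array([[0.0, 0.05, 0, 0, 0], [0, 0, 0, 0, 0]])
        m = MultinomialAgeModel.from_raw_polynomials(["a", "b"], raw, 45.0, 20.0)
        pk = find_peak_age(m, "a", (0.0, 90.0))
        assert pk.age == pytest.approx(90.0, abs=1e-3)
        assert pk.at_boundary

    def test_agrees_with_fine_grid_scan(self):
        m = quadratic_two_cause_model(vertex=37.3, curvature=0.004)
        pk = find_peak_age(m, "a", (0.0, 90.0))
        fine = np.arange(0.0, 90.0, 0.01)
        vals = predict_proportions(m, fine)[:, 0]
        assert abs(pk.age - fine[np.argmax(vals)]) <= 0.01

    def test_flat_curve_flagged(self):
        m = constant_model(["a", "b"], [0.3, -0.3])
        pk = find_peak_age(m, "a", (0.0, 90.0))
        assert pk.flat


class TestAgeScale:
    def test_reported_peaks_give_the_printed_factor(self):
        human = quadratic_two_cause_model(vertex=53.0, curvature=0.0012,
                                          height=1.2)
        dog = quadratic_two_cause_model(vertex=11.5, curvature=0.025,
                                        height=1.2, center=10.0, scale=5.0)
        human = MultinomialAgeModel(labels=("neoplastic", "other"),
                                    coef=human.coef, age_center=50.0,
                                    age_scale=20.0)
        dog = MultinomialAgeModel(labels=("neoplastic", "other"),
                                  coef=dog.coef, age_center=10.0, age_scale=5.0)
        s = compute_age_scale(human, dog, human_age_range=(0, 100),
                              dog_age_range=(0, 20))
        assert s.scale_factor == pytest.approx(53.0 / 11.5, rel=1e-3)
        assert s.scale_factor == pytest.approx(4.6087, abs=0.01)

    def test_identical_models_give_unit_factor(self):
        m = quadratic_two_cause_model(vertex=12.0, curvature=0.02,
                                      center=10.0, scale=5.0)
        m = MultinomialAgeModel(labels=("neoplastic", "other"), coef=m.coef,
                                age_center=10.0, age_scale=5.0)
        s = compute_age_scale(m, m, human_age_range=(0, 25),
                              dog_age_range=(0, 25))
        assert s.scale_factor == pytest.approx(1.0, abs=1e-6)

    def test_age_compression_equivariance(self):
        # dog model = human model with age pre-divided by 4 => factor 4
        human = quadratic_two_cause_model(vertex=48.0, curvature=0.002)
        dog = quadratic_two_cause_model(vertex=12.0, curvature=0.002 * 16,
                                        center=12.5, scale=5.0)
        human = MultinomialAgeModel(labels=("neoplastic", "other"),
                                    coef=human.coef, age_center=50.0,
                                    age_scale=20.0)
        dog = MultinomialAgeModel(labels=("neoplastic", "other"), coef=dog.coef,
                                  age_center=12.5, age_scale=5.0)
        s = compute_age_scale(human, dog, human_age_range=(0, 100),
                              dog_age_range=(0, 25))
        assert s.scale_factor == pytest.approx(4.0, rel=1e-3)

    def test_boundary_peak_is_an_error(self):
        raw = np.array([[0.0, 0.05, 0, 0, 0], [0, 0, 0, 0, 0]])
        mono = MultinomialAgeModel.from_raw_polynomials(
            ["neoplastic", "other"], raw, 45.0, 20.0)
        ok = quadratic_two_cause_model(vertex=12.0, center=10.0, scale=5.0)
        ok = MultinomialAgeModel(labels=("neoplastic", "other"), coef=ok.coef,
                                 age_center=10.0, age_scale=5.0)
        with pytest.raises(ValueError):
            compute_age_scale(mono, ok, human_age_range=(0, 90),
                              dog_age_range=(0, 20))


class TestLog2OddsRatio:
    def test_printed_formula_arithmetic(self):
        # p_human = 0.8, p_dog = 0.2 -> log2(4) - log2(1/4) = 4
        human = constant_model(["a", "b"], [np.log(4.0), 0.0])   # p_a = 0.8
        dog = constant_model(["a", "b"], [np.log(0.25), 0.0])    # p_a = 0.2
        val = log2_odds_ratio(human, dog, AgeScale(1.0, 1.0), "a", 30.0)
        assert val == pytest.approx(4.0, abs=1e-9)

    def test_identical_models_give_zero_everywhere(self):
        m = quadratic_two_cause_model(vertex=40.0)
        for age in (0.0, 17.0, 53.0, 88.0):
            assert log2_odds_ratio(m, m, AgeScale(1.0, 1.0), "a", age) == (
                pytest.approx(0.0, abs=1e-9))

    def test_two_to_the_result_equals_the_odds_ratio(self):
        human = quadratic_two_cause_model(vertex=50.0, curvature=0.001)
        dog = quadratic_two_cause_model(vertex=12.0, curvature=0.016,
                                        center=10.0, scale=5.0)
        scale = AgeScale(50.0, 12.0)
        for age in (10.0, 40.0, 70.0):
            ph = predict_proportions(human, age)[0]
            pdg = predict_proportions(dog, scale.to_dog_age(age))[0]
            direct = (ph / (1 - ph)) / (pdg / (1 - pdg))
            got = log2_odds_ratio(human, dog, scale, "a", age)
            assert 2.0**got == pytest.approx(direct, rel=1e-9)

    def test_antisymmetry_under_cohort_swap(self):
        a = quadratic_two_cause_model(vertex=50.0, curvature=0.001)
        b = quadratic_two_cause_model(vertex=12.0, curvature=0.016,
                                      center=10.0, scale=5.0)
        s_ab = AgeScale(50.0, 12.0)
        s_ba = AgeScale(12.0, 50.0)
        for age_a in (20.0, 45.0, 80.0):
            fwd = log2_odds_ratio(a, b, s_ab, "a", age_a)
            rev = log2_odds_ratio(b, a, s_ba, "a", s_ab.to_dog_age(age_a))
            assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_clipping_keeps_values_finite_and_flagged(self):
        human = constant_model(["a", "b"], [40.0, 0.0])  # p_a ~ 1
        dog = constant_model(["a", "b"], [-40.0, 0.0])   # p_a ~ 0
        curve = odds_ratio_curve(human, dog, AgeScale(1.0, 1.0), "a",
                                 np.array([10.0]))
        assert np.isfinite(curve.log2_or).all()
        assert curve.clipped.all()
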