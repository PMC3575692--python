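"""Unit and property tests for the five performance measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markergain.metrics import (
    MetricSet,
    PredictionSet,
    brier_scaled,
    brier_score,
    c_statistic,
    compare_nested_models,
    discrimination_slope,
    idi,
    metric_set,
    nagelkerke_r2,
)
from markergain.metrics import DegenerateOutcomesError


def brute_force_c(probs, outcomes):
    """All-pairs enumeration oracle: concordant + 0.5 * ties over all
    event/non-event pairs."""
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes)
    ev = probs[outcomes == 1]
    ne = probs[outcomes == 0]
    total = 0.0
    for pe in ev:
        for pn in ne:
            if pe > pn:
                total += 1.0
            elif pe == pn:
                total += 0.5
    return total / (len(ev) * len(ne))


def random_prediction_set(rng, n=None):
    n = n or int(rng.integers(4, 201))
    probs = rng.random(n)
    # occasional heavy ties to exercise the midrank path
    if rng.random() < 0.3:
        probs = np.round(probs, 1)
    outcomes = rng.integers(0, 2, size=n)
    if outcomes.sum() in (0, n):  # force both classes
        outcomes[0], outcomes[1] = 0, 1
    return probs, outcomes


class TestCStatistic:
    @pytest.mark.parametrize(
        "probs, outcomes, expected",
        [
            ([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0], 0.75),
            ([0.4, 0.4, 0.4, 0.4], [1, 0, 0, 1], 0.5),  # all pairs tied
            ([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], 1.0),  # perfect separation
            ([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.0),  # perfect reversal
        ],
    )
    def test_known_values(self, probs, outcomes, expected):
        assert c_statistic(probs, outcomes) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            probs, outcomes = random_prediction_set(rng)
            assert c_statistic(probs, outcomes) == pytest.approx(
                brute_force_c(probs, outcomes), abs=1e-12
            )

    @pytest.mark.parametrize("transform", [np.sqrt, lambda p: p**3, lambda p: p / (2 - p)])
    def test_invariant_under_strictly_increasing_transform(self, rng, transform):
        for _ in range(20):
            probs, outcomes = random_prediction_set(rng)
            assert c_statistic(transform(probs), outcomes) == pytest.approx(
                c_statistic(probs, outcomes), abs=1e-12
            )

    def test_degenerate_outcomes_raise(self):
        with pytest.raises(DegenerateOutcomesError, match="no events"):
            c_statistic([0.1, 0.2], [0, 0])
        with pytest.raises(DegenerateOutcomesError, match="no non-events"):
            c_statistic([0.1, 0.2], [1, 1])


class TestBrier:
    @pytest.mark.parametrize(
        "probs, outcomes, expected",
        [
            ([0.8, 0.2], [1, 0], 0.04),
            ([1.0, 0.0, 1.0], [1, 0, 1], 0.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 1], 0.25),
        ],
    )
    def test_known_values(self, probs, outcomes, expected):
        assert brier_score(probs, outcomes) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_evaluation(self, rng):
        for _ in range(100):
            probs, outcomes = random_prediction_set(rng)
            direct = sum((p - y) ** 2 for p, y in zip(probs, outcomes)) / len(probs)
            assert brier_score(probs, outcomes) == pytest.approx(direct, abs=1e-12)


class TestBrierScaled:
    def test_worked_example(self):
        # mean(p) = 0.5 -> brier_max = 0.25; 1 - 0.04/0.25 = 0.84
        assert brier_scaled([0.8, 0.2], [1, 0]) == pytest.approx(0.84, abs=1e-12)

    def test_null_forecast_scores_zero(self):
        # constant predictions at the event rate: brier == brier_max
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0])
        probs = np.full(8, y.mean())
        assert brier_scaled(probs, y) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction_scores_one(self):
        y = np.array([1, 0, 1])
        assert brier_scaled(y.astype(float), y) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_mean_probability_raises(self):
        with pytest.raises(ZeroDivisionError):
            brier_scaled([0.0, 0.0], [0, 0])


class TestNagelkerkeR2:
    def test_zero_when_model_equals_null(self):
        ll0 = 100 * math.log(0.5)
        assert nagelkerke_r2(ll0, ll0, 100) == 0.0

    def test_one_for_saturated_fit(self):
        ll0 = 10 * (0.3 * math.log(0.3) + 0.7 * math.log(0.7))
        assert nagelkerke_r2(0.0, ll0, 10) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_against_arbitrary_precision(self):
        # independent high-precision evaluation of the rescaled Cox–Snell form
        import sympy

        llm, ll0, n = sympy.Rational(-3, 2), 4 * sympy.log(sympy.Rational(1, 2)), 4
        lr = 2 * (llm - ll0)
        expected = (1 - sympy.exp(-lr / n)) / (1 - sympy.exp(2 * ll0 / n))
        assert nagelkerke_r2(-1.5, float(4 * math.log(0.5)), 4) == pytest.approx(
            float(expected.evalf(30)), rel=1e-12
        )

    def test_likelihood_decrease_raises(self):
        with pytest.raises(ValueError, match="failed fit"):
            nagelkerke_r2(-10.0, -5.0, 20)

    def test_zero_null_loglik_raises(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(0.0, 0.0, 10)


class TestDiscriminationSlopeAndIDI:
    def test_worked_example(self):
        assert discrimination_slope([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(
            0.1, abs=1e-12
        )

    def test_constant_probs_zero_and_perfect_one(self):
        assert discrimination_slope([0.4, 0.4, 0.4], [1, 0, 1]) == 0.0
        assert discrimination_slope([1.0, 0.0, 1.0], [1, 0, 1]) == 1.0

    def test_idi_is_slope_difference(self, rng):
        for _ in range(50):
            probs_new, outcomes = random_prediction_set(rng)
            probs_old = rng.random(len(probs_new))
            expected = discrimination_slope(probs_new, outcomes) - discrimination_slope(
                probs_old, outcomes
            )
            assert idi(probs_new, probs_old, outcomes) == pytest.approx(expected, abs=1e-12)

    def test_idi_antisymmetry(self, rng):
        for _ in range(50):
            probs_new, outcomes = random_prediction_set(rng)
            probs_old = rng.random(len(probs_new))
            assert idi(probs_new, probs_old, outcomes) == pytest.approx(
                -idi(probs_old, probs_new, outcomes), abs=1e-12
            )

    def test_idi_zero_for_equal_subgroup_means_from_different_probs(self):
        # two prediction sets with identical event and non-event means
        outcomes = [1, 1, 0, 0]
        new = [0.7, 0.5, 0.3, 0.1]  # means 0.6 / 0.2
        old = [0.8, 0.4, 0.4, 0.0]  # means 0.6 / 0.2
        assert idi(new, old, outcomes) == pytest.approx(0.0, abs=1e-12)

    def test_idi_requires_shared_outcomes(self):
        new = PredictionSet([0.9, 0.1], [1, 0])
        old = PredictionSet([0.9, 0.1], [0, 1])
        with pytest.raises(ValueError, match="identical outcomes"):
            idi(new, old)


class TestPredictionSetValidation:
    @pytest.mark.parametrize(
        "probs, outcomes",
        [
            ([0.5], [1]),  # too short
            ([0.5, 1.5], [1, 0]),  # prob out of range
            ([0.5, 0.5], [1, 2]),  # non-binary outcome
            ([0.5, 0.5, 0.5], [1, 0]),  # length mismatch
        ],
    )
    def test_invalid_inputs_raise(self, probs, outcomes):
        with pytest.raises(ValueError):
            PredictionSet(probs, outcomes)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=40), st.data())
def test_c_statistic_hypothesis_vs_brute_force(probs, data):
    outcomes = data.draw(
        st.lists(st.integers(0, 1), min_size=len(probs), max_size=len(probs))
    )
    outcomes = np.array(outcomes)
    if outcomes.sum() in (0, len(outcomes)):
        outcomes[0], outcomes[-1] = 0, 1
    probs = np.array(probs)
    assert c_statistic(probs, outcomes) == pytest.approx(
        brute_force_c(probs, outcomes), abs=1e-12
    )


class TestMetricSetAndComparison:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0])
        ms = metric_set(
            y.astype(float), loglik_model=0.0, loglik_null=4 * math.log(0.5), outcomes=y
        )
        assert ms == MetricSet(1.0, 0.0, 1.0, pytest.approx(1.0), 1.0)

    def test_null_model_predictions(self):
        y = np.array([1, 0, 0, 0])
        ll0 = 4 * (0.25 * math.log(0.25) + 0.75 * math.log(0.75))
        ms = metric_set(np.full(4, 0.25), loglik_model=ll0, loglik_null=ll0, outcomes=y)
        assert ms.c_statistic == 0.5
        assert ms.discrimination_slope == 0.0
        assert ms.brier_scaled == pytest.approx(0.0, abs=1e-12)
        assert ms.r2_nagelkerke == 0.0

    def test_compare_identical_fits_gives_zero_deltas(self):
        from markergain.engine import FittedLogit

        y = np.array([1, 0, 1, 0, 0])
        probs = np.array([0.7, 0.3, 0.6, 0.4, 0.2])
        ll = float(np.sum(y * np.log(probs) + (1 - y) * np.log(1 - probs)))
        fit = FittedLogit(np.array([0.0]), probs, ll, True, 1)
        cmp = compare_nested_models(fit, fit, y)
        for m in ("c_statistic", "brier", "brier_scaled", "r2_nagelkerke", "discrimination_slope"):
            assert getattr(cmp.delta, m) == 0.0
        assert cmp.idi == 0.0
        assert cmp.idi == cmp.delta.discrimination_slope
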