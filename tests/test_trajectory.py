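import math
from collections import Counter

import numpy as np
import pytest

from venomshift import (
    aicc,
    classify_mode,
    classify_series,
    fit_linear,
    fit_sigmoid,
    tempo,
)
from venomshift.errors import InsufficientDataError, ParameterError
from venomshift.trajectory import TrajectoryFit, fit_constant


def logistic(t, a, t0, s):
    return a / (1 + np.exp((t0 - t) / s))


class TestLinearFit:
    def test_noiseless_line(self):
        t = np.arange(10.0)
        fit = fit_linear(t, 2 * t + 1)
        assert fit.params["slope"] == pytest.approx(2.0, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        fit = fit_linear(np.arange(5.0), np.full(5, 3.3))
        assert fit.params["slope"] == 0.0
        assert fit.r_squared == 0.0
        assert fit.p_value == 1.0

    def test_against_normal_equations(self):
        t = np.array([0.0, 1.0, 3.0, 4.0, 7.0])
        d = np.array([0.2, 0.8, 1.1, 2.3, 3.1])
        # closed-form OLS
        tm, dm = t.mean(), d.mean()
        slope = ((t - tm) * (d - dm)).sum() / ((t - tm) ** 2).sum()
        intercept = dm - slope * tm
        rss = ((d - intercept - slope * t) ** 2).sum()
        fit = fit_linear(t, d)
        assert fit.params["slope"] == pytest.approx(slope, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(intercept, abs=1e-12)
        assert fit.rss == pytest.approx(rss, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_linear(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestSigmoidFit:
    def test_noiseless_parameter_recovery(self):
        t = np.linspace(0, 1200, 15)
        d = logistic(t, a=1.0, t0=400.0, s=80.0)
        fit = fit_sigmoid(t, d)
        assert fit.params["asymptote"] == pytest.approx(1.0, rel=1e-4)
        assert fit.params["inflection"] == pytest.approx(400.0, rel=1e-4)
        assert fit.params["scale"] == pytest.approx(80.0, rel=1e-4)

    def test_linear_data_prefers_linear_by_aicc(self):
        rng = np.random.default_rng(17)
        t = np.linspace(0, 1000, 20)
        d = 0.002 * t + rng.normal(0, 0.05, 20)
        lin = fit_linear(t, d)
        sig = fit_sigmoid(t, d)
        assert sig.aicc > lin.aicc

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_sigmoid(np.arange(4.0), np.arange(4.0))

    def test_free_baseline_variant(self):
        t = np.linspace(0, 1200, 15)
        d = 0.3 + logistic(t, 1.0, 500.0, 60.0)
        fit = fit_sigmoid(t, d, free_baseline=True)
        assert fit.params["baseline"] == pytest.approx(0.3, rel=1e-3)
        assert fit.params["scale"] == pytest.approx(60.0, rel=1e-3)


class TestAicc:
    def test_hand_arithmetic(self):
        # 10 ln(0.1) + 6 + 4
        assert aicc(1.0, 10, 3) == pytest.approx(10 * math.log(0.1) + 10, abs=1e-9)

    def test_monotone_in_rss(self):
        assert aicc(2.0, 12, 3) > aicc(1.0, 12, 3)

    def test_small_sample_error(self):
        with pytest.raises(InsufficientDataError):
            aicc(1.0, 5, 4)

    def test_constant_beats_nothing_when_slope_real(self):
        # with a genuine slope and large n, the linear model wins on AICc
        rng = np.random.default_rng(3)
        t = np.linspace(0, 1000, 200)
        d = 0.001 * t + rng.normal(0, 0.05, 200)
        assert fit_linear(t, d).aicc < fit_constant(t, d).aicc


class TestTempo:
    @pytest.mark.parametrize("s, expected", [(50.0, 180.0), (100.0, 360.0)])
    def test_max_rate_formula(self, s, expected):
        fit = TrajectoryFit(
            "sigmoid", {"asymptote": 1.0, "inflection": 0.0, "scale": s},
            rss=0.1, n=10, k=4, aicc=0.0, r_squared=0.9, p_value=0.01,
        )
        assert tempo(fit) == pytest.approx(expected)

    def test_discrete_boundary_scale(self):
        # tempo < 244 iff s < 244/3.6
        boundary = 244 / 3.6
        below = TrajectoryFit(
            "sigmoid", {"asymptote": 1.0, "inflection": 0.0, "scale": boundary - 1e-6},
            rss=0.1, n=10, k=4, aicc=0.0, r_squared=0.9, p_value=0.01,
        )
        above = TrajectoryFit(
            "sigmoid", {"asymptote": 1.0, "inflection": 0.0, "scale": boundary + 1e-6},
            rss=0.1, n=10, k=4, aicc=0.0, r_squared=0.9, p_value=0.01,
        )
        assert tempo(below) < 244 < tempo(above)

    def test_invariant_to_distance_axis_rescaling(self):
        t = np.linspace(0, 1200, 15)
        d = logistic(t, 1.0, 500.0, 70.0)
        t1 = tempo(fit_sigmoid(t, d))
        t2 = tempo(fit_sigmoid(t, 12.5 * d))
        assert t1 == pytest.approx(t2, rel=1e-6)

    def test_requires_sigmoid(self):
        lin = fit_linear(np.arange(5.0), np.arange(5.0) * 2)
        with pytest.raises(TypeError):
            tempo(lin)


def _fit(model, aicc_val, p=0.001, s=60.0, n=15):
    params = (
        {"asymptote": 1.0, "inflection": 500.0, "scale": s}
        if model == "sigmoid"
        else {"slope": 0.001, "intercept": 0.0}
    )
    k = 4 if model == "sigmoid" else 3
    return TrajectoryFit(model, params, rss=0.1, n=n, k=k, aicc=aicc_val,
                         r_squared=0.9, p_value=p)


class TestClassifyMode:
    def test_sigmoid_decisively_better_discrete(self):
        cls = classify_mode(_fit("linear", 10.0), _fit("sigmoid", 5.0, s=60.0), 1200)
        assert cls.mode == "sigmoid_discrete"
        assert cls.tempo_days == pytest.approx(216.0)

    def test_sigmoid_decisively_better_gradual(self):
        cls = classify_mode(_fit("linear", 10.0), _fit("sigmoid", 5.0, s=200.0), 1200)
        assert cls.mode == "sigmoid_gradual"
        assert cls.tempo_days == pytest.approx(720.0)

    def test_linear_decisively_better_uses_span(self):
        cls = classify_mode(_fit("linear", 5.0), _fit("sigmoid", 10.0, s=60.0), 677.0)
        assert cls.mode == "linear_gradual"
        assert cls.tempo_days == pytest.approx(677.0)

    def test_linear_narrow_winner_reports_sigmoid_tempo(self):
        # AICc difference below the decisive threshold: linear mode, but
        # the competitive sigmoid supplies the tempo
        cls = classify_mode(_fit("linear", 5.0), _fit("sigmoid", 5.6, s=60.0), 1200)
        assert cls.mode == "linear_gradual"
        assert cls.tempo_days == pytest.approx(216.0)

    def test_sigmoid_failure_falls_back_to_span(self):
        cls = classify_mode(_fit("linear", 5.0), None, 900.0)
        assert cls.mode == "linear_gradual"
        assert cls.tempo_days == pytest.approx(900.0)
        assert math.isnan(cls.delta_aicc)

    def test_insignificant_best_model_is_no_shift(self):
        cls = classify_mode(_fit("linear", 10.0, p=0.6), _fit("sigmoid", 5.0, p=0.7), 1200)
        assert cls.mode == "no_shift"

    def test_mismatched_n_raises(self):
        with pytest.raises(ParameterError):
            classify_mode(_fit("linear", 5.0, n=15), _fit("sigmoid", 4.0, n=14), 1200)


def test_three_class_recovery_on_simulated_series():
    """Directly simulated distance series (n = 15 over 1200 days,
    sigma = 0.05): the generating class is recovered >= 90% per class."""
    t = np.linspace(0, 1200, 15)
    reps = 40
    expected = {
        ("logistic", 40.0): "sigmoid_discrete",
        ("logistic", 150.0): "sigmoid_gradual",
        ("linear", None): "linear_gradual",
    }
    for (kind, s), want in expected.items():
        calls = []
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            if kind == "linear":
                d = 0.5 + t / 1200.0 + rng.normal(0, 0.05, t.size)
            else:
                d = logistic(t, 2.0, 500.0, s) + rng.normal(0, 0.05, t.size)
            _, _, cls = classify_series(t, d)
            calls.append(cls.mode)
        rate = Counter(calls)[want] / reps
        assert rate >= 0.9, f"{kind}/{s}: {Counter(calls)}"
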