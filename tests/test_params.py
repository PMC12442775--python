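"""Rate/effect functions, probability conversion, and config round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oacbenefit import fixtures
from oacbenefit.params import (
    ParameterValidationError,
    annual_to_monthly,
    baseline_bleed_rate,
    baseline_mortality_rate,
    bleed_rr,
    fit_line_least_squares,
    load_parameters,
    mortality_rr,
    save_parameters,
    stroke_rr,
)


class TestAnnualToMonthly:
    @pytest.mark.parametrize("p_annual, expected", [
        (0.0, 0.0),
        (1.0, 1.0),
        (0.06, 1.0 - 0.94 ** (1.0 / 12.0)),  # ~0.005143
    ])
    def test_values(self, p_annual, expected):
        assert annual_to_monthly(p_annual) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0 - 1e-9))
    @settings(max_examples=200, deadline=None)
    def test_inverse_of_twelve_cycle_compounding(self, p):
        m = annual_to_monthly(p)
        assert 1.0 - (1.0 - m) ** 12 == pytest.approx(p, abs=1e-12)

    def test_monotone(self):
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff(annual_to_monthly(grid)) >= 0)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            annual_to_monthly(bad)


class TestRiskDependentFunctions:
    """Every printed anchor must be matched exactly."""

    @pytest.mark.parametrize("fn, risk, expected", [
        (baseline_bleed_rate, 0.01, 0.009),
        (baseline_bleed_rate, 0.06, 0.022),
        (baseline_bleed_rate, 0.03, 0.0142),
        (baseline_mortality_rate, 0.01, 0.037),
        (baseline_mortality_rate, 0.06, 0.120),
        (baseline_mortality_rate, 0.03, 0.0702),
        (stroke_rr, 0.01, 0.68),
        (stroke_rr, 0.06, 0.32),
        (stroke_rr, 0.08, 0.32),  # constant above 6%
        (stroke_rr, 0.004, 1.0 - 0.2768),  # line extended below 1%
        (mortality_rr, 0.004, 1.0),  # no mortality effect below 1%
        (mortality_rr, 0.06, 0.57),
        (mortality_rr, 0.035, 0.785),
        (mortality_rr, 0.08, 0.57),
    ])
    def test_anchors(self, fn, risk, expected):
        assert fn(risk) == pytest.approx(expected, abs=1e-12)

    def test_bleed_rr_constant_product(self):
        assert bleed_rr() == 1.91
        assert bleed_rr(0.05) == 1.91
        assert round(2.22 * 0.86, 2) == 1.91

    def test_monotonicity_and_continuity(self):
        grid = np.linspace(0.0, 0.10, 1001)
        assert np.all(np.diff(baseline_bleed_rate(grid)) >= 0)
        assert np.all(np.diff(baseline_mortality_rate(grid)) >= 0)
        assert np.all(np.diff(stroke_rr(grid)) <= 1e-15)
        assert np.all(np.diff(mortality_rr(grid)) <= 1e-15)
        for fn in (baseline_bleed_rate, baseline_mortality_rate,
                   stroke_rr, mortality_rr):
            vals = fn(grid)
            assert np.max(np.abs(np.diff(vals))) < 1e-2  # no jumps

    def test_range_check(self):
        with pytest.raises(ValueError):
            stroke_rr(0.2)


class TestLeastSquares:
    @pytest.mark.parametrize("points, slope, intercept", [
        ([(1, 0.9), (6, 2.2)], 0.26, 0.64),
        ([(0, 0), (1, 1), (2, 2)], 1.0, 0.0),
        ([(0, 1), (1, 2), (2, 2), (3, 3)], 0.6, 1.1),
    ])
    def test_known_fits(self, points, slope, intercept):
        s, i = fit_line_least_squares(points)
        assert s == pytest.approx(slope, abs=1e-10)
        assert i == pytest.approx(intercept, abs=1e-10)

    @given(st.lists(
        st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
        min_size=2, max_size=12,
    ))
    @settings(max_examples=100, deadline=None)
    def test_matches_normal_equations_oracle(self, points):
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        if np.ptp(x) < 1e-6:
            return
        # brute-force normal equations
        n = len(x)
        sxx = (x * x).sum() - x.sum() ** 2 / n
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        s, i = fit_line_least_squares(points)
        assert s == pytest.approx(slope, abs=1e-8)
        assert i == pytest.approx(intercept, abs=1e-8)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_line_least_squares([(1, 0), (1, 1)])
        with pytest.raises(ValueError):
            fit_line_least_squares([(1, 0)])


class TestParameterSetIO:
    def test_default_round_trip_yaml_and_json(self, params, tmp_path):
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            save_parameters(params, path)
            loaded = load_parameters(path)
            assert loaded == params

    def test_default_values(self, params):
        assert params.bleed_rr() == 1.91
        assert params.post_event_mortality.annual_after_ischemic_stroke == 0.14
        assert params.post_event_mortality.annual_after_intracranial_bleed == 0.16
        assert params.psa.se_log_stroke_rr == 0.16
        assert params.psa.se_log_bleed_rr == 0.30
        assert params.psa.se_log_mortality_rr == 0.13

    def test_randomized_round_trip(self, params, tmp_path):
        rng = np.random.default_rng(0)
        for k in range(5):
            p = fixtures.default_parameters()
            p.bleed_relative_risk = float(rng.uniform(1.0, 3.0))
            p.simulation.seed = int(rng.integers(0, 2**31))
            p.utilities.severity_ratios["moderate"] = float(rng.uniform(0.2, 0.9))
            path = tmp_path / f"r{k}.yaml"
            save_parameters(p.validate(), path)
            assert load_parameters(path) == p

    def test_unknown_key_rejected_by_name(self, params, tmp_path):
        path = tmp_path / "p.yaml"
        save_parameters(params, path)
        text = path.read_text() + "\nbogus_key: 1\n"
        bad = tmp_path / "bad.yaml"
        bad.write_text(text)
        with pytest.raises(ParameterValidationError, match="bogus_key"):
            load_parameters(bad)

    def test_severity_not_summing_rejected(self, params, tmp_path):
        p = fixtures.default_parameters()
        p.severity.by_event["ischemic_stroke"]["untreated"]["mild"] -= 0.1
        with pytest.raises(ParameterValidationError, match="sum to 1"):
            p.validate()

    def test_probability_out_of_range_rejected(self):
        p = fixtures.default_parameters()
        p.post_event_mortality.annual_after_ischemic_stroke = 1.4
        with pytest.raises(ParameterValidationError, match=r"\[0, 1\]"):
            p.validate()

    def test_severity_stochastic_ordering_enforced(self):
        p = fixtures.default_parameters()
        # treated ischemic strokes may not be more often fatal than untreated
        tr = p.severity.by_event["ischemic_stroke"]["treated"]
        tr["fatal"], tr["mild"] = 0.5, tr["mild"] - (0.5 - tr["fatal"])
        with pytest.raises(ParameterValidationError, match="stochastically"):
            p.validate()
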