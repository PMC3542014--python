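"""Unit and property tests of the deterministic model mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from dberm import (
    ConstraintViolation,
    DBERMParams,
    RecoveryCoefficients,
    apply_recovery,
    bout_length_crossing_time,
    bout_stay_probability,
    evaluate_dynamics,
    expected_irt,
    half_life_to_rate,
    irt_log_density,
    irt_log_survival,
    rate_to_half_life,
    validate_constraints,
)
from dberm.core import HALF_LIFE_CAP, LN2

from conftest import random_valid_params


# ---------------------------------------------------------------------------
# dynamics


class TestDynamics:
    def test_time_zero_returns_baselines(self, wky_params):
        s = evaluate_dynamics(wky_params, 0.0)
        assert s.L_t == wky_params.L0
        assert s.w_t == wky_params.w0
        assert s.b_t == wky_params.b0
        assert s.p_t == pytest.approx(wky_params.L0 / (1 + wky_params.L0))

    def test_bout_length_halves_at_its_half_life(self, wky_params):
        # L0 = 2.81 with a 19.37-min half-life halves to 1.405 at t = 19.37
        s = evaluate_dynamics(wky_params, 19.37)
        assert s.L_t == pytest.approx(1.405, abs=5e-4)

    def test_negative_time_rejected(self, wky_params):
        with pytest.raises(ConstraintViolation):
            evaluate_dynamics(wky_params, -0.1)

    def test_invalid_params_rejected(self, wky_params):
        bad = DBERMParams(**{**wky_params.__dict__, "w0": wky_params.b0})
        with pytest.raises(ConstraintViolation):
            evaluate_dynamics(bad, 1.0)

    def test_crossing_time_of_reference_strains(self, shr_params, wky_params):
        # the slowly-decaying short-bout strain overtakes the fast-decaying
        # long-bout strain mid-session
        t = bout_length_crossing_time(shr_params, wky_params)
        assert round(t, 2) == 31.73

    def test_ordering_and_monotonicity_on_grid(self, rng):
        grid = np.linspace(0.0, 120.0, 41)
        for _ in range(50):
            p = random_valid_params(rng)
            states = [evaluate_dynamics(p, t) for t in grid]
            L = np.array([s.L_t for s in states])
            for s in states:
                assert s.w_t >= s.b_t >= p.omega - 1e-12
                assert 0.0 <= s.p_t < 1.0
                assert s.L_t <= p.L0 + 1e-12
            assert np.all(np.diff(L) <= 1e-12)


class TestBoutStayProbability:
    @pytest.mark.parametrize(
        "L, expected",
        [(0.0, 0.0), (1.0, 0.5), (2.81, 2.81 / 3.81)],
    )
    def test_values(self, L, expected):
        assert bout_stay_probability(L) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ConstraintViolation):
            bout_stay_probability(-0.5)


# ---------------------------------------------------------------------------
# the IRT mixture density


class TestIrtDensity:
    def test_zero_below_refractory_period(self, wky_params):
        s = evaluate_dynamics(wky_params, 0.0)
        assert irt_log_density(s, wky_params.delta, wky_params.delta / 2) == -math.inf

    def test_finite_value_on_support(self, wky_params):
        # p = L0/(1+L0) = 0.7375, w = 175.68, b = 14.70, delta = 0.12 s
        s = evaluate_dynamics(wky_params, 0.0)
        tau = 0.5 / 60.0
        ld = irt_log_density(s, wky_params.delta, tau)
        assert math.isfinite(ld)
        # plain-arithmetic cross-check of the mixture formula
        p, w, b, d = s.p_t, s.w_t, s.b_t, wky_params.delta
        direct = p * w * math.exp(-w * (tau - d)) + (1 - p) * b * math.exp(-b * (tau - d))
        assert ld == pytest.approx(math.log(direct), rel=1e-12)

    def test_normalization_over_support(self, rng):
        for _ in range(20):
            p = random_valid_params(rng)
            s = evaluate_dynamics(p, rng.uniform(0, 30))
            total, _ = quad(
                lambda tau: math.exp(irt_log_density(s, p.delta, tau)),
                p.delta, np.inf,
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_survival_matches_integral_of_density(self, rng):
        p = random_valid_params(rng)
        s = evaluate_dynamics(p, 5.0)
        for tau in (p.delta * 2, 0.05, 0.4):
            tail, _ = quad(
                lambda u: math.exp(irt_log_density(s, p.delta, u)), tau, np.inf
            )
            assert math.exp(irt_log_survival(s, p.delta, tau)) == pytest.approx(
                tail, rel=1e-6, abs=1e-9
            )

    def test_unordered_components_rejected(self, wky_params):
        s = evaluate_dynamics(wky_params, 0.0)
        bad = type(s)(t=s.t, L_t=s.L_t, w_t=5.0, b_t=10.0, p_t=s.p_t)
        with pytest.raises(ConstraintViolation):
            irt_log_density(bad, wky_params.delta, 0.1)

    def test_long_tau_underflows_to_finite(self, wky_params):
        s = evaluate_dynamics(wky_params, 0.0)
        ld = irt_log_density(s, wky_params.delta, 500.0)
        assert math.isfinite(ld) and ld < -100


class TestExpectedIrt:
    def test_single_component_limits(self):
        from dberm import DynamicState

        s0 = DynamicState(t=0, L_t=0.0, w_t=60.0, b_t=6.0, p_t=0.0)
        assert expected_irt(s0, 0.01) == pytest.approx(0.01 + 1 / 6.0)
        s1 = DynamicState(t=0, L_t=1e12, w_t=60.0, b_t=6.0, p_t=1.0)
        assert expected_irt(s1, 0.01) == pytest.approx(0.01 + 1 / 60.0)

    def test_mixture_mean(self):
        from dberm import DynamicState

        s = DynamicState(t=0, L_t=1.0, w_t=60.0, b_t=6.0, p_t=0.5)
        assert expected_irt(s, 0.0) == pytest.approx(0.5 / 60 + 0.5 / 6, rel=1e-12)

    def test_zero_rate_rejected(self):
        from dberm import DynamicState

        s = DynamicState(t=0, L_t=1.0, w_t=60.0, b_t=0.0, p_t=0.5)
        with pytest.raises(ConstraintViolation):
            expected_irt(s, 0.0)


# ---------------------------------------------------------------------------
# half-life transforms


class TestHalfLives:
    def test_definition(self):
        h = rate_to_half_life(LN2)
        assert h.minutes == pytest.approx(1.0) and not h.capped

    def test_zero_rate_maps_to_cap(self):
        h = rate_to_half_life(0.0)
        assert h.minutes == HALF_LIFE_CAP and h.capped

    def test_reference_round_trip(self):
        # H_b = 7.77 min <-> beta = ln2/7.77 = 0.08921 min^-1
        beta = half_life_to_rate(7.77)
        assert beta == pytest.approx(0.08921, abs=5e-6)
        assert rate_to_half_life(beta).minutes == pytest.approx(7.77, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=1e-6, max_value=1e5))
    def test_round_trip_identity(self, rate):
        h = rate_to_half_life(rate)
        if not h.capped:
            assert half_life_to_rate(h.minutes) == pytest.approx(rate, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConstraintViolation):
            rate_to_half_life(-1.0)


# ---------------------------------------------------------------------------
# recovery coefficients


class TestRecovery:
    def test_unit_coefficients_are_identity(self, wky_params):
        assert apply_recovery(wky_params, RecoveryCoefficients()) == wky_params

    def test_halved_bout_length(self, wky_params):
        out = apply_recovery(wky_params, RecoveryCoefficients(c_L0=0.5))
        assert out.L0 == pytest.approx(wky_params.L0 / 2, rel=1e-12)

    def test_initiation_rate_scaling(self, shr_params):
        out = apply_recovery(shr_params, RecoveryCoefficients(c_b0=0.73))
        assert out.b0 == pytest.approx(31.20, abs=0.005)

    def test_half_life_coefficient_divides_rate(self, wky_params):
        out = apply_recovery(wky_params, RecoveryCoefficients(c_HL=2.0))
        assert out.gamma == pytest.approx(wky_params.gamma / 2, rel=1e-12)

    def test_composition_is_elementwise_product(self, rng):
        for _ in range(20):
            p = random_valid_params(rng)
            cs = rng.uniform(0.7, 1.4, size=(2, 8))
            try:
                one = apply_recovery(
                    apply_recovery(p, RecoveryCoefficients(*cs[0])),
                    RecoveryCoefficients(*cs[1]),
                )
                both = apply_recovery(p, RecoveryCoefficients(*(cs[0] * cs[1])))
            except ConstraintViolation:
                continue
            for f in ("L0", "w0", "b0", "gamma", "alpha", "beta", "delta", "omega"):
                assert getattr(one, f) == pytest.approx(getattr(both, f), rel=1e-10)

    def test_invalid_result_names_violation(self, wky_params):
        # crushing w0 below b0 must be caught on the output
        with pytest.raises(ConstraintViolation, match="w0 > b0"):
            apply_recovery(wky_params, RecoveryCoefficients(c_w0=0.01))

    def test_nonpositive_coefficient_rejected(self, wky_params):
        with pytest.raises(ConstraintViolation):
            apply_recovery(wky_params, RecoveryCoefficients(c_L0=0.0))


# ---------------------------------------------------------------------------
# constraint reporting


class TestValidateConstraints:
    def test_reference_params_valid(self, wky_params, shr_params):
        assert validate_constraints(wky_params) == []
        assert validate_constraints(shr_params) == []

    def test_equal_rates_violation(self, wky_params):
        bad = DBERMParams(**{**wky_params.__dict__, "w0": wky_params.b0})
        v = validate_constraints(bad)
        assert len(v) == 1 and "w0 > b0" in v[0]

    def test_decay_order_violation(self, wky_params):
        bad = DBERMParams(**{**wky_params.__dict__, "alpha": wky_params.beta + 1})
        v = validate_constraints(bad)
        assert len(v) == 1 and "beta >= alpha" in v[0]

    def test_nonfinite_reported(self, wky_params):
        bad = DBERMParams(**{**wky_params.__dict__, "L0": math.nan})
        assert any("not finite" in s for s in validate_constraints(bad))
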