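"""Dispersion relation: Lambda_n, sigma_n, base flow and regime diagnostics."""
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from activedrop import (
    base_flow,
    lambda2_closed_form,
    lambda_mode,
    lambda_mode_exact,
    paterson_term,
    pressure_condition,
    regime_check,
    sigma,
    sigma_passive,
)
from activedrop.errors import DomainError, RegimeError


class TestLambda:
    def test_vanishes_at_zero_argument(self):
        for n in range(0, 21):
            assert lambda_mode(n, 0.0) == 0.0
            if n > 0:
                assert lambda_mode_exact(n, 0) == 0

    def test_mode_one_is_neutral_everywhere(self):
        for x in np.linspace(0.0, 1.0, 21):
            assert lambda_mode(1, float(x)) == pytest.approx(0.0, abs=1e-14)

    def test_matches_printed_closed_form_for_mode_two(self):
        for x in np.linspace(0.0, 0.99, 199):
            assert lambda_mode(2, float(x)) == pytest.approx(
                lambda2_closed_form(float(x)), rel=1e-10, abs=1e-12
            )

    def test_closed_form_spot_values(self):
        assert lambda2_closed_form(0.0) == 0.0
        assert lambda2_closed_form(4.0 / 3.0) == pytest.approx(0.0, abs=1e-15)
        assert lambda2_closed_form(1.0) == pytest.approx(1.0)
        assert lambda2_closed_form(0.5) == pytest.approx(0.625)
        with pytest.raises(DomainError, match="pole"):
            lambda2_closed_form(1.5)

    def test_turning_circle_value(self):
        # the interior pressure polynomial vanishes at rho = 2 alpha, hence
        # Lambda_n(1) = n - 1 exactly
        for n in (2, 3, 7, 20, 41):
            assert lambda_mode_exact(n, 1) == n - 1

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(n=st.integers(2, 60), x=st.floats(0.0, 1.0))
    def test_float_and_exact_paths_agree(self, n, x):
        exact = float(lambda_mode_exact(n, Fraction(x)))
        assert lambda_mode(n, x) == pytest.approx(exact, rel=1e-9, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(RegimeError):
            lambda_mode(3, 1.2)
        with pytest.raises(RegimeError):
            lambda_mode(3, -0.1)
        with pytest.raises(DomainError):
            lambda_mode(-1, 0.5)
        with pytest.raises(DomainError):
            lambda_mode(2.5, 0.5)


class TestSigma:
    def test_translation_mode_neutral_on_random_grid(self, rng):
        for _ in range(200):
            r0 = float(rng.uniform(0.5, 100.0))
            alpha = float(rng.uniform(0.0, 0.49) * r0)
            phi = float(rng.uniform(0.05, 10.0))
            assert abs(sigma(1, r0, alpha, phi).sigma) < 1e-10

    @pytest.mark.parametrize("n", range(2, 9))
    def test_passive_limit_equals_paterson_plus_growth(self, n, rng):
        for _ in range(20):
            r0 = float(rng.uniform(0.5, 50.0))
            phi = float(rng.uniform(0.1, 5.0))
            full = sigma(n, r0, 0.0, phi).sigma
            passive = sigma_passive(n, r0, phi)
            assert full == pytest.approx(passive, rel=1e-12, abs=1e-14)
            assert passive == pytest.approx(
                paterson_term(n, r0, phi) + 1.0 / (phi + 1.0), rel=1e-14
            )

    def test_activity_destabilizes(self):
        assert sigma(3, 5.0, 2.0, 0.5).sigma > sigma(3, 5.0, 0.0, 0.5).sigma

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 14),
        r0=st.floats(0.5, 60.0),
        phi=st.floats(0.1, 5.0),
        data=st.data(),
    )
    def test_activity_cannot_restabilize(self, n, r0, phi, data):
        # once a mode is unstable, extra activity only raises its growth rate
        # (in the deeply stable corner, small r0 with high n, sigma can dip
        # slightly with alpha; the destabilizing action concerns sigma >= 0)
        alphas = sorted(
            data.draw(st.lists(st.floats(0.0, 0.49 * r0), min_size=2, max_size=5))
        )
        values = [sigma(n, r0, a, phi).sigma for a in alphas]
        for lo, hi in zip(values, values[1:]):
            if lo >= 0.0:
                assert hi >= lo - 1e-10

    @pytest.mark.parametrize("phi", [0.5, 1.0, 2.0])
    def test_sigma_nondecreasing_in_alpha_near_onset(self, phi):
        # across the fingering-relevant radii the rate grows with activity
        for n in range(2, 9):
            for r0 in (5.0, 8.0, 12.0):
                values = [
                    sigma(n, r0, float(a), phi).sigma
                    for a in np.linspace(0.0, 0.49 * r0, 10)
                ]
                for lo, hi in zip(values, values[1:]):
                    assert hi >= lo - 1e-12

    def test_active_terms_vanish_at_large_radius(self):
        # for fixed alpha the activity contribution decays with r0
        for n in (2, 5):
            gap = abs(sigma(n, 1e5, 1.0, 0.5).sigma - sigma_passive(n, 1e5, 0.5))
            assert gap < 1e-3

    def test_passive_large_radius_limit_value(self):
        # n(phi-1)/(2(phi+1)) - 1/2 + 1/(phi+1) = -1/6 at n=2, phi=0.5
        assert sigma_passive(2, 1e6, 0.5) == pytest.approx(-1.0 / 6.0, abs=1e-10)
        assert sigma_passive(2, 1e6, 0.5) < 0

    def test_mode_zero_rejected(self):
        with pytest.raises(DomainError):
            sigma(0, 5.0, 0.0, 1.0)

    def test_high_activity_regime_guard(self):
        with pytest.raises(RegimeError):
            sigma(2, 5.0, 2.5, 1.0)
        flagged = sigma(2, 5.0, 2.5, 1.0, allow_invalid=True)
        assert not flagged.valid and flagged.regime == "high"
        assert math.isfinite(flagged.sigma)  # x = 1 boundary is evaluable
        beyond = sigma(2, 5.0, 4.0, 1.0, allow_invalid=True)
        assert math.isnan(beyond.sigma)


class TestRegimeAndPressure:
    @pytest.mark.parametrize(
        "alpha, r0, expected",
        [(0.0, 1.0, "low"), (2.0, 5.0, "low"), (3.0, 5.0, "high"), (2.5, 5.0, "high")],
    )
    def test_regime_check(self, alpha, r0, expected):
        assert regime_check(alpha, r0) == expected

    @pytest.mark.parametrize(
        "alpha, phi, r0, expected",
        [(0.0, 1.5, 7.0, True), (0.5, 1.0, 5.0, True), (0.0, 0.5, 5.0, False)],
    )
    def test_pressure_condition(self, alpha, phi, r0, expected):
        assert pressure_condition(alpha, phi, r0) is expected


class TestBaseFlow:
    def test_velocity_continuity_at_interface(self):
        r0 = 4.0
        inner = base_flow(r0, r0, 1.0, 2.0)
        outer = base_flow(r0 * (1 + 1e-12), r0, 1.0, 2.0)
        assert inner.v_rho == pytest.approx(r0 / 2.0)
        assert outer.v_rho == pytest.approx(r0 / 2.0, rel=1e-9)
        assert inner.v_theta == outer.v_theta == 0.0

    def test_divergences(self):
        r0, alpha, phi = 5.0, 1.0, 2.0
        h = 1e-6

        def div(rho):
            f = lambda p: p * base_flow(p, r0, alpha, phi).v_rho
            return (f(rho + h) - f(rho - h)) / (2 * h * rho)

        assert div(2.0) == pytest.approx(1.0, abs=1e-6)  # interior: div v = k = 1
        assert div(9.0) == pytest.approx(0.0, abs=1e-6)  # exterior incompressible

    def test_pressure_anchoring_and_gradient(self):
        r0, alpha, phi, p_i = 5.0, 1.0, 2.0, 3.0
        assert base_flow(r0, r0, alpha, phi, p_i).pressure == pytest.approx(p_i)
        # interior Darcy balance: dp/drho = alpha - rho/2
        h = 1e-6
        grad = (
            base_flow(2.0 + h, r0, alpha, phi, p_i).pressure
            - base_flow(2.0 - h, r0, alpha, phi, p_i).pressure
        ) / (2 * h)
        assert grad == pytest.approx(alpha - 1.0, abs=1e-6)
        # exterior: dp/drho = -phi * r0^2/(2 rho); Laplace jump 1/(2 r0)
        jump = p_i - base_flow(r0 * (1 + 1e-14), r0, alpha, phi, p_i).pressure
        assert jump == pytest.approx(1.0 / (2 * r0), rel=1e-6)
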