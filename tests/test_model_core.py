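"""Closed-form model geometry and local stability against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect, fsolve

import crforce as cf
from crforce.model import eigenvalue_checkmark_bottom


def valid_params(draw_r, draw_a, draw_e, draw_b, frac_d, k_factor):
    """Build a valid ModelParams from unconstrained draws (d < a*e, K > R*)."""
    d = frac_d * draw_a * draw_e
    R_star = d * draw_b / (draw_a * draw_e - d)
    return cf.ModelParams(
        r=draw_r, K_mean=R_star * (1.0 + k_factor), a=draw_a, e=draw_e, b=draw_b, d=d
    )


params_strategy = st.builds(
    valid_params,
    draw_r=st.floats(0.5, 30.0),
    draw_a=st.floats(0.1, 5.0),
    draw_e=st.floats(0.05, 1.0),
    draw_b=st.floats(0.1, 5.0),
    frac_d=st.floats(0.05, 0.9),
    k_factor=st.floats(0.05, 20.0),
)


class TestForcing:
    @pytest.mark.parametrize(
        "A, p, t, expected",
        [(0.5, 1.0, 0.0, 0.0), (0.5, 1.0, 0.25, 0.5), (0.0, 3.0, 17.2, 0.0)],
    )
    def test_forcing_value(self, A, p, t, expected):
        assert cf.forcing_value(cf.ForcingSpec(A=A, p=p), t) == pytest.approx(
            expected, abs=1e-12
        )

    def test_carrying_capacity_cycle(self, std):
        m = std.with_K(2.0)
        f = cf.ForcingSpec(A=0.5, p=1.0)
        assert cf.carrying_capacity(m, f, 0.0) == pytest.approx(2.0)
        assert cf.carrying_capacity(m, f, 0.75) == pytest.approx(1.5)

    def test_amplitude_exceeding_mean_rejected(self, std):
        m = std.with_K(1.0)
        with pytest.raises(cf.AmplitudeError):
            cf.carrying_capacity(m, cf.ForcingSpec(A=1.0, p=1.0), 0.3)


class TestVectorField:
    def test_extinction_is_fixed_point(self, std):
        f = cf.ForcingSpec(A=0.5, p=1.0)
        assert cf.vector_field(std, f, cf.State(0.0, 0.0), 3.7) == (0.0, 0.0)

    def test_hand_expanded_values(self):
        # dR = R(r(1-R/K) - aC/(b+R)), dC = C(eaR/(b+R) - d) at the stated point
        m = cf.ModelParams(r=10.0, K_mean=2.0, a=1.3, e=0.7, b=1.0, d=0.2)
        dR, dC = cf.vector_field(m, cf.ForcingSpec.unforced(), cf.State(1.0, 1.0))
        assert dR == pytest.approx(4.35, abs=1e-12)
        assert dC == pytest.approx(0.255, abs=1e-12)

    def test_vanishes_at_interior_equilibrium(self, std):
        eq = cf.interior_equilibrium(std)
        dR, dC = cf.vector_field(
            std, cf.ForcingSpec.unforced(), cf.State(eq.R_star, eq.C_star)
        )
        assert abs(dR) < 1e-12 and abs(dC) < 1e-12

    def test_unforced_field_time_invariant(self, std):
        f = cf.ForcingSpec.unforced()
        s = cf.State(0.9, 2.3)
        assert cf.vector_field(std, f, s, 0.0) == cf.vector_field(std, f, s, 1000.0)


class TestIsoclines:
    def test_resource_isocline_intercepts(self, std):
        K = 2.0
        assert cf.resource_isocline(std, K, K) == pytest.approx(0.0, abs=1e-14)
        # R -> 0 limit is r*b/a
        assert cf.resource_isocline(std, K, 1e-12) == pytest.approx(
            std.r * std.b / std.a, rel=1e-9
        )

    def test_resource_isocline_apex(self, std):
        K = 2.0
        apex = (K - std.b) / 2.0
        R = np.linspace(0.01, K, 2001)
        C = cf.resource_isocline(std, K, R)
        assert R[np.argmax(C)] == pytest.approx(apex, abs=2e-3)

    def test_consumer_isocline_value(self, std):
        # d*b/(a*e - d) = 0.2/0.71, cross-checked by root-finding dC/dt = 0
        assert cf.consumer_isocline_R(std) == pytest.approx(0.2 / 0.71, rel=1e-12)
        f0 = cf.ForcingSpec.unforced()

        def dC(R):
            return cf.vector_field(std, f0, cf.State(R, 1.0))[1]

        root = bisect(dC, 0.01, 2.0, xtol=1e-12)
        assert cf.consumer_isocline_R(std) == pytest.approx(root, abs=1e-9)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(cf.ParameterError):
            cf.ModelParams(r=1.0, K_mean=2.0, a=1.0, e=0.2, b=1.0, d=0.2)  # a*e == d


class TestEquilibrium:
    def test_matches_2d_root_solve(self, std, k_hopf_std):
        """Closed form agrees with a numeric root solve of the full system."""
        f0 = cf.ForcingSpec.unforced()

        def equations(x, K):
            return cf.vector_field(std.with_K(K), f0, cf.State(*x))

        for K in (k_hopf_std, 1.2, 3.0):
            eq = cf.interior_equilibrium(std, K)
            sol = fsolve(equations, [0.3, 5.0], args=(K,), xtol=1e-13)
            assert eq.R_star == pytest.approx(sol[0], abs=1e-8)
            assert eq.C_star == pytest.approx(sol[1], abs=1e-8)

    def test_oracle_value_at_hopf(self, std, k_hopf_std):
        eq = cf.interior_equilibrium(std, k_hopf_std)
        assert eq.R_star == pytest.approx(0.2816901408, rel=1e-9)
        assert eq.C_star == pytest.approx(8.0827306179, rel=1e-8)

    def test_R_star_is_K_invariant(self, std):
        eqs = [cf.interior_equilibrium(std, K) for K in (1.0, 5.0)]
        assert eqs[0].R_star == eqs[1].R_star
        assert eqs[0].C_star != eqs[1].C_star  # K moves the equilibrium in C only

    def test_no_coexistence_at_boundary(self, std):
        with pytest.raises(cf.NoCoexistenceError):
            cf.interior_equilibrium(std, cf.consumer_isocline_R(std))

    def test_excitability_flag(self, std):
        low = cf.interior_equilibrium(std, 0.5)  # below the checkmark bottom
        high = cf.interior_equilibrium(std, 1.4)
        assert not low.excitable and low.lambda_im == 0.0
        assert high.excitable and high.lambda_im > 0.0


class TestJacobian:
    def finite_difference(self, m, K, h=1e-7):
        eq = cf.interior_equilibrium(m, K)
        f0 = cf.ForcingSpec.unforced()
        mk = m.with_K(K)

        def field(x):
            return np.array(cf.vector_field(mk, f0, cf.State(*x)))

        x0 = np.array([eq.R_star, eq.C_star])
        J = np.empty((2, 2))
        for j in range(2):
            dx = np.zeros(2)
            dx[j] = h * max(1.0, abs(x0[j]))
            J[:, j] = (field(x0 + dx) - field(x0 - dx)) / (2 * dx[j])
        return J

    @pytest.mark.parametrize("K", [1.0, 1.5633802816901408, 2.0, 4.0])
    def test_matches_finite_difference(self, std, K):
        J = cf.jacobian(std, K)
        J_fd = self.finite_difference(std, K)
        assert np.allclose(J, J_fd, rtol=1e-6, atol=1e-8)

    def test_lower_right_entry_zero_and_det_positive(self, std):
        for K in np.linspace(0.4, 5.0, 25):
            J = cf.jacobian(std, K)
            assert J[1, 1] == 0.0
            assert np.linalg.det(J) > 0.0

    def test_trace_is_twice_real_part_when_complex(self, std):
        J = cf.jacobian(std, 2.0)
        re, im = cf.lambda_max(std, 2.0)
        assert im > 0
        assert np.trace(J) == pytest.approx(2.0 * re, rel=1e-12)


class TestDominantEigenvalue:
    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(m=params_strategy)
    def test_closed_form_matches_eigendecomposition(self, m):
        re, im = cf.lambda_max(m, m.K_mean)
        eig = np.linalg.eigvals(cf.jacobian(m, m.K_mean))
        assert re == pytest.approx(float(np.max(eig.real)), abs=1e-9)
        assert im == pytest.approx(float(np.max(np.abs(eig.imag))), abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(m=params_strategy)
    def test_hopf_point_bracketed_by_sign_change(self, m):
        kh = cf.k_hopf(m)
        assert kh > cf.consumer_isocline_R(m)
        assert cf.lambda_max_re(m, kh) == pytest.approx(0.0, abs=1e-9)
        assert cf.lambda_max_re(m, kh * 0.99) < 0 < cf.lambda_max_re(m, kh * 1.01)

    def test_continuous_across_discriminant_branch(self, std):
        # the joint is continuous but sqrt-sloped: the gap shrinks like sqrt(dK)
        K_cm = eigenvalue_checkmark_bottom(std)
        for dK, tol in [(1e-4, 3e-2), (1e-8, 3e-4)]:
            below = cf.lambda_max_re(std, K_cm * (1 - dK))
            above = cf.lambda_max_re(std, K_cm * (1 + dK))
            assert below == pytest.approx(above, abs=tol)

    def test_single_sign_change_over_K(self, std, k_hopf_std):
        R_star = cf.consumer_isocline_R(std)
        Ks = np.linspace(R_star * 1.01, 10 * k_hopf_std, 2000)
        signs = np.sign([cf.lambda_max_re(std, K) for K in Ks])
        assert np.count_nonzero(np.diff(signs)) == 1


class TestHopfPoint:
    def test_closed_form_value(self, std):
        assert cf.k_hopf(std) == pytest.approx(1.11 / 0.71, rel=1e-12)

    def test_verified_by_bisection(self, std, k_hopf_std):
        root = bisect(lambda K: cf.lambda_max_re(std, K), 1.0, 3.0, xtol=1e-12)
        assert k_hopf_std == pytest.approx(root, abs=1e-9)

    def test_invariant_to_r_and_linear_in_b(self, std):
        assert cf.k_hopf(std) == cf.k_hopf(
            cf.ModelParams(r=1.5, K_mean=std.K_mean, a=1.3, e=0.7, b=1.0, d=0.2)
        )
        doubled_b = cf.ModelParams(r=10.0, K_mean=4.0, a=1.3, e=0.7, b=2.0, d=0.2)
        assert cf.k_hopf(doubled_b) == pytest.approx(2.0 * cf.k_hopf(std), rel=1e-12)

    def test_checkmark_bottom_splits_real_and_complex(self, std):
        K_cm = eigenvalue_checkmark_bottom(std)
        assert cf.consumer_isocline_R(std) < K_cm < cf.k_hopf(std)
        assert cf.lambda_max(std, K_cm * 0.99)[1] == 0.0
        assert cf.lambda_max(std, K_cm * 1.01)[1] > 0.0


class TestTypes:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(r=-1.0, K_mean=2.0, a=1.3, e=0.7, b=1.0, d=0.2),
            dict(r=10.0, K_mean=0.0, a=1.3, e=0.7, b=1.0, d=0.2),
            dict(r=10.0, K_mean=2.0, a=1.3, e=1.4, b=1.0, d=0.2),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(cf.ParameterError):
            cf.ModelParams(**kwargs)

    def test_forcing_spec_validation(self):
        with pytest.raises(cf.ParameterError):
            cf.ForcingSpec(A=-0.1, p=1.0)
        with pytest.raises(cf.ParameterError):
            cf.ForcingSpec(A=0.5, p=0.0)
        assert cf.ForcingSpec(A=0.5, p=4.0).period == pytest.approx(0.25)

    def test_negative_state_rejected(self):
        with pytest.raises(cf.ParameterError):
            cf.State(R=-0.1, C=1.0)
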