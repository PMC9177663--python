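"""Closed-form rate laws: identities, limits and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import modkin as mk
from modkin.laws import NoModificationError
from modkin.units import UnitError

positive = st.floats(min_value=1e-2, max_value=1e2)


class TestMichaelisMenten:
    def test_half_saturation_identity(self, arg_params):
        # S = Km gives exactly kcat/2: 24.35/2 for the strong-inhibition set
        assert mk.mm_velocity(arg_params.km, arg_params) == pytest.approx(12.175, abs=1e-12)

    def test_zero_substrate_zero_velocity(self, arg_params):
        assert mk.mm_velocity(0.0, arg_params) == 0.0

    def test_monotone_and_saturating(self, arg_params):
        s = np.logspace(-2, 4, 50)
        v = mk.mm_velocity(s, arg_params)
        assert np.all(np.diff(v) > 0)
        assert v[-1] == pytest.approx(arg_params.kcat, rel=1e-2)

    def test_negative_substrate_rejected(self, arg_params):
        with pytest.raises(ValueError, match="substrate"):
            mk.mm_velocity(-1.0, arg_params)


class TestGeneralModifier:
    def test_reduces_to_mm_at_zero_modifier(self, random_params):
        s = np.linspace(0, 40, 15)
        for p in random_params:
            np.testing.assert_allclose(
                mk.general_modifier_velocity(s, 0.0, p), mk.mm_velocity(s, p), rtol=1e-14)

    def test_infinite_modifier_saturates_to_modified_branch(self, random_params):
        for p in random_params:
            s = 3.0
            v_inf = p.beta * p.kcat * s / (p.alpha * p.km + s)
            v_big = mk.general_modifier_velocity(s, 1e6 * p.kx, p)
            assert v_big == pytest.approx(v_inf, rel=1e-3)

    def test_hyperbolic_monotonicity_in_modifier(self, random_params):
        # v(X) at fixed S never has an interior extremum
        x = np.logspace(-3, 5, 60)
        for p in random_params:
            v = mk.general_modifier_velocity(2.0, x, p)
            d = np.diff(v)
            signs = np.sign(d[np.abs(d) > 1e-15])
            assert signs.size == 0 or np.all(signs == signs[0])

    def test_efficiency_independent_of_modifier_when_coupled(self, pro_params):
        # alpha = beta: the S->0 apparent efficiency does not move with X
        eps = 1e-9
        base = mk.general_modifier_velocity(eps, 0.0, pro_params) / eps
        high = mk.general_modifier_velocity(eps, 10 * pro_params.kx, pro_params) / eps
        assert high == pytest.approx(base, rel=1e-9)

    def test_direction_sign_matches_velocity_change(self, random_params):
        for p in random_params:
            s = 2.0
            dv = (mk.general_modifier_velocity(s, 5 * p.kx, p)
                  - mk.general_modifier_velocity(s, 0.0, p))
            direction = mk.modification_direction(s, p)
            if abs(dv) > 1e-12:
                assert math.copysign(1, dv) == direction

    def test_no_ternary_complex_limit_is_linear_competitive(self):
        p = mk.KineticParameters(kcat=2.0, km=1.0, kx=10.0, alpha=math.inf, beta=0.5)
        assert p.no_ternary_complex
        v = mk.general_modifier_velocity(1.0, 10.0, p)
        assert v == pytest.approx(2.0 * 1.0 / (1.0 * 2.0 + 1.0))


class TestApparentParameters:
    def test_zero_modifier_returns_base_parameters(self, ala_params):
        assert mk.apparent_parameters(0.0, ala_params) == (ala_params.kcat, ala_params.km)

    def test_alpha_one_leaves_km_unchanged(self):
        p = mk.KineticParameters(kcat=3.0, km=2.0, kx=10.0, alpha=1.0, beta=4.0)
        for x in (0.1, 1.0, 10.0, 100.0):
            _, km_app = mk.apparent_parameters(x, p)
            assert km_app == pytest.approx(2.0, rel=1e-14)

    def test_coupled_alpha_beta_preserves_efficiency(self, pro_params):
        base = pro_params.kcat / pro_params.km
        for fac in (0.1, 1.0, 10.0):
            kc, km = mk.apparent_parameters(fac * pro_params.kx, pro_params)
            assert kc / km == pytest.approx(base, rel=1e-9)

    def test_reconstructs_velocity_surface(self, random_params):
        s = np.linspace(0.1, 30, 12)
        for p in random_params:
            for x in (0.0, 0.3 * p.kx, 3 * p.kx):
                kc, km = mk.apparent_parameters(x, p)
                np.testing.assert_allclose(
                    mk.general_modifier_velocity(s, x, p), kc * s / (km + s), rtol=1e-12)


class TestHalfEffect:
    def test_alpha_one_midpoint_is_kx(self):
        p = mk.KineticParameters(kcat=1.0, km=2.0, kx=7.5, alpha=1.0, beta=3.0)
        assert mk.analytic_half_effect(5.0, p) == pytest.approx(7.5)

    def test_zero_substrate_midpoint_is_kx(self, ala_params):
        assert mk.analytic_half_effect(0.0, ala_params) == pytest.approx(ala_params.kx)

    def test_worked_midpoint_value(self):
        # Km=1.60 mM, alpha=0.82, KX=5.0 uM, S=1.0 mM
        p = mk.KineticParameters(kcat=1.74, km=1.60, kx=5.0, alpha=0.82, beta=25.4)
        expected = 0.82 * 5.0 * (1.60 + 1.0) / (0.82 * 1.60 + 1.0)
        x50 = mk.analytic_half_effect(1.0, p)
        assert x50 == pytest.approx(expected, rel=1e-12)
        assert x50 == pytest.approx(4.611, abs=5e-4)

    def test_midpoint_bisects_the_hyperbola(self, random_params):
        for p in random_params:
            s = 1.7
            x50 = mk.analytic_half_effect(s, p)
            v_mid = mk.general_modifier_velocity(s, x50, p)
            v0 = mk.general_modifier_velocity(s, 0.0, p)
            v_inf = p.beta * p.kcat * s / (p.alpha * p.km + s)
            assert v_mid == pytest.approx(0.5 * (v0 + v_inf), rel=1e-9)

    def test_silent_modifier_has_no_midpoint(self):
        p = mk.KineticParameters(kcat=1.0, km=1.0, kx=1.0, alpha=1.0, beta=1.0)
        with pytest.raises(NoModificationError):
            mk.analytic_half_effect(1.0, p)


class TestSubstrateInhibition:
    q = mk.SESParameters(vmax_over_etot=0.5, km=300.0, ksi=400.0, kx_ses=0.1)

    def test_infinite_ksi_recovers_mm(self):
        q_mm = mk.SESParameters(vmax_over_etot=0.5, km=300.0, ksi=math.inf)
        for s in (50.0, 300.0, 900.0):
            assert mk.ses_velocity(s, q_mm) == pytest.approx(0.5 * s / (300.0 + s))

    def test_peak_location_by_grid_search(self):
        s = np.linspace(1, 3000, 60001)
        v = mk.ses_velocity(s, self.q)
        s_star = math.sqrt(self.q.km * self.q.ksi)
        assert abs(s[np.argmax(v)] - s_star) <= (s[1] - s[0])
        # strictly decreasing beyond the peak
        tail = v[s > s_star * 1.01]
        assert np.all(np.diff(tail) < 0)

    def test_peak_velocity_closed_form(self):
        s_star = math.sqrt(self.q.km * self.q.ksi)
        expected = self.q.vmax_over_etot / (1 + 2 * math.sqrt(self.q.km / self.q.ksi))
        assert mk.ses_velocity(s_star, self.q) == pytest.approx(expected, rel=1e-12)

    def test_modifier_coupling_reduces_to_plain_at_zero(self):
        s = np.linspace(10, 1000, 20)
        np.testing.assert_allclose(mk.ses_velocity_with_modifier(s, 0.0, self.q),
                                   mk.ses_velocity(s, self.q), rtol=1e-14)

    def test_modifier_deepens_inhibition(self):
        # dv/dX < 0 in the inhibited regime
        v1 = mk.ses_velocity_with_modifier(600.0, 0.16, self.q)
        v2 = mk.ses_velocity_with_modifier(600.0, 0.16 + 1e-6, self.q)
        assert v2 < v1

    def test_infinite_modifier_kills_velocity(self):
        assert mk.ses_velocity_with_modifier(600.0, 1e12, self.q) == pytest.approx(0.0, abs=1e-9)

    def test_missing_coupling_constant_rejected(self):
        q = mk.SESParameters(vmax_over_etot=0.5, km=300.0, ksi=400.0)
        with pytest.raises(ValueError, match="kx_ses"):
            mk.ses_velocity_with_modifier(100.0, 0.1, q)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(kcat=positive, km=positive, kx=positive,
       alpha=st.floats(min_value=0.05, max_value=50),
       beta=st.floats(min_value=0.05, max_value=50),
       s=st.floats(min_value=0, max_value=1e3),
       x=st.floats(min_value=0, max_value=1e4))
def test_velocity_bounds_property(kcat, km, kx, alpha, beta, s, x):
    """0 <= v <= kcat*max(1, beta) for any admissible state."""
    p = mk.KineticParameters(kcat=kcat, km=km, kx=kx, alpha=alpha, beta=beta)
    v = mk.general_modifier_velocity(s, x, p)
    assert 0.0 <= v <= kcat * max(1.0, beta) * (1 + 1e-12)


def test_unit_tags_must_match():
    p = mk.KineticParameters(kcat=1.0, km=1.0, kx=1.0, alpha=2.0, beta=0.5, s_unit="mM")
    converted = p.with_units(s_unit="uM")
    assert converted.km == pytest.approx(1000.0)
    with pytest.raises(UnitError):
        mk.KineticParameters(kcat=1.0, km=1.0, kx=1.0, alpha=2.0, beta=0.5, s_unit="furlongs")
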