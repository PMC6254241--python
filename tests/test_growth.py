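"""Growth-law primitives: rate, ODE solutions, closed forms, asymptote."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpgrowth.growth import (
    ExponentPair,
    GrowthParameters,
    NAMED_MODELS,
    asymptotic_mass,
    closed_form_mass,
    growth_rate,
    solve_growth,
)

AGES = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9.5, 11, 12.4, 15.3])


class TestExponentPair:
    def test_diagonal_flag(self):
        assert ExponentPair(0.7, 0.7).is_gompertz
        assert not ExponentPair(0.7, 0.7 + 1e-6).is_gompertz
        assert ExponentPair(0.7, 0.7 + 1e-12).is_gompertz

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            ExponentPair(-0.1, 1.0)
        with pytest.raises(ValueError):
            ExponentPair(1.0, 0.5)

    def test_named_registry(self):
        assert set(NAMED_MODELS) == {
            "von-bertalanffy-mass",
            "vbgf-length",
            "west",
            "logistic",
            "gompertz",
            "richards",
            "generalized-bertalanffy",
        }
        assert NAMED_MODELS["von-bertalanffy-mass"].pair == ExponentPair(2 / 3, 1)
        assert NAMED_MODELS["gompertz"].pair.is_gompertz
        with pytest.raises(ValueError):
            NAMED_MODELS["richards"].pair  # free exponent, no single pair


class TestGrowthRate:
    def test_vanishes_at_asymptotic_mass(self):
        pair = ExponentPair(2 / 3, 1)
        params = GrowthParameters(200.0, 11.2, 0.86)
        m_star = (11.2 / 0.86) ** 3
        assert growth_rate(pair, params, m_star) == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_rate_zero_at_e_when_p_equals_q(self):
        pair = ExponentPair(1.0, 1.0)
        params = GrowthParameters(100.0, 2.0, 2.0)
        assert growth_rate(pair, params, math.e) == pytest.approx(0.0, abs=1e-12)

    def test_off_diagonal_arithmetic(self):
        # direct arithmetic oracle: p*m^a - q*m^b
        pair = ExponentPair(2 / 3, 1)
        params = GrowthParameters(200.0, 11.2, 0.86)
        m = 192.1
        expected = 11.2 * m ** (2 / 3) - 0.86 * m
        assert growth_rate(pair, params, m) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(207.8, abs=0.5)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(ExponentPair(1, 2), GrowthParameters(10, 1, 0.1), 0.0)

    @given(
        a=st.floats(0.0, 1.2),
        gap=st.floats(0.05, 1.0),
        p=st.floats(0.5, 30.0),
        q=st.floats(0.05, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_rate_zero_at_equilibrium_property(self, a, gap, p, q):
        pair = ExponentPair(a, a + gap)
        params = GrowthParameters(50.0, p, q)
        m_star = asymptotic_mass(pair, params)
        rate = growth_rate(pair, params, m_star)
        assert abs(rate) <= 1e-8 * max(p * m_star**a, 1.0)


class TestSolveGrowth:
    def test_exponential_limit(self):
        # q = 0, a = 1 degenerates to pure exponential growth
        pair = ExponentPair(1.0, 2.0)
        params = GrowthParameters(5.0, 0.3, 0.0)
        t = np.linspace(0, 10, 11)
        traj = solve_growth(pair, params, t)
        assert traj.success
        np.testing.assert_allclose(traj.masses, 5.0 * np.exp(0.3 * t), rtol=1e-7)

    def test_initial_condition(self):
        traj = solve_growth(
            ExponentPair(2 / 3, 1), GrowthParameters(203.8, 11.2, 0.86), AGES
        )
        assert traj.success
        assert traj.masses[0] == pytest.approx(203.8)

    @pytest.mark.parametrize(
        "pair, params",
        [
            (ExponentPair(2 / 3, 1), GrowthParameters(203.8, 11.2, 0.86)),
            (ExponentPair(0.3, 1), GrowthParameters(50.0, 20.0, 2.0)),
            (ExponentPair(1, 1), GrowthParameters(150.0, 14.0, 2.0)),
            (ExponentPair(1, 2), GrowthParameters(301.716, 0.528051, 0.000253611)),
        ],
    )
    def test_matches_closed_form(self, pair, params):
        t = np.linspace(0, 15.3, 40)
        traj = solve_growth(pair, params, t)
        exact = closed_form_mass(pair, params, t)
        assert traj.success
        np.testing.assert_allclose(traj.masses, exact, rtol=1e-6)

    def test_diagonal_limit_continuity(self):
        # general-equation trajectories converge to the Gompertz limit as
        # b -> a under the limiting parameter map p = P + Q/eps, q = Q/eps
        # (then p*m^a - q*m^(a+eps) -> m^a * (P - Q*ln m))
        a = 0.7
        P, Q, m0 = 21.0, 2.76, 175.0
        t = np.linspace(0, 15.3, 20)
        ref = solve_growth(ExponentPair(a, a), GrowthParameters(m0, P, Q), t).masses
        devs = {}
        for eps in (1e-3, 1e-4, 1e-5, 1e-6):
            near = solve_growth(
                ExponentPair(a, a + eps),
                GrowthParameters(m0, P + Q / eps, Q / eps),
                t,
            )
            assert near.success
            devs[eps] = float(np.max(np.abs(near.masses - ref) / ref))
        assert devs[1e-3] > devs[1e-4] > devs[1e-5]
        assert devs[1e-6] < 1e-4

    def test_monotone_and_bounded(self):
        pair = ExponentPair(0.6, 1.1)
        params = GrowthParameters(20.0, 8.0, 0.3)
        mmax = asymptotic_mass(pair, params)
        traj = solve_growth(pair, params, np.linspace(0, 40, 200))
        assert traj.success
        assert np.all(np.diff(traj.masses) > 0)
        assert np.all(traj.masses <= mmax * (1 + 1e-9))

    def test_failure_flagged_not_raised(self):
        # super-linear pure growth blows up in finite time
        traj = solve_growth(
            ExponentPair(2.0, 3.0), GrowthParameters(100.0, 50.0, 0.0),
            np.linspace(0, 50, 20),
        )
        assert not traj.success

    def test_invalid_times_raise(self):
        pair, params = ExponentPair(1, 2), GrowthParameters(10, 1, 0.01)
        with pytest.raises(ValueError):
            solve_growth(pair, params, [-1.0, 0.0])
        with pytest.raises(ValueError):
            solve_growth(pair, params, [2.0, 1.0])


class TestClosedForm:
    def test_initial_value(self):
        assert closed_form_mass(
            ExponentPair(2 / 3, 1), GrowthParameters(203.8, 11.2, 0.86), 0.0
        ) == pytest.approx(203.8)

    def test_gompertz_long_time_limit(self):
        params = GrowthParameters(150.0, 14.0, 2.0)
        val = closed_form_mass(ExponentPair(1, 1), params, 1e3)
        assert val == pytest.approx(math.exp(14.0 / 2.0), rel=1e-9)

    def test_unsupported_pair(self):
        with pytest.raises(NotImplementedError):
            closed_form_mass(ExponentPair(0.5, 0.9), GrowthParameters(10, 1, 0.1), 1.0)


class TestAsymptoticMass:
    def test_bertalanffy_value(self):
        val = asymptotic_mass(ExponentPair(2 / 3, 1), GrowthParameters(200, 11.2, 0.86))
        assert val == pytest.approx((11.2 / 0.86) ** 3, rel=1e-12)
        assert val == pytest.approx(2208.7, abs=1.0)

    def test_diagonal_value(self):
        val = asymptotic_mass(
            ExponentPair(0.686028, 0.686028), GrowthParameters(175.67, 21.3148, 2.76054)
        )
        assert val == pytest.approx(math.exp(21.3148 / 2.76054), rel=1e-12)
        assert val == pytest.approx(2256, abs=5)

    def test_p_equals_q(self):
        assert asymptotic_mass(ExponentPair(0.3, 0.9), GrowthParameters(10, 2, 2)) == 1.0

    def test_unbounded_growth(self):
        assert asymptotic_mass(ExponentPair(0.3, 1), GrowthParameters(10, 2, 0)) == math.inf
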