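"""Closed-form rate derivations against their defining endpoint conditions.

Each rate constant is defined by a daughter-cell bookkeeping condition on
the linear dilute-regime system (e.g. a unit factory seed leaves 2(1-p)
factory and 2p mutant daughters after one factory doubling).  The tests
re-derive those endpoints by direct numerical integration of the linear
system — an oracle independent of the closed forms under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mistsim import (
    VesselParams,
    derive_base_rates,
    derive_green_rates,
    derive_green_star_rates,
    derive_red_rates,
)
from mistsim.rates import ParameterError

LN2 = math.log(2.0)


def _integrate_linear(matrix, y0, t_end):
    """Independent endpoint oracle: integrate dy/dt = M y to high accuracy."""
    sol = solve_ivp(
        lambda t, y: matrix @ y,
        (0.0, t_end),
        np.asarray(y0, float),
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
    )
    return sol.y[:, -1]


class TestBaseRates:
    @pytest.mark.parametrize(
        "tau_b,tau_b_star,p,r_b,r_b_star,c_b",
        [
            (1.0, 1.0, 0.0, LN2, LN2, 0.0),  # p=0 removes mutation
            (2.0, 1.0, 0.5, 0.0, LN2, None),  # 2(1-p)=1 -> ln(1)=0
            (5.0, 1.0, 1e-6, math.log(2 * (1 - 1e-6)) / 5, LN2, None),
        ],
    )
    def test_closed_forms(self, tau_b, tau_b_star, p, r_b, r_b_star, c_b):
        rates = derive_base_rates(tau_b, tau_b_star, p)
        assert rates.r_b == pytest.approx(r_b, abs=1e-15)
        assert rates.r_b_star == pytest.approx(r_b_star, abs=1e-15)
        if c_b is not None:
            assert rates.c_b == pytest.approx(c_b, abs=1e-15)

    def test_mutation_gain_reproduces_daughter_count(self):
        """c_b is defined so that B*(tau_b) = 2p from a unit factory seed."""
        tau_b, p = 5.0, 1e-6
        rates = derive_base_rates(tau_b, 1.0, p)
        assert rates.c_b == pytest.approx(3.6968e-8, rel=1e-3)
        m = np.array([[rates.r_b, 0.0], [rates.c_b, rates.r_b_star]])
        b, bstar = _integrate_linear(m, [1.0, 0.0], tau_b)
        assert b == pytest.approx(2 * (1 - p), rel=1e-9)
        assert bstar == pytest.approx(2 * p, rel=1e-6)

    def test_degenerate_limit_is_zero_when_mutation_free(self):
        rates = derive_base_rates(1.0, 1.0, 0.0)
        assert rates.c_b == 0.0


class TestRedRates:
    def test_exact_identities(self, std_rates):
        r, b = std_rates.red, std_rates.base
        assert r.r_a_star == -r.r_a  # the Eq-style identity is exact
        assert r.c_ab_star == -r.r_a
        assert r.c_ab_2star == b.r_b_star
        assert r.r_a <= 0.0 <= r.r_a_star

    def test_identity_from_stem_survival(self, std_params):
        """exp(r_a tau_b*) = 1-p exactly, hence p r_a/(e^{r_a tau_b*}-1) = -r_a."""
        p = std_params.p
        base = derive_base_rates(5.0, 1.0, p)
        red = derive_red_rates(base, 5.0, 1.0, p)
        assert math.exp(red.r_a * 1.0) == pytest.approx(1 - p, rel=1e-15)
        assert p * red.r_a / math.expm1(red.r_a * 1.0) == pytest.approx(
            -red.r_a, rel=1e-9
        )

    def test_mutation_free_case(self):
        base = derive_base_rates(5.0, 1.0, 0.0)
        red = derive_red_rates(base, 5.0, 1.0, 0.0)
        assert red.r_a == 0.0 and red.r_a_star == 0.0 and red.c_ab_star == 0.0
        assert red.c_ab_2star == LN2
        assert red.c_ab == pytest.approx(base.r_b / math.expm1(base.r_b), rel=1e-12)

    def test_conversion_rate_reproduces_fate_counts(self):
        """One stem cell yields (1-p) stem + (1-p) factory + p mutant stem per tau_b*."""
        tau_b, p = 5.0, 1e-6
        base = derive_base_rates(tau_b, 1.0, p)
        red = derive_red_rates(base, tau_b, 1.0, p)
        assert red.c_ab == pytest.approx(0.93229, rel=1e-4)
        # (A, A*, B) block of the linear red system
        m = np.array(
            [
                [red.r_a, 0.0, 0.0],
                [red.r_a_star, 0.0, 0.0],
                [red.c_ab, 0.0, base.r_b],
            ]
        )
        a, astar, b = _integrate_linear(m, [1.0, 0.0, 0.0], 1.0)
        assert a == pytest.approx(1 - p, rel=1e-9)
        assert astar == pytest.approx(p, rel=1e-6)
        assert b == pytest.approx(1 - p, rel=1e-6)


class TestGreenRates:
    def test_mutation_free_case(self):
        g = derive_green_rates(5.0, 1.0, 0.0)
        assert g.r_bg == 0.0 and g.c_bg_star == 0.0 and g.c_bag_star == 0.0
        assert g.r_ag == LN2 and g.c_ag == 0.0
        assert g.c_bag_2star == LN2

    @pytest.mark.parametrize("p", [1e-6, 1e-3, 0.3])
    def test_sign_structure(self, p):
        g = derive_green_rates(5.0, 1.0, p)
        assert g.r_bg < 0.0 < g.r_ag  # ln monotone, p < 1/2

    def test_factory_conversion_reproduces_stem_count(self):
        """Each factory cell delivers one (surviving) stem daughter per tau_b.

        Integrating the linear green (B, A) block from a unit factory seed
        must give A(tau_b) = 1-p through the factory-derived channel.
        """
        tau_b, p = 5.0, 1e-6
        g = derive_green_rates(tau_b, 1.0, p)
        m = np.array([[g.r_bg, 0.0], [g.c_bag, g.r_ag]])
        b, a = _integrate_linear(m, [1.0, 0.0], tau_b)
        assert a == pytest.approx(1 - p, rel=1e-6)
        assert b == pytest.approx(1 - p, rel=1e-9)


class TestGreenStarRates:
    def test_mutation_free_case(self):
        gs = derive_green_star_rates(derive_base_rates(5.0, 1.0, 0.0), 1.0, 0.0)
        assert gs.r_ags == gs.r_ags_star == LN2
        assert gs.c_ags == 0.0

    def test_same_form_as_base_on_fast_clock(self):
        """r_ags etc. are the base formulas with tau_b replaced by tau_b*."""
        p = 1e-4
        base_fast = derive_base_rates(1.0, 1.0, p)
        gs = derive_green_star_rates(derive_base_rates(5.0, 1.0, p), 1.0, p)
        assert gs.r_ags == base_fast.r_b
        assert gs.r_ags_star == base_fast.r_b_star
        assert gs.c_ags == base_fast.c_b

    def test_mutation_gain_reproduces_daughter_count(self):
        p = 1e-6
        gs = derive_green_star_rates(derive_base_rates(5.0, 1.0, p), 1.0, p)
        m = np.array([[gs.r_ags, 0.0], [gs.c_ags, gs.r_ags_star]])
        a, astar = _integrate_linear(m, [1.0, 0.0], 1.0)
        assert a == pytest.approx(2 * (1 - p), rel=1e-9)
        assert astar == pytest.approx(2 * p, rel=1e-6)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    tau_b_star=st.floats(0.1, 10.0),
    ratio=st.floats(1.0, 20.0),
    p=st.floats(0.0, 0.5, exclude_max=True),
)
def test_rate_invariants(tau_b_star, ratio, p):
    """For all admissible parameters: ordering, signs and exact identities."""
    tau_b = ratio * tau_b_star
    base = derive_base_rates(tau_b, tau_b_star, p)
    red = derive_red_rates(base, tau_b, tau_b_star, p)
    green = derive_green_rates(tau_b, tau_b_star, p)
    gs = derive_green_star_rates(base, tau_b_star, p)

    assert base.r_b_star >= base.r_b
    assert red.r_a <= 0.0 <= red.r_a_star
    assert red.r_a_star == -red.r_a
    assert red.c_ab_2star == base.r_b_star
    assert green.c_bg_star == -green.r_bg
    assert gs.r_ags_star >= gs.r_ags
    for c in (
        base.c_b, red.c_ab, red.c_ab_star, red.c_ab_2star,
        green.c_bag, green.c_ag, green.c_bag_star, green.c_bag_2star,
        gs.c_ags,
    ):
        assert c >= 0.0
    if p == 0.0:
        assert base.c_b == 0.0 and gs.c_ags == 0.0


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(tau_b=0.0),
        dict(tau_b_star=-1.0),
        dict(p=1.0),
        dict(p=-0.1),
        dict(q=1.5),
        dict(q=0.0),
        dict(m=-0.2),
        dict(tau_b=1.0, tau_b_star=2.0),  # factory faster than mutants
        dict(init_B=0.9, init_A=0.3),  # exceeds K = 1
        dict(init_Bstar=-0.5),
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ParameterError):
        VesselParams(**kwargs)
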