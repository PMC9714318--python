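"""Closed-form solutions of the linear (dilute, closed-vessel) regimes.

When the populations are far below the carrying capacity and there is no
outflow, every scenario reduces to a linear, lower-triangular ODE system
whose solution is a sum of exponentials.  These solutions serve two
purposes:

* they are the *defining* relations of the rate constants — e.g. a unit
  factory seed must produce exactly ``2(1-p)`` factory and ``2p`` mutant
  daughters after one factory doubling time — so evaluating them at the
  doubling time recovers the division-diagram fate counts exactly;
* they are independent oracles for the numerical integrator (the dynamics
  module must reproduce them to ~1e-8 relative error with crowding and
  dilution disabled).

The mutant-factory line of the red system (and the mutant-stem line of the
green system) receives sources from three other exponentials; rather than
expanding the four-term symbolic solution, those single components are
evaluated by high-accuracy quadrature of the exact integrand — the oracle
is meant to be simple and independent, not fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .rates import BaseRates, GreenRates, GreenStarRates, RateSet, RedRates

__all__ = [
    "LinearSolution",
    "linear_base",
    "linear_red",
    "linear_green",
    "linear_green_star",
    "linear_system_matrix",
]

_QUAD_KW = dict(epsabs=1e-13, epsrel=1e-11, limit=200)


def _two_exp(c: float, r1: float, r2: float, t: float) -> float:
    """c * (exp(r1 t) - exp(r2 t)) / (r1 - r2), with the r1 == r2 limit c*t*exp(r1 t)."""
    if abs(r1 - r2) < 1e-12 * max(abs(r1), abs(r2), 1.0):
        return c * t * np.exp(r1 * t)
    return c * (np.exp(r1 * t) - np.exp(r2 * t)) / (r1 - r2)


def _expm1_ratio(r: float, t: float) -> float:
    """(exp(r t) - 1) / r, with the r == 0 limit t."""
    if abs(r) < 1e-300:
        return t
    return np.expm1(r * t) / r


@dataclass(frozen=True)
class LinearSolution:
    """Evaluable closed-form solution y(t) = (B, B*, A, A*) of a linear regime."""

    y0: np.ndarray
    _eval: Callable[[float], np.ndarray]

    def __call__(self, t) -> np.ndarray:
        """Evaluate at a scalar time or an array of times (rows = times)."""
        if np.ndim(t) == 0:
            return self._eval(float(t))
        return np.stack([self._eval(float(ti)) for ti in np.asarray(t).ravel()])


def linear_base(B0: float, Bstar0: float, rates: BaseRates) -> LinearSolution:
    """Dilute-regime base model: factory growth plus a mutation trickle.

    ``B(t) = B0 e^{r_b t}``;
    ``B*(t) = B*_0 e^{r_b* t} + c_b B0 (e^{r_b* t} - e^{r_b t})/(r_b* - r_b)``.
    At ``t = tau_b`` with a unit factory seed this gives the fate counts
    ``2(1-p)`` and ``2p``.
    """

    def ev(t: float) -> np.ndarray:
        B = B0 * np.exp(rates.r_b * t)
        Bs = Bstar0 * np.exp(rates.r_b_star * t) + _two_exp(
            rates.c_b * B0, rates.r_b_star, rates.r_b, t
        )
        return np.array([B, Bs, 0.0, 0.0])

    return LinearSolution(y0=np.array([B0, Bstar0, 0.0, 0.0]), _eval=ev)


def linear_red(
    A0: float,
    Astar0: float,
    B0: float,
    Bstar0: float,
    base: BaseRates,
    red: RedRates,
) -> LinearSolution:
    """Dilute-regime red-light model (asymmetric stem division).

    The stem line is autonomous, the mutant-stem line is driven by A only,
    and the factory line collects the stem conversion flux:

    ``A(t) = A0 e^{r_a t}``;
    ``A*(t) = A*_0 + A0 r_a* (e^{r_a t} - 1)/r_a``;
    ``B(t) = B0 e^{r_b t} + c_ab A0 (e^{r_b t} - e^{r_a t})/(r_b - r_a)``.

    At ``t = tau_b*`` a unit stem seed yields ``(A, A*, B) = (1-p, p, 1-p)``.
    The mutant-factory component, sourced by all three other populations,
    is evaluated by quadrature of the exact exponential integrand.
    """

    def A(t: float) -> float:
        return A0 * np.exp(red.r_a * t)

    def Astar(t: float) -> float:
        return Astar0 + A0 * red.r_a_star * _expm1_ratio(red.r_a, t)

    def B(t: float) -> float:
        return B0 * np.exp(base.r_b * t) + _two_exp(
            red.c_ab * A0, base.r_b, red.r_a, t
        )

    def Bstar(t: float) -> float:
        def integrand(s: float) -> float:
            src = base.c_b * B(s) + red.c_ab_star * A(s) + red.c_ab_2star * Astar(s)
            return np.exp(base.r_b_star * (t - s)) * src

        val, _ = quad(integrand, 0.0, t, **_QUAD_KW)
        return Bstar0 * np.exp(base.r_b_star * t) + val

    def ev(t: float) -> np.ndarray:
        return np.array([B(t), Bstar(t), A(t), Astar(t)])

    return LinearSolution(y0=np.array([B0, Bstar0, A0, Astar0]), _eval=ev)


def linear_green(
    B0: float,
    Bstar0: float,
    A0: float,
    Astar0: float,
    green: GreenRates,
) -> LinearSolution:
    """Dilute-regime green-light model (symmetric stem division).

    The factory count is conserved up to mutation (``r_bg <= 0``), mutant
    factories accumulate only from factory mutation, and the stem pool
    collects both its own doubling and the factory conversion flux.  The
    mutant-stem component is evaluated by quadrature.
    """

    def B(t: float) -> float:
        return B0 * np.exp(green.r_bg * t)

    def Bstar(t: float) -> float:
        return Bstar0 + green.c_bg_star * B0 * _expm1_ratio(green.r_bg, t)

    def A(t: float) -> float:
        return A0 * np.exp(green.r_ag * t) + _two_exp(
            green.c_bag * B0, green.r_ag, green.r_bg, t
        )

    def Astar(t: float) -> float:
        def integrand(s: float) -> float:
            src = (
                green.c_ag * A(s)
                + green.c_bag_star * B(s)
                + green.c_bag_2star * Bstar(s)
            )
            return np.exp(green.r_ag_star * (t - s)) * src

        val, _ = quad(integrand, 0.0, t, **_QUAD_KW)
        return Astar0 * np.exp(green.r_ag_star * t) + val

    def ev(t: float) -> np.ndarray:
        return np.array([B(t), Bstar(t), A(t), Astar(t)])

    return LinearSolution(y0=np.array([B0, Bstar0, A0, Astar0]), _eval=ev)


def linear_green_star(
    B0: float,
    Bstar0: float,
    A0: float,
    Astar0: float,
    base: BaseRates,
    gs: GreenStarRates,
) -> LinearSolution:
    """Dilute-regime green-light-star model.

    Factory and mutant-factory components follow the base-model closed
    form; stems follow the same two-exponential pattern on the fast clock.
    """
    factory = linear_base(B0, Bstar0, base)

    def ev(t: float) -> np.ndarray:
        out = factory(t)
        out[2] = A0 * np.exp(gs.r_ags * t)
        out[3] = Astar0 * np.exp(gs.r_ags_star * t) + _two_exp(
            gs.c_ags * A0, gs.r_ags_star, gs.r_ags, t
        )
        return out

    return LinearSolution(y0=np.array([B0, Bstar0, A0, Astar0]), _eval=ev)


def linear_system_matrix(scenario: str, rates: RateSet) -> np.ndarray:
    """System matrix M of the linear regime, dy/dt = M y, y = (B, B*, A, A*).

    A second, fully independent route to the same solutions via
    ``scipy.linalg.expm``; used to cross-check the hand-written forms.
    """
    b, r, g, gs = rates.base, rates.red, rates.green, rates.green_star
    if scenario == "base":
        return np.array(
            [
                [b.r_b, 0, 0, 0],
                [b.c_b, b.r_b_star, 0, 0],
                [0, 0, 0, 0],
                [0, 0, 0, 0],
            ]
        )
    if scenario == "red":
        return np.array(
            [
                [b.r_b, 0, r.c_ab, 0],
                [b.c_b, b.r_b_star, r.c_ab_star, r.c_ab_2star],
                [0, 0, r.r_a, 0],
                [0, 0, r.r_a_star, 0],
            ]
        )
    if scenario == "green":
        return np.array(
            [
                [g.r_bg, 0, 0, 0],
                [g.c_bg_star, 0, 0, 0],
                [g.c_bag, 0, g.r_ag, 0],
                [g.c_bag_star, g.c_bag_2star, g.c_ag, g.r_ag_star],
            ]
        )
    if scenario == "green_star":
        return np.array(
            [
                [b.r_b, 0, 0, 0],
                [b.c_b, b.r_b_star, 0, 0],
                [0, 0, gs.r_ags, 0],
                [0, 0, gs.c_ags, gs.r_ags_star],
            ]
        )
    raise ValueError(f"unknown scenario {scenario!r}")
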