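"""ODE right-hand sides and integration for the four MiST scenarios.

The state is always the four-vector ``(B, B*, A, A*)`` — factory, mutant
factory, stem and mutant stem cells — even for the base model, where the
stem components are identically zero.  All scenarios share the same
structure: every growth term is throttled by the logistic crowding factor
``C = 1 - N/K`` (N summing all four populations) and every population is
diluted at the continuous harvest rate ``m``.

Internally time is measured in mutant doubling times (``tau_b_star = 1``)
and populations as absolute counts with whatever K the caller supplies;
the model is scale-free in K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .rates import ParameterError, RateSet, VesselParams

__all__ = [
    "PopulationState",
    "Trajectory",
    "crowding",
    "make_rhs",
    "integrate",
    "IntegrationError",
    "EXTINCTION_FLOOR",
    "DEFAULT_RTOL",
]

#: populations below EXTINCTION_FLOOR * K are treated as zero in fractions
EXTINCTION_FLOOR = 1e-12
DEFAULT_RTOL = 1e-8
#: dense-output sampling step for stored trajectories (mutant doubling times)
SAMPLE_DT = 0.02

SCENARIOS = ("base", "red", "green", "green_star")
PHASE_LABELS = ("none", "red", "green", "green_star")


@dataclass(frozen=True)
class PopulationState:
    """The four population counts at one instant."""

    B: float
    B_star: float
    A: float
    A_star: float

    def __post_init__(self) -> None:
        if min(self.B, self.B_star, self.A, self.A_star) < 0:
            raise ParameterError("populations must be non-negative")

    @property
    def total(self) -> float:
        return self.B + self.B_star + self.A + self.A_star

    def as_array(self) -> np.ndarray:
        return np.array([self.B, self.B_star, self.A, self.A_star], dtype=float)


def crowding(state, K: float) -> float:
    """Logistic crowding factor ``C = 1 - N/K``.

    ``state`` may be a :class:`PopulationState` or any length-4 sequence.
    The sum always runs over all four populations; in the base model the
    stem components are zero so this reduces to ``1 - (B + B*)/K``.
    """
    if K <= 0:
        raise ParameterError(f"carrying capacity must be positive, got K={K}")
    n = state.total if isinstance(state, PopulationState) else float(np.sum(state[:4]))
    return 1.0 - n / K


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state reached."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(f"{message} (at t={t:g})")
        self.t = t
        self.last_state = state


def make_rhs(
    scenario: str,
    rates: RateSet,
    m: float,
    K: float,
    *,
    crowded: bool = True,
    quadrature: bool = False,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the ODE right-hand side ``f(t, y)`` for one scenario.

    Parameters
    ----------
    scenario:
        One of ``base``, ``red``, ``green``, ``green_star``.
    rates:
        Internally normalised :class:`RateSet` (``tau_b_star = 1``).
    m:
        Dilution rate per internal time unit (``RateSet.m_internal``).
    crowded:
        If False the crowding factor is pinned at 1, giving the linear
        dilute-regime system (used by the closed-form oracle tests).
    quadrature:
        If True the state gains a fifth component accumulating the harvest
        integral ``\\int m B/N dt`` alongside the populations.

    Notes
    -----
    The mutation channels are structural, not symmetric: e.g. under red
    light the mutant stem pool grows in proportion to the *productive*
    stem pool A (a mutant stem cell's asymmetric division replaces itself
    and adds a mutant factory cell, so A* is not self-amplifying), and
    under green light mutant factory cells feed the mutant stem pool
    rather than doubling themselves.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if K <= 0:
        raise ParameterError(f"carrying capacity must be positive, got K={K}")

    b = rates.base
    r = rates.red
    g = rates.green
    gs = rates.green_star
    floor = EXTINCTION_FLOOR * K

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        B, Bs, A, As = y[0], y[1], y[2], y[3]
        N = B + Bs + A + As
        C = 1.0 - N / K if crowded else 1.0

        if scenario == "base":
            dB = b.r_b * B * C - m * B
            dBs = (b.r_b_star * Bs + b.c_b * B) * C - m * Bs
            dA = -m * A
            dAs = -m * As
        elif scenario == "red":
            dB = (b.r_b * B + r.c_ab * A) * C - m * B
            dBs = (
                b.r_b_star * Bs + b.c_b * B + r.c_ab_star * A + r.c_ab_2star * As
            ) * C - m * Bs
            dA = r.r_a * A * C - m * A
            dAs = r.r_a_star * A * C - m * As
        elif scenario == "green":
            dB = g.r_bg * B * C - m * B
            dBs = g.c_bg_star * B * C - m * Bs
            dA = (g.r_ag * A + g.c_bag * B) * C - m * A
            dAs = (
                g.r_ag_star * As + g.c_ag * A + g.c_bag_star * B + g.c_bag_2star * Bs
            ) * C - m * As
        else:  # green_star: factory lines identical to base
            dB = b.r_b * B * C - m * B
            dBs = (b.r_b_star * Bs + b.c_b * B) * C - m * Bs
            dA = gs.r_ags * A * C - m * A
            dAs = (gs.r_ags_star * As + gs.c_ags * A) * C - m * As

        if quadrature:
            dh = m * B / N if N > floor else 0.0
            return np.array([dB, dBs, dA, dAs, dh])
        return np.array([dB, dBs, dA, dAs])

    return rhs


@dataclass
class Trajectory:
    """Time-stamped population states annotated with the active light phase.

    ``times`` are in mutant doubling times (``tau_b_star`` units); the
    ``generations`` property converts to factory doubling times, the unit
    used for all reporting.  ``harvest`` (optional) is the cumulative
    harvest integral ``\\int m B/N dt`` carried as an ODE quadrature state.
    """

    times: np.ndarray
    states: np.ndarray  # (n, 4)
    phases: np.ndarray  # (n,) str labels
    params: VesselParams | None = None
    harvest: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.phases = np.asarray(self.phases, dtype=object)
        if self.states.ndim != 2 or self.states.shape[1] != 4:
            raise ParameterError("states must be an (n, 4) array")
        n = len(self.times)
        if self.states.shape[0] != n or len(self.phases) != n:
            raise ParameterError("times, states and phases must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        if self.harvest is not None:
            self.harvest = np.asarray(self.harvest, dtype=float)
            if len(self.harvest) != n:
                raise ParameterError("harvest must match times in length")

    # -- column accessors -------------------------------------------------
    @property
    def B(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def B_star(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def A(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def A_star(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def N(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def generations(self) -> np.ndarray:
        """Time in factory doubling times (tau_b units)."""
        ratio = self.params.ratio if self.params is not None else 1.0
        return self.times / ratio

    def _floor(self) -> float:
        K = self.params.K if self.params is not None else 1.0
        return EXTINCTION_FLOOR * K

    @property
    def factory_fraction(self) -> np.ndarray:
        """B/N, defined as 0 where N is below the extinction floor."""
        N = self.N
        safe = N > self._floor()
        return np.divide(self.B, N, out=np.zeros_like(N), where=safe)

    @property
    def productive_fraction(self) -> np.ndarray:
        """(B + A)/N — the non-mutant share; 0 below the extinction floor."""
        N = self.N
        safe = N > self._floor()
        return np.divide(self.B + self.A, N, out=np.zeros_like(N), where=safe)

    def final_state(self) -> PopulationState:
        return PopulationState(*self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.times,
                "generation": self.generations,
                "B": self.B,
                "B_star": self.B_star,
                "A": self.A,
                "A_star": self.A_star,
            }
        )
        df["N"] = self.N
        df["factory_fraction"] = self.factory_fraction
        df["phase"] = self.phases
        return df

    @staticmethod
    def concatenate(pieces: Sequence["Trajectory"]) -> "Trajectory":
        """Stitch contiguous segments, dropping duplicated joint points."""
        if not pieces:
            raise ParameterError("cannot concatenate an empty list of segments")
        times = [pieces[0].times]
        states = [pieces[0].states]
        phases = [pieces[0].phases]
        harvest = [pieces[0].harvest] if pieces[0].harvest is not None else None
        for seg in pieces[1:]:
            start = 1 if np.isclose(seg.times[0], times[-1][-1]) else 0
            times.append(seg.times[start:])
            states.append(seg.states[start:])
            phases.append(seg.phases[start:])
            if harvest is not None:
                harvest.append(seg.harvest[start:])
        return Trajectory(
            times=np.concatenate(times),
            states=np.concatenate(states),
            phases=np.concatenate(phases),
            params=pieces[0].params,
            harvest=np.concatenate(harvest) if harvest is not None else None,
        )


def _clamp_small_negatives(y: np.ndarray, tol: float, t: float) -> np.ndarray:
    """Clamp tolerance-level undershoots to zero; raise on real negatives."""
    if y.min() < -tol:
        raise IntegrationError(
            f"population went negative beyond tolerance ({y.min():.3e} < -{tol:.1e})",
            t,
            y,
        )
    return np.where(y < 0, 0.0, y)


def solve_segment(
    rhs: Callable,
    y0: np.ndarray,
    t_span: tuple[float, float],
    *,
    events=None,
    rtol: float = DEFAULT_RTOL,
    atol=None,
    max_step: float = np.inf,
    K: float = 1.0,
):
    """Low-level wrapper around ``solve_ivp`` (LSODA, dense output).

    Returns the scipy solution object; raises :class:`IntegrationError` on
    solver failure.  The mutation channels span ~6 orders of magnitude
    relative to the growth rates, so the stiff-capable LSODA with a tight
    relative tolerance is the default.
    """
    if atol is None:
        n = len(y0)
        atol = np.full(n, 1e-12 * K)
        if n == 5:  # harvest quadrature state is O(1..100), not O(K)
            atol[4] = 1e-10
    sol = solve_ivp(
        rhs,
        t_span,
        np.asarray(y0, dtype=float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        events=events,
        dense_output=True,
    )
    if sol.status == -1:
        raise IntegrationError(sol.message, sol.t[-1], sol.y[:, -1])
    return sol


def _sample_times(t0: float, t1: float, dt: float) -> np.ndarray:
    n = max(int(np.ceil((t1 - t0) / dt)), 1)
    return np.linspace(t0, t1, n + 1)


def integrate(
    scenario: str,
    state0: PopulationState | Sequence[float],
    t_span: tuple[float, float],
    params: VesselParams,
    *,
    crowded: bool = True,
    dilution: bool = True,
    rtol: float = DEFAULT_RTOL,
    atol=None,
    max_step: float = np.inf,
    sample_dt: float = SAMPLE_DT,
    quadrature: bool = True,
) -> Trajectory:
    """Integrate one scenario over ``t_span`` (internal time units).

    Returns a :class:`Trajectory` sampled on a uniform grid from the
    solver's dense output.  Small negative undershoots (within the solver's
    absolute tolerance) are clamped to zero; larger ones raise
    :class:`IntegrationError`.

    ``crowded=False`` and ``dilution=False`` reduce the system to the
    linear dilute regime used by the closed-form oracles.
    """
    rates = RateSet.from_params(params)
    m = rates.m_internal if dilution else 0.0
    rhs = make_rhs(scenario, rates, m, params.K, crowded=crowded, quadrature=quadrature)
    y0 = state0.as_array() if isinstance(state0, PopulationState) else np.asarray(state0, float)
    if quadrature and len(y0) == 4:
        y0 = np.append(y0, 0.0)
    sol = solve_segment(
        rhs, y0, t_span, rtol=rtol, atol=atol, max_step=max_step, K=params.K
    )
    ts = _sample_times(t_span[0], sol.t[-1], sample_dt)
    ys = sol.sol(ts)
    clamp_tol = 10 * rtol * params.K + 1e-10 * params.K
    states = np.stack(
        [_clamp_small_negatives(ys[:4, i], clamp_tol, ts[i]) for i in range(len(ts))]
    )
    phase = scenario if scenario != "base" else "none"
    return Trajectory(
        times=ts,
        states=states,
        phases=np.full(len(ts), phase, dtype=object),
        params=params,
        harvest=ys[4] if quadrature else None,
    )
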