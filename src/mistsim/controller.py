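"""Threshold-driven light-cycling controller for the switched MiST scenarios.

The red-green and red-green-star bioreactors regulate the factory-cell
fraction ``B/N`` around the harvesting threshold ``q`` with a bang-bang
light controller:

* **red light** (production) while ``B/N < q`` — stem cells divide
  asymmetrically, converting the stem pool into new factory cells and
  driving the factory fraction back up toward ``q``;
* **green light** (regeneration) while ``B/N >= q`` — the factory fraction
  is at target, so the vessel can afford to let stem cells double
  symmetrically, replenishing the stem pool at the cost of a transient dip
  in ``B/N``.

Cells need time to adapt to a light change, so each phase is held for at
least one factory doubling time ``tau_b`` before the threshold is
re-examined.  The controller starts in red.  As escape mutants accumulate,
the red phases eventually become unable to lift ``B/N`` back to ``q``; the
vessel then remains in a terminal red phase and is allowed to finish
producing until the productive populations are effectively extinct
("takeover").

Note the threshold compares *productive* factory cells B only (mutant
factory cells make no product) against the total population N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    EXTINCTION_FLOOR,
    DEFAULT_RTOL,
    SAMPLE_DT,
    Trajectory,
    make_rhs,
    solve_segment,
    _clamp_small_negatives,
    _sample_times,
)
from .rates import ParameterError, RateSet, VesselParams

__all__ = [
    "LightSchedule",
    "run_switched",
    "simulate",
    "takeover_time",
    "DEFAULT_TAKEOVER_EPSILON",
    "DEFAULT_HORIZON_GENERATIONS",
]

logger = logging.getLogger(__name__)

#: production is over when the productive fraction (B+A)/N drops below this
DEFAULT_TAKEOVER_EPSILON = 1e-3
#: hard cap on run length, in factory generations (tau_b units)
DEFAULT_HORIZON_GENERATIONS = 200.0

SWITCHED_SCENARIOS = {"red_green": "green", "red_green_star": "green_star"}
SINGLE_SCENARIOS = ("base", "red", "green", "green_star")


@dataclass
class LightSchedule:
    """Ordered light phases of one switched run.

    ``phases`` is a list of ``(start, end, label)`` tuples in internal time
    units (mutant doubling times) that tile the simulated interval without
    gaps.  ``terminal_red_start`` is the start of the final red phase in
    which the threshold was never re-attained (None if the run ended while
    still cycling, e.g. a mutation-free control).
    """

    phases: list[tuple[float, float, str]] = field(default_factory=list)
    terminal_red_start: float | None = None

    def validate(self, min_dwell: float) -> None:
        for (t0, t1, _), (s0, _, _) in zip(self.phases, self.phases[1:]):
            if not np.isclose(t1, s0):
                raise ParameterError("schedule phases must tile the interval")
        # every phase except the last satisfies the minimum dwell
        for t0, t1, _ in self.phases[:-1]:
            if t1 - t0 < min_dwell * (1 - 1e-9):
                raise ParameterError("non-terminal phase shorter than the minimum dwell")

    def phase_at(self, t: float) -> str:
        for t0, t1, label in self.phases:
            if t0 <= t <= t1:
                return label
        raise ParameterError(f"time {t} outside the scheduled interval")

    def to_records(self) -> list[dict]:
        return [
            {"start": t0, "end": t1, "phase": label} for t0, t1, label in self.phases
        ]


def _takeover_event(epsilon: float):
    def ev(t, y):
        return (y[0] + y[2]) - epsilon * (y[0] + y[1] + y[2] + y[3])

    ev.terminal = True
    ev.direction = -1
    return ev


def _washout_event(K: float):
    def ev(t, y):
        return (y[0] + y[1] + y[2] + y[3]) - EXTINCTION_FLOOR * K

    ev.terminal = True
    ev.direction = -1
    return ev


def _threshold_event(q: float, direction: int):
    """Crossing of B - q N; +1 detects recovery to q, -1 the drop below."""

    def ev(t, y):
        return y[0] - q * (y[0] + y[1] + y[2] + y[3])

    ev.terminal = True
    ev.direction = direction
    return ev


def _segment_to_traj(sol, t0, t1, phase, params, sample_dt, rtol):
    ts = _sample_times(t0, t1, sample_dt)
    ys = sol.sol(ts)
    clamp_tol = 10 * rtol * params.K + 1e-10 * params.K
    states = np.stack(
        [_clamp_small_negatives(ys[:4, i], clamp_tol, ts[i]) for i in range(len(ts))]
    )
    return Trajectory(
        times=ts,
        states=states,
        phases=np.full(len(ts), phase, dtype=object),
        params=params,
        harvest=ys[4],
    )


def run_switched(
    params: VesselParams,
    scenario: str = "red_green",
    horizon: float = DEFAULT_HORIZON_GENERATIONS,
    *,
    epsilon: float = DEFAULT_TAKEOVER_EPSILON,
    rtol: float = DEFAULT_RTOL,
    sample_dt: float = SAMPLE_DT,
) -> tuple[Trajectory, LightSchedule]:
    """Run a red-green or red-green-star light-cycled simulation.

    Parameters
    ----------
    params:
        Vessel parameters; the run starts from ``params.initial_state``.
    scenario:
        ``"red_green"`` (stems regenerate from both stem doubling and
        factory conversion under green light) or ``"red_green_star"``
        (factory cells stay committed under green light).
    horizon:
        Hard cap on run length in factory generations (tau_b units).
    epsilon:
        Takeover threshold on the productive fraction (B+A)/N.

    Returns
    -------
    (trajectory, schedule):
        The stitched :class:`Trajectory` (internal time units, cumulative
        harvest integral included) and the :class:`LightSchedule`.

    The run ends at mutant takeover, complete washout, or the horizon,
    whichever comes first.
    """
    if scenario not in SWITCHED_SCENARIOS:
        raise ParameterError(
            f"unknown switched scenario {scenario!r}; expected one of "
            f"{sorted(SWITCHED_SCENARIOS)}"
        )
    green_label = SWITCHED_SCENARIOS[scenario]
    rates = RateSet.from_params(params)
    dwell = rates.ratio  # one factory doubling time, internal units
    H = horizon * rates.ratio
    if H <= dwell:
        raise ParameterError("horizon must exceed one factory doubling time")

    m, K, q = rates.m_internal, params.K, params.q
    rhs = {
        lbl: make_rhs(lbl, rates, m, K, quadrature=True)
        for lbl in ("red", green_label)
    }
    take, wash = _takeover_event(epsilon), _washout_event(K)

    y = np.append(np.asarray(params.initial_state, dtype=float), 0.0)
    t = 0.0
    phase = "red"
    pieces: list[Trajectory] = []
    schedule = LightSchedule()
    terminal = False

    def frac(yv) -> float:
        n = yv[:4].sum()
        return yv[0] / n if n > EXTINCTION_FLOOR * K else 0.0

    while t < H:
        t_phase_start = t
        # minimum dwell: threshold ignored, takeover/washout still honoured
        sol = solve_segment(
            rhs[phase], y, (t, min(t + dwell, H)), events=[take, wash], rtol=rtol, K=K
        )
        t_end = sol.t[-1]
        pieces.append(
            _segment_to_traj(sol, t, t_end, phase, params, sample_dt, rtol)
        )
        y = sol.y[:, -1]
        t = t_end
        ended = sol.status == 1 or t >= H * (1 - 1e-12)
        if not ended:
            f = frac(y)
            wants_switch = (f >= q) if phase == "red" else (f < q)
            if not wants_switch:
                # hold the phase until the threshold crossing (or the end)
                direction = +1 if phase == "red" else -1
                sol = solve_segment(
                    rhs[phase],
                    y,
                    (t, H),
                    events=[take, wash, _threshold_event(q, direction)],
                    rtol=rtol,
                    K=K,
                )
                t_end = sol.t[-1]
                pieces.append(
                    _segment_to_traj(sol, t, t_end, phase, params, sample_dt, rtol)
                )
                y = sol.y[:, -1]
                t = t_end
                crossed = len(sol.t_events[2]) > 0
                ended = not crossed
        schedule.phases.append((t_phase_start, t, phase))
        if ended:
            # a red phase that never re-attained q is the terminal red phase
            if phase == "red":
                terminal = True
                schedule.terminal_red_start = t_phase_start
            break
        logger.info(
            "t=%.3f switching %s -> %s (B/N=%.4f)",
            t,
            phase,
            "red" if phase != "red" else green_label,
            frac(y),
        )
        phase = green_label if phase == "red" else "red"

    traj = Trajectory.concatenate(pieces)
    logger.info(
        "%s finished at t=%.2f (%.1f generations)%s",
        scenario,
        t,
        t / rates.ratio,
        " in terminal red" if terminal else "",
    )
    return traj, schedule


def simulate(
    params: VesselParams,
    scenario: str = "base",
    horizon: float = DEFAULT_HORIZON_GENERATIONS,
    *,
    epsilon: float = DEFAULT_TAKEOVER_EPSILON,
    rtol: float = DEFAULT_RTOL,
    sample_dt: float = SAMPLE_DT,
) -> tuple[Trajectory, LightSchedule]:
    """Simulate any scenario to takeover, washout or the horizon.

    Single-phase scenarios (``base``, ``red``, ``green``, ``green_star``)
    run under one light condition for the whole span; the switched
    scenarios delegate to :func:`run_switched`.
    """
    if scenario in SWITCHED_SCENARIOS:
        return run_switched(
            params, scenario, horizon, epsilon=epsilon, rtol=rtol, sample_dt=sample_dt
        )
    if scenario not in SINGLE_SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}")
    rates = RateSet.from_params(params)
    H = horizon * rates.ratio
    rhs = make_rhs(scenario, rates, rates.m_internal, params.K, quadrature=True)
    y0 = np.append(np.asarray(params.initial_state, dtype=float), 0.0)
    sol = solve_segment(
        rhs,
        y0,
        (0.0, H),
        events=[_takeover_event(epsilon), _washout_event(params.K)],
        rtol=rtol,
        K=params.K,
    )
    label = scenario if scenario != "base" else "none"
    traj = _segment_to_traj(sol, 0.0, sol.t[-1], label, params, sample_dt, rtol)
    schedule = LightSchedule(phases=[(0.0, sol.t[-1], label)])
    return traj, schedule


def takeover_time(
    traj: Trajectory, epsilon: float = DEFAULT_TAKEOVER_EPSILON
) -> float:
    """First time the productive fraction (B+A)/N drops below ``epsilon``.

    Complete washout (N below the extinction floor) also counts as
    takeover, since production has ended either way.  Returns the final
    trajectory time if the productive fraction never collapses.
    """
    if len(traj.times) == 0:
        raise ParameterError("takeover_time requires a non-empty trajectory")
    below = traj.productive_fraction < epsilon
    if not below.any():
        return float(traj.times[-1])
    return float(traj.times[int(np.argmax(below))])
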