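"""Harvested-yield index, scenario comparisons and parameter sweeps.

The figure of merit for a production run is the cumulative harvested
factory yield

    B_Har = integral of m * B(t)/N(t) dt

over the whole run — the outflow volume (in vessel volumes) weighted by
the fraction of it that is productive factory cells.  B_Har is invariant
under time rescaling, so it can be computed on the internal clock and
reported directly.

Scenarios are compared by the percent change of B_Har against the
conventional-culture base model, and surfaces of that index are swept
over the cell-division ratio (tau_b/tau_b*) and the harvest rate m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .controller import (
    DEFAULT_HORIZON_GENERATIONS,
    DEFAULT_TAKEOVER_EPSILON,
    simulate,
)
from .dynamics import EXTINCTION_FLOOR, Trajectory
from .rates import ParameterError, VesselParams

__all__ = [
    "YieldResult",
    "SweepSurface",
    "harvest_index",
    "percent_change",
    "compare",
    "sweep",
    "UndefinedComparisonError",
]

logger = logging.getLogger(__name__)

MIST_SCENARIOS = ("red_green", "red_green_star")


class UndefinedComparisonError(ValueError):
    """Percent change against a zero or incompatible base yield."""


@dataclass(frozen=True)
class YieldResult:
    """Cumulative harvested factory yield of one run.

    ``b_har`` is in vessel-volume equivalents (>= 0, and bounded by
    m x simulated generations since B/N <= 1); ``n_generations`` is the
    simulated span in factory doubling times.
    """

    b_har: float
    n_generations: float
    scenario: str
    params: VesselParams | None = None


def _infer_scenario(traj: Trajectory) -> str:
    labels = set(traj.phases)
    if "green" in labels:
        return "red_green"
    if "green_star" in labels:
        return "red_green_star"
    if labels == {"none"}:
        return "base"
    (only,) = labels
    return only


def harvest_index(
    traj: Trajectory,
    m: float | None = None,
    *,
    method: str = "auto",
    normalize: str = "total",
) -> YieldResult:
    """Compute B_Har over a trajectory.

    Parameters
    ----------
    traj:
        Trajectory to integrate over.  If it carries the ODE quadrature
        state (``traj.harvest``), that integrator-native value is used
        unless ``method="trapezoid"`` forces re-integration of the sampled
        fractions.
    m:
        Harvest rate per unit of ``traj.times``.  Defaults to the
        trajectory's own parameters (in which case the quadrature state is
        directly usable).
    method:
        ``"auto"`` (quadrature state when available), ``"quadrature"``,
        or ``"trapezoid"``.
    normalize:
        ``"total"`` — the standard index, fraction B/N of the outflow;
        ``"capacity"`` — B/K instead, i.e. absolute harvested cells per
        vessel volume.  The two coincide when the vessel runs near
        capacity; they differ markedly in washout regimes.
    """
    if len(traj.times) == 0:
        raise ParameterError("harvest_index requires a non-empty trajectory")
    if normalize not in ("total", "capacity"):
        raise ParameterError(f"unknown normalization {normalize!r}")
    if m is not None and m < 0:
        raise ParameterError("harvest rate must be non-negative")

    scenario = _infer_scenario(traj)
    n_gen = float(traj.generations[-1] - traj.generations[0])

    if m is None:
        if traj.params is None:
            raise ParameterError("no harvest rate: pass m or attach params")
        m_internal = traj.params.m / traj.params.ratio
    else:
        m_internal = m

    use_quad = (
        normalize == "total"
        and traj.harvest is not None
        and m is None
        and method in ("auto", "quadrature")
    )
    if method == "quadrature" and not use_quad:
        raise ParameterError(
            "quadrature method requires a params-attached trajectory with a "
            "harvest state and the default normalization"
        )
    if use_quad:
        b_har = float(traj.harvest[-1] - traj.harvest[0])
    else:
        if normalize == "total":
            frac = traj.factory_fraction
        else:
            K = traj.params.K if traj.params is not None else 1.0
            frac = traj.B / K
        b_har = float(np.trapezoid(m_internal * frac, traj.times))
    return YieldResult(
        b_har=b_har, n_generations=n_gen, scenario=scenario, params=traj.params
    )


_SHARED_FIELDS = ("p", "K", "q", "m")


def percent_change(scenario_yield: YieldResult, base_yield: YieldResult) -> float:
    """Percent change of a scenario's B_Har against the base model's.

    Both runs must share the physical parameter set (p, K, q, m and the
    division ratio); initial compositions may differ (the base comparison
    run starts all-factory).
    """
    if base_yield.b_har <= 0:
        raise UndefinedComparisonError("base yield is zero; percent change undefined")
    sp, bp = scenario_yield.params, base_yield.params
    if sp is not None and bp is not None:
        mismatched = [
            f for f in _SHARED_FIELDS if not np.isclose(getattr(sp, f), getattr(bp, f))
        ]
        if not np.isclose(sp.ratio, bp.ratio):
            mismatched.append("ratio")
        if mismatched:
            raise UndefinedComparisonError(
                f"runs are not comparable; differing parameters: {mismatched}"
            )
    return 100.0 * (scenario_yield.b_har - base_yield.b_har) / base_yield.b_har


def _base_params(params: VesselParams) -> VesselParams:
    """The matched conventional-culture control: vessel full of factory cells."""
    return replace(
        params, init_B=params.K, init_Bstar=0.0, init_A=0.0, init_Astar=0.0
    )


def compare(
    params: VesselParams,
    scenarios: tuple[str, ...] = MIST_SCENARIOS,
    horizon: float = DEFAULT_HORIZON_GENERATIONS,
    *,
    epsilon: float = DEFAULT_TAKEOVER_EPSILON,
) -> dict:
    """Run base plus the requested MiST scenarios and compare yields.

    Returns a dict with per-scenario :class:`YieldResult`s and percent
    changes vs base; every run continues to mutant takeover (or the
    horizon cap).
    """
    base_traj, _ = simulate(_base_params(params), "base", horizon, epsilon=epsilon)
    yields = {"base": harvest_index(base_traj)}
    deltas: dict[str, float] = {}
    for sc in scenarios:
        traj, _ = simulate(params, sc, horizon, epsilon=epsilon)
        yields[sc] = harvest_index(traj)
        deltas[sc] = percent_change(yields[sc], yields["base"])
    return {"yields": yields, "deltas": deltas}


@dataclass
class SweepSurface:
    """Grid of yields and percent changes over (division ratio, harvest rate).

    ``yields[scenario][i, j]`` is B_Har at ``ratios[i]``,
    ``harvest_rates[j]``; ``delta[scenario]`` the percent change vs
    ``base_yields``.  Failed grid points are NaN.
    """

    ratios: np.ndarray
    harvest_rates: np.ndarray
    base_yields: np.ndarray
    yields: dict[str, np.ndarray]
    delta: dict[str, np.ndarray]

    def best_delta(self) -> np.ndarray:
        """Elementwise percent change of the better MiST variant."""
        return np.nanmax(np.stack(list(self.delta.values())), axis=0)

    def max_improvement(self) -> float:
        """Largest percent improvement of the better variant over the grid."""
        return float(np.nanmax(self.best_delta()))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: ratio, m, scenario, b_har, delta_pct."""
        rows = []
        for i, r in enumerate(self.ratios):
            for j, m in enumerate(self.harvest_rates):
                rows.append(
                    {
                        "ratio": r,
                        "m": m,
                        "scenario": "base",
                        "b_har": self.base_yields[i, j],
                        "delta_pct": 0.0,
                    }
                )
                for sc in self.yields:
                    rows.append(
                        {
                            "ratio": r,
                            "m": m,
                            "scenario": sc,
                            "b_har": self.yields[sc][i, j],
                            "delta_pct": self.delta[sc][i, j],
                        }
                    )
        return pd.DataFrame(rows)


def sweep(
    params_template: VesselParams | None = None,
    ratios=None,
    harvest_rates=None,
    scenarios: tuple[str, ...] = MIST_SCENARIOS,
    horizon: float = DEFAULT_HORIZON_GENERATIONS,
    *,
    epsilon: float = DEFAULT_TAKEOVER_EPSILON,
    sample_dt: float = 0.05,
) -> SweepSurface:
    """Sweep B_Har and its percent change over a (ratio, m) grid.

    Each grid point is independent: the template's tau_b is set to
    ratio x tau_b_star and m to the grid value, then base and the
    requested scenarios run to takeover (capped at ``horizon``
    generations).  Individual failures are logged and recorded as NaN.

    Defaults reproduce the standard sensitivity grid: ratios 1..10,
    m 0.1..0.9.
    """
    if params_template is None:
        params_template = VesselParams()
    ratios = np.asarray(
        [float(r) for r in (ratios if ratios is not None else range(1, 11))]
    )
    harvest_rates = np.asarray(
        list(harvest_rates) if harvest_rates is not None else np.arange(0.1, 0.91, 0.1)
    )
    if ratios.size == 0 or harvest_rates.size == 0:
        raise ParameterError("sweep grids must be non-empty")

    shape = (len(ratios), len(harvest_rates))
    base_y = np.full(shape, np.nan)
    yields = {sc: np.full(shape, np.nan) for sc in scenarios}
    delta = {sc: np.full(shape, np.nan) for sc in scenarios}

    for i, ratio in enumerate(ratios):
        for j, m in enumerate(harvest_rates):
            pt = replace(
                params_template,
                tau_b=ratio * params_template.tau_b_star,
                m=float(m),
            )
            try:
                base_traj, _ = simulate(
                    _base_params(pt), "base", horizon, epsilon=epsilon,
                    sample_dt=sample_dt,
                )
                yb = harvest_index(base_traj)
                base_y[i, j] = yb.b_har
                for sc in scenarios:
                    traj, _ = simulate(
                        pt, sc, horizon, epsilon=epsilon, sample_dt=sample_dt
                    )
                    ys = harvest_index(traj)
                    yields[sc][i, j] = ys.b_har
                    delta[sc][i, j] = percent_change(ys, yb)
            except Exception:  # noqa: BLE001 - per-point isolation is the contract
                logger.warning(
                    "sweep point ratio=%g m=%g failed", ratio, m, exc_info=True
                )
    return SweepSurface(
        ratios=ratios,
        harvest_rates=harvest_rates,
        base_yields=base_y,
        yields=yields,
        delta=delta,
    )
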