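"""Vessel parameters and closed-form rate constants for the MiST model family.

Every intrinsic growth and conversion rate in the four scenarios (base,
red light, green light, green light star) is derived in closed form from
three biological inputs:

* ``tau_b`` — doubling time of product-producing factory cells (B), slowed
  by biosynthetic burden;
* ``tau_b_star`` — doubling time of escape mutants (B*), stem cells (A) and
  mutant stem cells (A*), which carry no burden;
* ``p`` — probability that any one daughter cell of a division is a mutant.

The derivations all follow the same template: solve the linear (dilute,
closed-vessel) system over one doubling time and match the endpoint to the
daughter-cell bookkeeping of the division diagram.  E.g. a factory cell
produces on average ``2(1-p)`` factory and ``2p`` mutant daughters per
``tau_b``, giving ``r_b = ln(2(1-p))/tau_b`` and the two-exponential
matching condition for the mutation gain rate ``c_b``.

Rates are expressed per unit of whatever time unit the ``tau`` arguments
are given in.  :class:`RateSet` holds the internally normalised set
(``tau_b_star = 1``), which the dynamics and controller modules use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "VesselParams",
    "BaseRates",
    "RedRates",
    "GreenRates",
    "GreenStarRates",
    "RateSet",
    "derive_base_rates",
    "derive_red_rates",
    "derive_green_rates",
    "derive_green_star_rates",
]


class ParameterError(ValueError):
    """Raised for physically inadmissible vessel parameters."""


def _check_times_p(tau_b: float, tau_b_star: float, p: float) -> None:
    if not (tau_b > 0 and tau_b_star > 0):
        raise ParameterError(
            f"doubling times must be positive, got tau_b={tau_b}, tau_b_star={tau_b_star}"
        )
    if not (0.0 <= p < 1.0):
        raise ParameterError(f"mutation probability must lie in [0, 1), got p={p}")


def _exp_ratio(r1: float, r2: float, tau: float) -> float:
    """(r1 - r2) / (exp(r1*tau) - exp(r2*tau)), with the analytic limit at r1 == r2.

    The limit as r2 -> r1 is 1 / (tau * exp(r1*tau)); used so that mutation
    gain rates degrade gracefully when the two exponents coincide (e.g. the
    p = 0 mutation-free control with tau_b == tau_b_star).
    """
    d = r1 - r2
    # relative spacing below ~1e-9 loses all precision in the subtraction
    scale = max(abs(r1), abs(r2), 1.0)
    if abs(d) < 1e-9 * scale:
        return math.exp(-r1 * tau) / tau
    return d / (math.exp(r1 * tau) - math.exp(r2 * tau))


@dataclass(frozen=True)
class VesselParams:
    """User-facing physical and biological parameters of one bioreactor run.

    Attributes
    ----------
    K:
        Carrying capacity of the vessel (cell count; the model is
        scale-free in K, so K = 1.0 is a fine default).
    m:
        Continuous dilution/harvest rate, in vessel volumes per **factory**
        doubling time ``tau_b`` (i.e. per generation, the unit all
        simulated time courses are reported in).
    p:
        Per-daughter mutation probability, ``0 <= p < 1``.
    tau_b, tau_b_star:
        Doubling times of factory cells and of mutants/stem cells.  Their
        ratio ``tau_b / tau_b_star`` is the cell-division ratio, a proxy
        for biosynthetic burden; ``tau_b >= tau_b_star`` is required.
    q:
        Factory-fraction threshold for red/green light switching,
        ``0 < q < 1``.
    init_B, init_Bstar, init_A, init_Astar:
        Initial populations.  Defaults start the vessel full at the target
        composition: 90% factory cells, 10% stem cells.
    """

    K: float = 1.0
    m: float = 0.2
    p: float = 1e-6
    tau_b: float = 5.0
    tau_b_star: float = 1.0
    q: float = 0.9
    init_B: float = field(default=-1.0)  # -1 sentinel -> 0.9 K
    init_Bstar: float = 0.0
    init_A: float = field(default=-1.0)  # -1 sentinel -> 0.1 K
    init_Astar: float = 0.0

    def __post_init__(self) -> None:
        if self.init_B < 0:
            object.__setattr__(self, "init_B", 0.9 * self.K)
        if self.init_A < 0:
            object.__setattr__(self, "init_A", 0.1 * self.K)
        if self.K <= 0:
            raise ParameterError(f"carrying capacity must be positive, got K={self.K}")
        _check_times_p(self.tau_b, self.tau_b_star, self.p)
        if self.tau_b < self.tau_b_star:
            raise ParameterError(
                "factory cells divide no faster than mutants: require tau_b >= tau_b_star"
            )
        if self.m < 0:
            raise ParameterError(f"dilution rate must be non-negative, got m={self.m}")
        if not (0.0 < self.q < 1.0):
            raise ParameterError(f"switching threshold must lie in (0, 1), got q={self.q}")
        inits = (self.init_B, self.init_Bstar, self.init_A, self.init_Astar)
        if any(x < 0 for x in inits):
            raise ParameterError("initial populations must be non-negative")
        if sum(inits) > self.K * (1 + 1e-12):
            raise ParameterError("initial populations exceed the carrying capacity K")

    @property
    def ratio(self) -> float:
        """Cell-division ratio tau_b / tau_b_star."""
        return self.tau_b / self.tau_b_star

    @property
    def initial_state(self) -> tuple[float, float, float, float]:
        return (self.init_B, self.init_Bstar, self.init_A, self.init_Astar)


@dataclass(frozen=True)
class BaseRates:
    """Rates of the conventional-culture (base) model.

    ``r_b``: factory intrinsic growth rate; ``r_b_star``: mutant-factory
    intrinsic growth rate; ``c_b``: mutant-factory gain rate fed by factory
    cell mutation.
    """

    r_b: float
    r_b_star: float
    c_b: float


@dataclass(frozen=True)
class RedRates:
    """Rates specific to the red-light (production) scenario.

    Under red light a stem cell divides asymmetrically into one stem and one
    factory daughter, so the stem pool is conserved up to mutation losses
    (``r_a = ln(1-p)/tau_b_star <= 0``) while the factory pool gains
    ``c_ab`` per stem cell.  A mutant stem cell likewise yields one mutant
    factory cell per division (``c_ab_2star = r_b_star``).
    """

    r_a: float
    r_a_star: float
    c_ab: float
    c_ab_star: float
    c_ab_2star: float


@dataclass(frozen=True)
class GreenRates:
    """Rates of the green-light (regeneration) scenario.

    Under green light stem cells divide symmetrically (stem pool doubles
    per ``tau_b_star``) and factory cells divide asymmetrically at their
    own slow rate, each division handing one stem daughter to the A pool
    (``c_bag``, exponents over ``tau_b``).
    """

    r_bg: float
    c_bg_star: float
    r_ag: float
    c_bag: float
    r_ag_star: float
    c_ag: float
    c_bag_star: float
    c_bag_2star: float


@dataclass(frozen=True)
class GreenStarRates:
    """Rates of the green-light-star scenario.

    Stem cells behave as under green light (symmetric division with
    mutation); factory cells remain committed and follow the base-model
    dynamics, so only the three stem-side rates are new.
    """

    r_ags: float
    r_ags_star: float
    c_ags: float


def derive_base_rates(tau_b: float, tau_b_star: float, p: float) -> BaseRates:
    """Derive the base-model rates from doubling times and mutation probability.

    ``r_b = ln(2(1-p))/tau_b`` (a factory cell leaves ``2(1-p)`` factory
    daughters per doubling), ``r_b_star = ln(2)/tau_b_star``, and ``c_b``
    matches ``B*(tau_b) = 2p`` from a unit factory seed in the dilute limit.
    """
    _check_times_p(tau_b, tau_b_star, p)
    r_b = math.log(2.0 * (1.0 - p)) / tau_b
    r_b_star = math.log(2.0) / tau_b_star
    c_b = 2.0 * p * _exp_ratio(r_b_star, r_b, tau_b)
    return BaseRates(r_b=r_b, r_b_star=r_b_star, c_b=c_b)


def derive_red_rates(
    base: BaseRates, tau_b: float, tau_b_star: float, p: float
) -> RedRates:
    """Derive the red-light rates.

    ``r_a = ln(1-p)/tau_b_star`` (one stem cell leaves ``1-p`` stem
    daughters), ``r_a_star = -r_a`` and ``c_ab_star = -r_a`` (mutant stem
    and mutant factory gains from stem division are equal),
    ``c_ab_2star = r_b_star``, and ``c_ab`` matches
    ``B_r(tau_b_star) = (1-p)`` from a unit stem seed.
    """
    _check_times_p(tau_b, tau_b_star, p)
    r_a = math.log(1.0 - p) / tau_b_star
    c_ab = (1.0 - p) * _exp_ratio(base.r_b, r_a, tau_b_star)
    return RedRates(
        r_a=r_a,
        r_a_star=-r_a,
        c_ab=c_ab,
        c_ab_star=-r_a,
        c_ab_2star=base.r_b_star,
    )


def derive_green_rates(tau_b: float, tau_b_star: float, p: float) -> GreenRates:
    """Derive the green-light rates.

    Factory cells divide asymmetrically at their slow clock: the factory
    count is conserved up to mutation (``r_bg = ln(1-p)/tau_b <= 0``) and
    each factory cell delivers one stem daughter per ``tau_b``
    (``c_bag``; the matching exponents run over ``tau_b``).  Stem cells
    divide symmetrically: ``r_ag = ln(2(1-p))/tau_b_star``, with mutation
    spill-over ``c_ag`` into the mutant stem pool.
    """
    _check_times_p(tau_b, tau_b_star, p)
    r_bg = math.log(1.0 - p) / tau_b
    r_ag = math.log(2.0 * (1.0 - p)) / tau_b_star
    r_ag_star = math.log(2.0) / tau_b_star
    c_bag = (1.0 - p) * _exp_ratio(r_bg, r_ag, tau_b)
    c_ag = 2.0 * p * _exp_ratio(r_ag_star, r_ag, tau_b_star)
    return GreenRates(
        r_bg=r_bg,
        c_bg_star=-r_bg,
        r_ag=r_ag,
        c_bag=c_bag,
        r_ag_star=r_ag_star,
        c_ag=c_ag,
        c_bag_star=-r_bg,
        c_bag_2star=r_ag_star,
    )


def derive_green_star_rates(
    base: BaseRates, tau_b_star: float, p: float
) -> GreenStarRates:
    """Derive the green-light-star stem rates.

    Stem cells double symmetrically with mutation exactly as factory cells
    do in the base model, but on the fast clock: the formulas are the base
    triple with ``tau_b`` replaced by ``tau_b_star``.
    """
    _check_times_p(tau_b_star, tau_b_star, p)
    r_ags = math.log(2.0 * (1.0 - p)) / tau_b_star
    r_ags_star = math.log(2.0) / tau_b_star
    c_ags = 2.0 * p * _exp_ratio(r_ags_star, r_ags, tau_b_star)
    return GreenStarRates(r_ags=r_ags, r_ags_star=r_ags_star, c_ags=c_ags)


@dataclass(frozen=True)
class RateSet:
    """All scenario rates for one vessel, in internal units (tau_b_star = 1).

    The simulator normalises time so that one mutant doubling time is one
    time unit; the cell-division ratio then equals ``tau_b`` internally.
    The user-facing dilution rate ``m`` (per factory doubling) is rescaled
    to ``m_internal = m / ratio`` accordingly.
    """

    base: BaseRates
    red: RedRates
    green: GreenRates
    green_star: GreenStarRates
    ratio: float
    m_internal: float
    p: float

    @classmethod
    def from_params(cls, params: VesselParams) -> "RateSet":
        ratio = params.ratio
        base = derive_base_rates(ratio, 1.0, params.p)
        return cls(
            base=base,
            red=derive_red_rates(base, ratio, 1.0, params.p),
            green=derive_green_rates(ratio, 1.0, params.p),
            green_star=derive_green_star_rates(base, 1.0, params.p),
            ratio=ratio,
            m_internal=params.m / ratio,
            p=params.p,
        )

    def as_dict(self) -> dict[str, float]:
        """Flat name -> value map, for the JSON run summary."""
        out: dict[str, float] = {}
        for prefix, rates in (
            ("base", self.base),
            ("red", self.red),
            ("green", self.green),
            ("green_star", self.green_star),
        ):
            for name, value in vars(rates).items():
                out[f"{prefix}.{name}"] = value
        return out
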