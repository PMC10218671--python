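"""Three-state Markov cohort model for leg-ulcer management.

States: *active ulcer*, *healed ulcer*, *recurred ulcer*.  The cohort
starts fully active; a fraction ``p_healed`` of the initial cohort heals at
the strategy's mean healing time (a tunnel transition, optionally a
constant hazard), healed ulcers recur with a constant per-cycle probability
calibrated so that cumulative recurrence over the horizon matches the
strategy's recurrence proportion, and a recurred ulcer behaves like a fresh
conservatively-managed ulcer: the conservative-care healing fraction of
recurrences re-heals with a constant per-cycle probability whose mean
equals the conservative-care healing time, the remainder stays recurred.
(Internally the recurred state is therefore split into healable and chronic
sub-states; they share utility and costs and are reported as one state.)

Cycles are monthly; QALYs accrue as annual utility weights / 12 per cycle
and both QALYs and costs are discounted at the compound monthly equivalent
of the annual rate.  Costs per cycle: procedure cost at cycle 0 (stenting),
first outpatient visit at cycle 1 (conservative arm — the procedure
admission already covers the first contact of the stenting arm), a monthly
management cost on active + recurred occupancy, and a one-off healing-phase
cost on every healing event, including re-healing after recurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CohortTrace",
    "ModelConfig",
    "StrategyParams",
    "TransitionSchedule",
    "UtilitySet",
    "build_schedule",
    "mean_outcomes",
    "monthly_discount_rate",
    "run_cohort",
    "run_strategy",
]


@dataclass
class StrategyParams:
    """Clinical and cost inputs of one treatment arm.

    Proportions are cumulative over the horizon and refer to the initial
    cohort; ``t_heal`` is the mean healing time in months (fractional
    values are supported — a fractional tunnel splits the healing flow
    between the two adjacent cycles so the mean time is honoured exactly).
    ``p_reheal`` / ``t_reheal`` govern the conservative re-management of
    recurred ulcers and default to the conservative-care base case.
    ``procedure_cost`` should already include the expected re-intervention
    cost (see :func:`tdabc_cea.tdabc.expected_cost_with_reintervention`).
    """

    name: str
    p_healed: float
    t_heal: float
    p_recur: float
    first_visit_cost: float
    monthly_active_cost: float
    healing_event_cost: float
    procedure_cost: float = 0.0
    p_reintervention: float = 0.0
    p_reheal: float = 0.61
    t_reheal: float = 3.0

    def __post_init__(self) -> None:
        for name in ("p_healed", "p_recur", "p_reintervention", "p_reheal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.t_heal < 1.0 or self.t_reheal < 1.0:
            raise ValueError("healing times must be >= 1 month")
        for name in ("first_visit_cost", "monthly_active_cost", "healing_event_cost", "procedure_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class UtilitySet:
    """Annual utility weights of the three health states."""

    u_healed: float = 1.0
    u_active: float = 0.73
    u_recurred: float = 0.64

    def __post_init__(self) -> None:
        for name in ("u_healed", "u_active", "u_recurred"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ModelConfig:
    horizon: int = 36  # monthly cycles
    discount_annual: float = 0.03
    perspective: Literal["hospital", "societal"] = "hospital"
    healing_model: Literal["tunnel", "constant_hazard"] = "tunnel"
    discount_conversion: Literal["compound", "simple"] = "compound"

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 cycle")
        if self.discount_annual < 0:
            raise ValueError("discount rate must be >= 0")


def monthly_discount_rate(cfg: ModelConfig) -> float:
    """Monthly discount rate equivalent to the annual one.

    Compound conversion ``(1+d)^(1/12)-1`` by default; the simple ``d/12``
    alternative differs by <0.02% over 36 months.
    """
    if cfg.discount_conversion == "simple":
        return cfg.discount_annual / 12.0
    return (1.0 + cfg.discount_annual) ** (1.0 / 12.0) - 1.0


@dataclass
class TransitionSchedule:
    """Per-cycle transition rule for one arm.

    ``heal_flow[t]`` is the fraction of the *initial* cohort that moves
    active -> healed at the end of cycle t (tunnel mode); in constant-hazard
    mode ``heal_hazard`` is applied to current active occupancy instead.
    ``q_recur`` is the constant healed -> recurred per-cycle probability;
    a fraction ``p_reheal`` of that flow enters the healable recurred
    sub-state, which re-heals with per-cycle probability ``r_reheal``.
    """

    horizon: int
    healing_model: str
    heal_flow: np.ndarray
    heal_hazard: float
    q_recur: float
    p_reheal: float
    r_reheal: float


def _tunnel_flows(p_healed: float, t_heal: float, horizon: int) -> np.ndarray:
    """Split the healing flow over the two cycles bracketing a fractional
    mean healing time, so the mean time equals ``t_heal`` exactly."""
    flows = np.zeros(horizon + 1)
    lo = int(math.floor(t_heal))
    frac = t_heal - lo
    if lo <= horizon:
        flows[lo] += p_healed * (1.0 - frac)
    if frac > 0 and lo + 1 <= horizon:
        flows[lo + 1] += p_healed * frac
    return flows


def _simulate(
    schedule: TransitionSchedule, q_recur: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Propagate the cohort; returns (occupancy[t] = (active, healed,
    recurred) at the start of cycle t for t = 1..horizon, newly-healed
    fraction per cycle, cumulative healed -> recurred flow)."""
    n = schedule.horizon
    occ = np.zeros((n + 1, 3))
    newly_healed = np.zeros(n + 1)
    a, h, rh, rc = 1.0, 0.0, 0.0, 0.0  # active, healed, recurred (healable / chronic)
    cum_recur = 0.0
    for t in range(1, n + 1):
        occ[t] = (a, h, rh + rc)
        if schedule.healing_model == "tunnel":
            a_out = schedule.heal_flow[t]
            if a_out > a + 1e-12:
                raise ValueError(
                    "tunnel healing flow exceeds active occupancy "
                    f"(cycle {t}: flow {a_out:.6f} > active {a:.6f})"
                )
        else:
            a_out = schedule.heal_hazard * a
        h_out = q_recur * h
        r_out = schedule.r_reheal * rh
        newly_healed[t] = a_out + r_out
        cum_recur += h_out
        a -= a_out
        h += a_out + r_out - h_out
        rh += schedule.p_reheal * h_out - r_out
        rc += (1.0 - schedule.p_reheal) * h_out
    return occ, newly_healed, cum_recur


def build_schedule(params: StrategyParams, cfg: ModelConfig) -> TransitionSchedule:
    """Build the per-cycle transition rule for one arm.

    The recurrence probability is calibrated numerically so that cumulative
    healed -> recurred flow over the horizon equals ``p_recur`` of the
    initial cohort.
    """
    if cfg.healing_model == "tunnel":
        heal_flow = _tunnel_flows(params.p_healed, params.t_heal, cfg.horizon)
        heal_hazard = 0.0
    else:
        # constant hazard reaching cumulative p_healed at the mean healing time
        heal_flow = np.zeros(cfg.horizon + 1)
        heal_hazard = 1.0 - (1.0 - params.p_healed) ** (1.0 / params.t_heal)
    schedule = TransitionSchedule(
        horizon=cfg.horizon,
        healing_model=cfg.healing_model,
        heal_flow=heal_flow,
        heal_hazard=heal_hazard,
        q_recur=0.0,
        p_reheal=params.p_reheal,
        r_reheal=1.0 / params.t_reheal,
    )
    if params.p_recur > 0:
        target = params.p_recur

        def gap(q: float) -> float:
            return _simulate(schedule, q)[2] - target

        if gap(1.0) < 0:
            raise ValueError(
                f"recurrence proportion {target} unreachable within the horizon"
            )
        schedule.q_recur = brentq(gap, 0.0, 1.0, xtol=1e-12)
    return schedule


@dataclass
class CohortTrace:
    """State occupancies per cycle with discounted accumulators.

    Row ``t`` of ``occupancy`` (t = 1..horizon) is the distribution over
    (active, healed, recurred) at the start of cycle t; row 0 is the
    initial distribution.  ``disc_qaly``/``disc_cost`` are cumulative
    through each cycle; their last entries are the model outcomes.
    """

    occupancy: np.ndarray
    disc_qaly: np.ndarray
    disc_cost: np.ndarray
    newly_healed: np.ndarray

    @property
    def qalys(self) -> float:
        return float(self.disc_qaly[-1])

    @property
    def cost(self) -> float:
        return float(self.disc_cost[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.occupancy)),
                "active": self.occupancy[:, 0],
                "healed": self.occupancy[:, 1],
                "recurred": self.occupancy[:, 2],
                "disc_qaly": self.disc_qaly,
                "disc_cost": self.disc_cost,
            }
        )


def run_cohort(
    schedule: TransitionSchedule,
    utilities: UtilitySet,
    params: StrategyParams,
    cfg: ModelConfig,
) -> CohortTrace:
    """Propagate the cohort and accumulate discounted QALYs and costs."""
    occ, newly_healed, _ = _simulate(schedule, schedule.q_recur)
    occ[0] = (1.0, 0.0, 0.0)
    d_m = monthly_discount_rate(cfg)
    u = np.array([utilities.u_active, utilities.u_healed, utilities.u_recurred])

    n = schedule.horizon
    disc_qaly = np.zeros(n + 1)
    disc_cost = np.zeros(n + 1)
    disc_cost[0] = params.procedure_cost  # cycle 0, undiscounted
    for t in range(1, n + 1):
        df = (1.0 + d_m) ** (-t)
        disc_qaly[t] = disc_qaly[t - 1] + df * float(occ[t] @ u) / 12.0
        cost_t = params.monthly_active_cost * (occ[t, 0] + occ[t, 2])
        cost_t += params.healing_event_cost * newly_healed[t]
        if t == 1:
            cost_t += params.first_visit_cost
        disc_cost[t] = disc_cost[t - 1] + df * cost_t

    sums = occ[1:].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-12):
        raise AssertionError("cohort occupancy is not conserved")
    return CohortTrace(
        occupancy=occ, disc_qaly=disc_qaly, disc_cost=disc_cost, newly_healed=newly_healed
    )


def mean_outcomes(trace: CohortTrace) -> tuple[float, float]:
    """Final discounted (QALYs, cost) of a completed trace."""
    return trace.qalys, trace.cost


def run_strategy(
    params: StrategyParams, utilities: UtilitySet, cfg: ModelConfig
) -> CohortTrace:
    """Convenience wrapper: build the schedule and run the cohort."""
    return run_cohort(build_schedule(params, cfg), utilities, params, cfg)
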