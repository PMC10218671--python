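"""Time-driven activity-based costing (TDABC) for care pathways.

TDABC prices a care cycle by walking its process map: every step consumes
minutes of one resource (nurse, surgeon, ward staff, ...) priced at that
resource's *capacity cost rate* in EUR per minute, plus directly attributable
goods/services/technology costs and any cost borne out-of-pocket by the
patient.  Rolling the steps up by macro-phase gives the cost profile of the
whole episode of care.

This module provides the step/rate data model, the roll-up into per-phase
breakdowns, and the episode-level arithmetic used downstream by the
cost-utility model: expected procedure cost under a re-intervention risk,
multi-month outpatient episode cost split by payer, and reimbursement-gap
reports against DRG / outpatient tariffs.

All internal sums are kept unrounded; currency is rounded half-up to the
cent only at reporting time (percent shares only reconcile when computed on
unrounded totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "ActivityStep",
    "CostBreakdown",
    "EpisodeCost",
    "EpisodeSpec",
    "PhaseCost",
    "block_share",
    "episode_cost",
    "expected_cost_with_reintervention",
    "load_activity_log",
    "load_rates",
    "outpatient_reimbursement",
    "personnel_cost",
    "reimbursement_gap",
    "roll_up",
    "round_eur",
]


def round_eur(x: float, ndigits: int = 2) -> float:
    """Round a currency amount half-up (0.005 -> 0.01), as ledgers do.

    Python's builtin ``round`` is banker's rounding; accounting tables are
    conventionally half-up, and the difference matters at the cent level.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ActivityStep:
    """One timed, resourced step of a care pathway.

    ``role`` may be empty for steps with no personnel component (e.g. a pure
    consumable line).  ``frequency`` scales minutes and both cost components
    for steps not performed at every occurrence of the phase (e.g. wound
    debridement at 50% of visits).
    """

    macro_phase: str
    step: str
    minutes: float = 0.0
    role: str = ""
    goods_cost: float = 0.0
    patient_cost: float = 0.0
    frequency: float = 1.0

    def __post_init__(self) -> None:
        if self.minutes < 0:
            raise ValueError(f"step {self.step!r}: minutes must be >= 0")
        if self.goods_cost < 0 or self.patient_cost < 0:
            raise ValueError(f"step {self.step!r}: costs must be >= 0")
        if self.frequency < 0:
            raise ValueError(f"step {self.step!r}: frequency must be >= 0")


def personnel_cost(step: ActivityStep, rates: Mapping[str, float]) -> float:
    """Personnel cost of a step: minutes x capacity cost rate of its role.

    Steps without a role cost nothing in personnel terms; an unknown role is
    an error (a silent zero would understate the episode cost).
    """
    if not step.role:
        return 0.0
    if step.role not in rates:
        raise KeyError(f"role {step.role!r} not found in the rate table")
    rate = rates[step.role]
    if rate < 0:
        raise ValueError(f"role {step.role!r}: capacity cost rate must be >= 0")
    return step.minutes * step.frequency * rate


@dataclass
class CostBreakdown:
    """Per-phase and total roll-up of a care-cycle activity log.

    ``per_phase`` is indexed by macro-phase in declared order with columns
    ``minutes, personnel, goods, patient, total``; ``totals`` are the column
    sums; ``shares`` hold whole-percent time and cost shares computed on the
    unrounded values.
    """

    per_phase: pd.DataFrame
    totals: pd.Series
    shares: pd.DataFrame

    def rounded(self) -> pd.DataFrame:
        """Reporting view: currency columns rounded half-up to the cent."""
        out = self.per_phase.copy()
        out.loc["Total"] = self.totals
        for col in ("personnel", "goods", "patient", "total"):
            out[col] = out[col].map(round_eur)
        return out

    def to_table(self) -> pd.DataFrame:
        """Rounded breakdown with whole-percent share columns appended."""
        out = self.rounded()
        out["time_pct"] = list(self.shares["time_pct"]) + [100]
        out["cost_pct"] = list(self.shares["cost_pct"]) + [100]
        return out


def roll_up(
    log: Iterable[ActivityStep],
    rates: Mapping[str, float],
    phase_order: Sequence[str],
) -> CostBreakdown:
    """Aggregate an activity log into a per-phase cost breakdown.

    Every step's phase must appear in ``phase_order`` (reports follow the
    declared pathway ordering, never an inferred one).  An empty log yields
    an all-zero breakdown.
    """
    cols = ["minutes", "personnel", "goods", "patient"]
    acc = pd.DataFrame(0.0, index=list(phase_order), columns=cols)
    for s in log:
        if s.macro_phase not in acc.index:
            raise ValueError(
                f"step {s.step!r} has phase {s.macro_phase!r} outside the declared order"
            )
        acc.loc[s.macro_phase, "minutes"] += s.minutes * s.frequency
        acc.loc[s.macro_phase, "personnel"] += personnel_cost(s, rates)
        acc.loc[s.macro_phase, "goods"] += s.goods_cost * s.frequency
        acc.loc[s.macro_phase, "patient"] += s.patient_cost * s.frequency
    acc["total"] = acc["personnel"] + acc["goods"] + acc["patient"]
    totals = acc.sum(axis=0)
    totals.name = "Total"

    def _pct(col: str, denom: float) -> list[int]:
        if denom == 0:
            return [0] * len(acc)
        return [int(round_eur(100.0 * v / denom, 0)) for v in acc[col]]

    shares = pd.DataFrame(
        {
            "time_pct": _pct("minutes", totals["minutes"]),
            "cost_pct": _pct("total", totals["total"]),
        },
        index=acc.index,
    )
    return CostBreakdown(per_phase=acc, totals=totals, shares=shares)


def block_share(breakdown: CostBreakdown, phases: Sequence[str], kind: str = "cost") -> int:
    """Whole-percent share of a block of phases, as the sum of the phases'
    rounded whole-percent shares (the convention of published TDABC tables,
    where block percentages are read off the printed per-phase column)."""
    col = {"cost": "cost_pct", "time": "time_pct"}[kind]
    return int(breakdown.shares.loc[list(phases), col].sum())


def expected_cost_with_reintervention(base_cost: float, p_reintervention: float) -> float:
    """Expected episode cost when a fraction of cases repeats the procedure.

    A re-intervention is modelled as a full repeat of the procedure cost, so
    the expectation is ``base_cost * (1 + p)``.
    """
    if not 0.0 <= p_reintervention <= 1.0:
        raise ValueError("re-intervention probability must lie in [0, 1]")
    return base_cost * (1.0 + p_reintervention)


@dataclass(frozen=True)
class PhaseCost:
    """One aggregated breakdown row: minutes plus the three cost components."""

    minutes: float = 0.0
    personnel: float = 0.0
    goods: float = 0.0
    patient: float = 0.0

    @property
    def total(self) -> float:
        return self.personnel + self.goods + self.patient

    @property
    def hospital(self) -> float:
        return self.personnel + self.goods


@dataclass(frozen=True)
class EpisodeSpec:
    """Outpatient episode: first visit, a monthly block repeated while the
    ulcer stays active, and a final phase charged on healing."""

    first_visit: PhaseCost
    monthly: PhaseCost
    final_phase: PhaseCost
    months_active: int = 0

    def __post_init__(self) -> None:
        if self.months_active < 0:
            raise ValueError("months_active must be >= 0")


class EpisodeCost(NamedTuple):
    total: float
    hospital: float
    patient: float


def episode_cost(spec: EpisodeSpec) -> EpisodeCost:
    """Total episode cost and its payer split.

    total = first_visit + months_active x monthly + final_phase, with the
    patient-borne component accumulated the same way; hospital = total -
    patient.  Affine in ``months_active`` with slope equal to the monthly
    total.
    """
    m = spec.months_active
    total = spec.first_visit.total + m * spec.monthly.total + spec.final_phase.total
    patient = spec.first_visit.patient + m * spec.monthly.patient + spec.final_phase.patient
    return EpisodeCost(total=total, hospital=total - patient, patient=patient)


def reimbursement_gap(real_cost: float, reimbursement: float) -> float:
    """Signed gap between the real (TDABC) cost and the tariff actually paid;
    positive means the provider is under-reimbursed."""
    if real_cost < 0 or reimbursement < 0:
        raise ValueError("costs and reimbursements must be >= 0")
    return real_cost - reimbursement


def outpatient_reimbursement(n_visits: int, visit_tariff: float, medication_mean: float) -> float:
    """Tariff-side value of an outpatient episode: each visit is reimbursed at
    the visit tariff plus the mean medication tariff."""
    if n_visits < 0 or visit_tariff < 0 or medication_mean < 0:
        raise ValueError("all inputs must be >= 0")
    return n_visits * (visit_tariff + medication_mean)


# ---------------------------------------------------------------------------
# CSV interfaces

LOG_COLUMNS = ["macro_phase", "step", "minutes", "role", "goods_cost", "patient_cost", "frequency"]


def load_activity_log(path: str | Path) -> list[ActivityStep]:
    """Read an activity-log CSV (``frequency`` column optional, default 1)."""
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"activity log is missing columns: {sorted(missing)}")
    if "frequency" not in df.columns:
        df["frequency"] = 1.0
    df["role"] = df["role"].fillna("")
    return [
        ActivityStep(
            macro_phase=str(r.macro_phase),
            step=str(r.step),
            minutes=float(r.minutes),
            role=str(r.role),
            goods_cost=float(r.goods_cost),
            patient_cost=float(r.patient_cost),
            frequency=float(r.frequency),
        )
        for r in df.itertuples()
    ]


def save_activity_log(log: Iterable[ActivityStep], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in log])[LOG_COLUMNS].to_csv(path, index=False)


def load_rates(path: str | Path) -> dict[str, float]:
    """Read a resource-rate CSV with columns ``role,rate_eur_per_min``."""
    df = pd.read_csv(path)
    if not {"role", "rate_eur_per_min"} <= set(df.columns):
        raise ValueError("rate table needs columns role,rate_eur_per_min")
    if df["role"].duplicated().any():
        dupes = df.loc[df["role"].duplicated(), "role"].tolist()
        raise ValueError(f"duplicate roles in rate table: {dupes}")
    return dict(zip(df["role"].astype(str), df["rate_eur_per_min"].astype(float)))


def save_rates(rates: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"role": list(rates), "rate_eur_per_min": list(rates.values())}
    ).to_csv(path, index=False)
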