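"""Synthetic inputs for every stage of the pipeline.

Real activity logs from hospital field observation are not shareable, so
this module generates them: deterministic fixture logs whose noiseless
roll-up reproduces the published per-phase cost profile of the stenting
care cycle and the outpatient ulcer pathway to the cent, lognormally
perturbed per-patient variants (emulating case-mix variability in timings
and consumables), and study-outcome tables with controlled between-study
heterogeneity for exercising the proportion meta-analysis.

All generators are seed-deterministic and the noise is expectation
preserving (lognormal multipliers with unit mean), so sample means converge
to the fixture values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .meta_props import StudyOutcome
from .tdabc import ActivityStep, EpisodeSpec, PhaseCost

__all__ = [
    "STENTING_PHASES",
    "SimConfig",
    "fixture_soc_phases",
    "fixture_stenting_log",
    "fixture_stenting_rates",
    "noisy_logs",
    "simulate_studies",
]

STENTING_PHASES = [
    "1 Patient reception",
    "2 Preliminary assessment",
    "3 Pre-operative hospitalization",
    "4 Preparation for surgery",
    "5 Surgical intervention",
    "6 Surgery closure",
    "7 Post-operative hospitalization",
    "8 Post-operative assessment",
    "9 Discharge",
]

# phase -> (minutes, personnel EUR, goods/services/tech EUR, role).
# Costs carry sub-cent digits: the published table rounds each cell
# independently of its unrounded internals, so the printed per-phase values,
# the per-phase totals AND the grand totals (1220.17 / 3861.82 / 5081.99)
# are only simultaneously reproducible from internals like these — printed
# cells alone sum to one cent less in every currency column.
_STENTING_TABLE: dict[str, tuple[float, float, float, str]] = {
    "1 Patient reception": (21, 13.42, 0.67, "reception_clerk"),
    "2 Preliminary assessment": (127, 185.822, 239.562, "assessment_team"),
    "3 Pre-operative hospitalization": (1161, 106.067, 37.157, "ward_staff_preop"),
    "4 Preparation for surgery": (87, 70.073, 10.483, "or_prep_team"),
    "5 Surgical intervention": (145, 479.672, 3519.512, "surgical_team"),
    "6 Surgery closure": (80, 92.312, 10.852, "or_closure_team"),
    "7 Post-operative hospitalization": (1255, 144.662, 40.162, "ward_staff_postop"),
    "8 Post-operative assessment": (35, 50.87, 1.12, "assessment_team_postop"),
    "9 Discharge": (72, 77.273, 2.303, "discharge_clerk"),
}

# itemized goods inside the surgical phase: 1.5 stents at EUR 1420 each and
# intravascular ultrasound at 18% of total goods cost (2983-minute cycle
# totals EUR 3861.82 in goods), remainder lumped as other consumables
STENT_UNIT_COST = 1420.0
STENTS_PER_PROCEDURE = 1.5
_TOTAL_GOODS = sum(g for _, _, g, _ in _STENTING_TABLE.values())
_IVUS_COST = round(0.18 * _TOTAL_GOODS, 2)


def fixture_stenting_log() -> list[ActivityStep]:
    """Deterministic activity log of the 9-phase stenting care cycle."""
    log: list[ActivityStep] = []
    for phase, (minutes, _personnel, goods, role) in _STENTING_TABLE.items():
        if phase == "5 Surgical intervention":
            stent_cost = STENT_UNIT_COST * STENTS_PER_PROCEDURE
            log.append(
                ActivityStep(
                    macro_phase=phase,
                    step="endovascular procedure",
                    minutes=minutes,
                    role=role,
                    goods_cost=goods - stent_cost - _IVUS_COST,
                )
            )
            log.append(
                ActivityStep(
                    macro_phase=phase,
                    step="venous stents (1.5 x EUR 1420)",
                    goods_cost=stent_cost,
                )
            )
            log.append(
                ActivityStep(macro_phase=phase, step="IVUS imaging", goods_cost=_IVUS_COST)
            )
        else:
            log.append(
                ActivityStep(
                    macro_phase=phase,
                    step=phase.split(" ", 1)[1],
                    minutes=minutes,
                    role=role,
                    goods_cost=goods,
                )
            )
    return log


def fixture_stenting_rates() -> dict[str, float]:
    """Capacity cost rates (EUR/min) consistent with the fixture log."""
    return {
        role: personnel / minutes
        for minutes, personnel, _goods, role in _STENTING_TABLE.values()
    }


# Outpatient conservative-care pathway, per step:
# (step, minutes, personnel EUR, goods EUR, patient EUR)
_SOC_FIRST_VISIT = [
    ("Patient reception", 2, 0.73, 0.02, 0.0),
    ("Acquisition of informed consent", 3, 1.10, 0.03, 0.0),
    ("Dermatological visit", 65, 51.16, 58.59, 0.0),
    ("Communication to patient and caregiver", 20, 32.32, 0.11, 0.0),
    ("Definition of treatment program", 15, 24.24, 67.38, 0.0),
    ("Delivery of treatment program", 15, 8.10, 0.08, 0.0),
]
# The wound-debridement row is performed at 50% of visits; its printed costs
# already carry the frequency, and its effective minutes (19.8) make the
# monthly block total the published 176.8 rather than the naive 177.
# The treatment-and-bandages internals carry sub-cent digits for the same
# reason as the stenting table: the printed monthly column totals
# (148.91 + 257.21 + 38.72) exceed the printed block total 444.83 by a cent.
_SOC_MONTHLY = [
    ("Patient reception", 2, 0.73, 0.02, 0.0),
    ("Visit", 20, 32.32, 0.32, 0.0),
    ("Cleansing, curettage and swab", 20, 21.56, 3.11, 0.0),
    ("Wound debridement (50% of visits)", 19.8, 32.32, 8.95, 0.0),
    ("Medication", 5, 2.70, 3.36, 0.0),
    ("Treatment and bandages", 107, 57.658, 241.426, 38.72),
    ("Booking next visit", 3, 1.62, 0.02, 0.0),
]
_SOC_FINAL = [
    ("Last medical visit", 20, 32.32, 0.11, 0.0),
    ("Instruction on braces use", 10, 5.40, 0.05, 0.0),
    ("Closing therapy (drugs and elastic socks)", 0, 0.0, 25.00, 185.50),
    ("Control visits", 40, 64.64, 0.43, 0.0),
]


def _aggregate(rows: list[tuple]) -> PhaseCost:
    return PhaseCost(
        minutes=sum(r[1] for r in rows),
        personnel=sum(r[2] for r in rows),
        goods=sum(r[3] for r in rows),
        patient=sum(r[4] for r in rows),
    )


def fixture_soc_phases(months_active: int = 3) -> EpisodeSpec:
    """Outpatient episode spec for conservative ulcer management: first
    visit, monthly management block, and the healing (final) phase."""
    return EpisodeSpec(
        first_visit=_aggregate(_SOC_FIRST_VISIT),
        monthly=_aggregate(_SOC_MONTHLY),
        final_phase=_aggregate(_SOC_FINAL),
        months_active=months_active,
    )


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic generators.

    ``timing_cv`` / ``cost_cv`` are coefficients of variation of the
    lognormal per-patient multipliers on step minutes and goods costs
    (0.2 emulates the case-mix variability of weight/complexity reported in
    field observation).  ``meta_*`` control the simulated study pool:
    ``meta_tau`` is between-study SD on the arcsine scale.
    """

    seed: int = 0
    n_patients: int = 100
    timing_cv: float = 0.2
    cost_cv: float = 0.2
    meta_k: int = 5
    meta_true_p: float = 0.61
    meta_tau: float = 0.0
    meta_size_range: tuple[int, int] = (30, 150)

    def __post_init__(self) -> None:
        if self.timing_cv < 0 or self.cost_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.meta_k < 1:
            raise ValueError("need at least one study")
        if not 0.0 < self.meta_true_p < 1.0:
            raise ValueError("true proportion must lie in (0, 1)")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def noisy_logs(cfg: SimConfig) -> list[list[ActivityStep]]:
    """Per-patient perturbations of the stenting fixture log.

    Minutes and goods costs get independent unit-mean lognormal multipliers
    per patient and step, so the expected roll-up equals the fixture's.
    """
    rng = np.random.default_rng(cfg.seed)
    base = fixture_stenting_log()
    logs = []
    for _ in range(cfg.n_patients):
        tf = _lognormal_factor(rng, cfg.timing_cv, len(base))
        cf = _lognormal_factor(rng, cfg.cost_cv, len(base))
        logs.append(
            [
                ActivityStep(
                    macro_phase=s.macro_phase,
                    step=s.step,
                    minutes=s.minutes * tf[i],
                    role=s.role,
                    goods_cost=s.goods_cost * cf[i],
                    patient_cost=s.patient_cost,
                    frequency=s.frequency,
                )
                for i, s in enumerate(base)
            ]
        )
    return logs


def simulate_studies(cfg: SimConfig) -> list[StudyOutcome]:
    """Simulated single-arm study pool with between-study heterogeneity.

    Study-level true proportions are drawn on the arcsine scale around the
    transform of ``meta_true_p`` with SD ``meta_tau``, then event counts are
    binomial.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.meta_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.meta_k)
    t0 = math.asin(math.sqrt(cfg.meta_true_p))
    studies = []
    for i, n in enumerate(sizes):
        t = rng.normal(t0, cfg.meta_tau) if cfg.meta_tau > 0 else t0
        p = math.sin(min(max(t, 0.0), math.pi / 2.0)) ** 2
        events = int(rng.binomial(int(n), p))
        studies.append(StudyOutcome(study_id=f"sim_{i + 1:02d}", events=events, total=int(n)))
    return studies
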