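"""Radar-chart value summary combining outcomes and costs.

Each strategy is scored on a common set of 0-100 axes: cost axes carry
normalized reciprocal cost ratios anchored to the cheapest strategy (the
cheapest scores 100, a strategy twice as expensive scores 50), outcome
rates are expressed as percentages, and QALYs are scaled against the
maximum attainable over the model horizon.  Larger enclosed polygon area
means better overall value, because on every axis "farther from the
center" reads as "better".
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_AXIS_ORDER",
    "build_value_axes",
    "normalize_cost_axis",
    "outcome_axes",
    "radar_area",
    "radar_plot",
]

DEFAULT_AXIS_ORDER = [
    "hospital_cost",
    "patient_cost",
    "qalys",
    "healing",
    "no_recurrence",
    "procedural_success",
]


def normalize_cost_axis(costs: Mapping[str, float]) -> dict[str, float]:
    """Reciprocal cost scores: 100 x min(costs) / cost, so the cheapest
    strategy anchors the axis at 100.  Scale-free in the currency unit."""
    if not costs:
        raise ValueError("need at least one strategy cost")
    if any(c <= 0 for c in costs.values()):
        raise ValueError("costs must be strictly positive")
    floor = min(costs.values())
    return {name: 100.0 * floor / c for name, c in costs.items()}


def outcome_axes(
    metrics: Mapping[str, Mapping[str, float]], horizon_years: float = 3.0
) -> dict[str, dict[str, float]]:
    """Score outcome metrics onto 0-100 axes.

    ``metrics`` maps strategy -> {qalys, healing, recurrence,
    procedural_success}; rates become percentages, recurrence is flipped to
    a no-recurrence score, and QALYs are scaled by 100 / horizon_years
    (full health over the whole horizon scores 100).
    """
    out: dict[str, dict[str, float]] = {}
    for name, m in metrics.items():
        for key in ("healing", "recurrence", "procedural_success"):
            if not 0.0 <= m[key] <= 1.0:
                raise ValueError(f"{name}: {key} must be a rate in [0, 1]")
        if m["qalys"] < 0:
            raise ValueError(f"{name}: QALYs must be >= 0")
        out[name] = {
            "qalys": min(100.0, 100.0 * m["qalys"] / horizon_years),
            "healing": 100.0 * m["healing"],
            "no_recurrence": 100.0 * (1.0 - m["recurrence"]),
            "procedural_success": 100.0 * m["procedural_success"],
        }
    return out


def build_value_axes(
    costs_hospital: Mapping[str, float],
    costs_patient: Mapping[str, float],
    metrics: Mapping[str, Mapping[str, float]],
    horizon_years: float = 3.0,
    axis_order: Sequence[str] = DEFAULT_AXIS_ORDER,
) -> pd.DataFrame:
    """Assemble the full score table: one row per strategy, one column per
    axis, in the declared spoke order (shared by all strategies so polygon
    areas are comparable)."""
    hosp = normalize_cost_axis(costs_hospital)
    pat = normalize_cost_axis(costs_patient)
    outcome = outcome_axes(metrics, horizon_years)
    rows = {}
    for name in metrics:
        rows[name] = {
            "hospital_cost": hosp[name],
            "patient_cost": pat[name],
            **outcome[name],
        }
    return pd.DataFrame(rows).T[list(axis_order)]


def radar_area(scores: Sequence[float]) -> float:
    """Area of the polygon formed by the scores on equally spaced spokes.

    With spoke angle 2*pi/n the area is sum(r_i * r_{i+1}) * sin(2*pi/n)/2;
    a regular hexagon of radius 100 gives 3*sqrt(3)/2 * 100^2.
    """
    r = np.asarray(scores, dtype=float)
    n = len(r)
    if n < 3:
        raise ValueError("a radar polygon needs at least 3 axes")
    if np.any(r < 0):
        raise ValueError("scores must be >= 0")
    theta = 2.0 * math.pi / n
    return 0.5 * math.sin(theta) * float(np.sum(r * np.roll(r, -1)))


def radar_plot(axes_df: pd.DataFrame, path) -> None:
    """Write the radar chart (one polygon per strategy) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(axes_df.columns)
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"projection": "polar"})
    for name, row in axes_df.iterrows():
        values = row.to_numpy(dtype=float)
        ax.plot(np.r_[angles, angles[0]], np.r_[values, values[0]], label=str(name))
        ax.fill(np.r_[angles, angles[0]], np.r_[values, values[0]], alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels([l.replace("_", " ") for l in labels])
    ax.set_ylim(0, 100)
    ax.legend(loc="lower right", bbox_to_anchor=(1.1, -0.1))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
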