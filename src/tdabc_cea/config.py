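"""Model configuration: the base case and YAML round-tripping.

The base case compares venous stenting against conservative compression
management (standard of care, SOC) of post-thrombotic leg ulcers over 36
monthly cycles from either the hospital or the societal (hospital +
out-of-pocket) perspective.  Clinical inputs are pooled single-arm
proportions; cost inputs are the TDABC roll-ups of the stenting care cycle
and the outpatient ulcer pathway.  Follow-up (conservative-care) costs are
shared between the arms: after stenting the patient still receives
compression therapy until healing, so the stenting arm accrues the same
monthly management costs while the ulcer stays active.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

from .markov import ModelConfig, StrategyParams, UtilitySet

__all__ = [
    "base_case",
    "get_path",
    "load_config",
    "make_model_config",
    "make_strategy",
    "make_utilities",
    "save_config",
    "set_path",
]


def base_case() -> dict[str, Any]:
    """The base-case configuration as a nested dict (YAML-serialisable)."""
    return {
        "strategies": {
            "stenting": {
                "p_healed": 0.81,
                "t_heal": 2.0,
                "p_recur": 0.05,
                # TDABC procedure cost 5081.99 x 1.03 re-intervention risk
                "procedure_cost": 5234.0,
                "p_reintervention": 0.03,
                # the procedure admission covers the first contact, so the
                # outpatient first visit is not charged on top of it
                "include_first_visit": False,
            },
            "soc": {
                "p_healed": 0.61,
                "t_heal": 3.0,
                "p_recur": 0.10,
                "procedure_cost": 0.0,
                "p_reintervention": 0.0,
                "include_first_visit": True,
            },
        },
        # follow-up costs are common to both arms (conservative approach)
        "costs": {
            "first_visit": {"hospital": 243.86, "societal": 243.86},
            "monthly_active": {"hospital": 406.11, "societal": 444.83},
            "healing_event": {"hospital": 127.95, "societal": 313.45},
        },
        "utilities": {"healed": 1.0, "active": 0.73, "recurred": 0.64},
        "model": {
            "horizon_months": 36,
            "discount_annual": 0.03,
            "perspective": "hospital",
            "healing_model": "tunnel",
        },
    }


def make_strategy(config: dict, name: str, perspective: str | None = None) -> StrategyParams:
    """Build one arm's :class:`StrategyParams` for the given perspective."""
    persp = perspective or config["model"].get("perspective", "hospital")
    arm = config["strategies"][name]
    costs = config["costs"]
    soc = config["strategies"]["soc"]
    first_visit = float(costs["first_visit"][persp]) if arm.get("include_first_visit", True) else 0.0
    return StrategyParams(
        name=name,
        p_healed=float(arm["p_healed"]),
        t_heal=float(arm["t_heal"]),
        p_recur=float(arm["p_recur"]),
        procedure_cost=float(arm.get("procedure_cost", 0.0)),
        p_reintervention=float(arm.get("p_reintervention", 0.0)),
        first_visit_cost=first_visit,
        monthly_active_cost=float(costs["monthly_active"][persp]),
        healing_event_cost=float(costs["healing_event"][persp]),
        # recurred ulcers are re-managed conservatively in both arms
        p_reheal=float(soc["p_healed"]),
        t_reheal=float(soc["t_heal"]),
    )


def make_utilities(config: dict) -> UtilitySet:
    u = config["utilities"]
    return UtilitySet(u_healed=float(u["healed"]), u_active=float(u["active"]), u_recurred=float(u["recurred"]))


def make_model_config(config: dict, perspective: str | None = None) -> ModelConfig:
    m = config["model"]
    return ModelConfig(
        horizon=int(m.get("horizon_months", 36)),
        discount_annual=float(m.get("discount_annual", 0.03)),
        perspective=perspective or m.get("perspective", "hospital"),
        healing_model=m.get("healing_model", "tunnel"),
        discount_conversion=m.get("discount_conversion", "compound"),
    )


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def get_path(config: dict, dotted: str) -> Any:
    """Fetch a nested value by dotted path, e.g. ``strategies.soc.t_heal``."""
    node: Any = config
    for key in dotted.split("."):
        try:
            node = node[key]
        except (KeyError, TypeError):
            raise KeyError(f"unknown configuration path {dotted!r}") from None
    return node


def set_path(config: dict, dotted: str, value: Any) -> dict:
    """Return a deep copy of ``config`` with the dotted path set to ``value``."""
    out = copy.deepcopy(config)
    keys = dotted.split(".")
    node: Any = out
    for key in keys[:-1]:
        try:
            node = node[key]
        except (KeyError, TypeError):
            raise KeyError(f"unknown configuration path {dotted!r}") from None
    if keys[-1] not in node:
        raise KeyError(f"unknown configuration path {dotted!r}")
    node[keys[-1]] = value
    return out
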