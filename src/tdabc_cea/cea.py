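"""Cost-utility analysis: ICUR, one-way sensitivity, probabilistic SA.

The incremental cost-utility ratio compares two strategies:

    ICUR = (Cost_A - Cost_B) / (QALY_A - QALY_B)

with the usual dominance vocabulary — a strategy that is cheaper *and* more
effective is *dominant*, one that is dearer and less effective *dominated*;
the ratio is undefined when the arms are equally effective.

One-way sensitivity varies each parameter to 80% / 120% of its base value
(capped where the natural domain requires, e.g. utilities at 1), re-running
the full model each time.  The probabilistic sensitivity analysis draws
parameters from method-of-moments beta (utilities, proportions) and gamma
(costs, healing times) distributions with a standard deviation equal to a
fixed fraction (default 20%) of the baseline value, and summarises the
draws as a cost-effectiveness acceptability curve: the share of draws for
which the incremental net monetary benefit ``wtp * dQALY - dCost`` is
non-negative at each willingness-to-pay threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import config as cfgmod
from .markov import run_strategy

__all__ = [
    "CEAResult",
    "DEFAULT_PSA_PARAMS",
    "DEFAULT_SA_PARAMS",
    "PSAConfig",
    "PSAResult",
    "SAEntry",
    "beta_mm",
    "ceac_from_draws",
    "gamma_mm",
    "icur",
    "one_way_sa",
    "psa",
    "run_cea",
]


@dataclass(frozen=True)
class CEAResult:
    """Mean costs and QALYs per arm plus the incremental verdict.

    ``icur`` is EUR/QALY when a meaningful ratio exists, else ``None`` with
    the verdict carrying the label (``dominant`` / ``dominated`` /
    ``undefined (equal effectiveness)``).
    """

    cost_stenting: float
    cost_soc: float
    qaly_stenting: float
    qaly_soc: float
    icur: float | None
    verdict: str

    @property
    def delta_cost(self) -> float:
        return self.cost_stenting - self.cost_soc

    @property
    def delta_qaly(self) -> float:
        return self.qaly_stenting - self.qaly_soc

    @property
    def icur_label(self) -> str:
        if self.icur is None:
            return self.verdict
        return f"{self.icur:.2f}"


def icur(
    cost_stenting: float, cost_soc: float, qaly_stenting: float, qaly_soc: float
) -> CEAResult:
    """Incremental cost-utility ratio with dominance labelling."""
    dc = cost_stenting - cost_soc
    dq = qaly_stenting - qaly_soc
    if dq == 0:
        value, verdict = None, "undefined (equal effectiveness)"
    elif dq > 0 and dc < 0:
        value, verdict = None, "dominant"
    elif dq < 0 and dc > 0:
        value, verdict = None, "dominated"
    else:
        value, verdict = dc / dq, "icur"
    return CEAResult(
        cost_stenting=cost_stenting,
        cost_soc=cost_soc,
        qaly_stenting=qaly_stenting,
        qaly_soc=qaly_soc,
        icur=value,
        verdict=verdict,
    )


def run_cea(config: dict, perspective: str | None = None) -> CEAResult:
    """Run both arms of the Markov model and form the ICUR."""
    utilities = cfgmod.make_utilities(config)
    mc = cfgmod.make_model_config(config, perspective)
    persp = mc.perspective
    traces = {
        name: run_strategy(cfgmod.make_strategy(config, name, persp), utilities, mc)
        for name in ("stenting", "soc")
    }
    return icur(
        traces["stenting"].cost,
        traces["soc"].cost,
        traces["stenting"].qalys,
        traces["soc"].qalys,
    )


# ---------------------------------------------------------------------------
# One-way sensitivity analysis

# (label, config path, upper cap or None) — the tornado rows of the base case
DEFAULT_SA_PARAMS: list[tuple[str, str, float | None]] = [
    ("Stenting % ulcers healed", "strategies.stenting.p_healed", 1.0),
    ("SOC % ulcers healed", "strategies.soc.p_healed", 1.0),
    ("Utility healed ulcer", "utilities.healed", 1.0),
    ("Utility active ulcer", "utilities.active", 1.0),
    ("Cost Stenting", "strategies.stenting.procedure_cost", None),
    ("Cost FUP-active ulcer (monthly)", "costs.monthly_active.{persp}", None),
    ("SOC mean healing time (months)", "strategies.soc.t_heal", None),
    ("Utility recurred ulcer", "utilities.recurred", 1.0),
    ("Cost first visit-active ulcer", "costs.first_visit.{persp}", None),
]


@dataclass(frozen=True)
class SAEntry:
    parameter: str
    low: float
    base: float
    high: float
    icur_low: float | str
    icur_high: float | str
    variation: float | str


def _icur_or_label(result: CEAResult) -> float | str:
    return result.icur if result.icur is not None else result.verdict.capitalize()


def one_way_sa(
    config: dict,
    params: Sequence[tuple[str, str, float | None]] | None = None,
    perspective: str | None = None,
    spread: float = 0.20,
) -> list[SAEntry]:
    """Tornado table: ICUR at 1 +/- ``spread`` times each parameter's base.

    ``params`` entries are ``(label, dotted config path, upper cap)``; the
    literal ``{persp}`` in a path resolves to the active perspective.  When
    either limit yields a dominance label rather than a ratio, the variation
    column reports ``"CEA result change"``.
    """
    persp = perspective or config["model"].get("perspective", "hospital")
    entries = []
    for label, path, cap in params or DEFAULT_SA_PARAMS:
        path = path.format(persp=persp)
        base = float(cfgmod.get_path(config, path))
        low, high = base * (1.0 - spread), base * (1.0 + spread)
        if cap is not None:
            low, high = min(low, cap), min(high, cap)
        res_low = run_cea(cfgmod.set_path(config, path, low), persp)
        res_high = run_cea(cfgmod.set_path(config, path, high), persp)
        icur_low, icur_high = _icur_or_label(res_low), _icur_or_label(res_high)
        if isinstance(icur_low, str) or isinstance(icur_high, str):
            variation: float | str = "CEA result change"
        else:
            variation = abs(icur_high - icur_low)
        entries.append(
            SAEntry(
                parameter=label,
                low=low,
                base=base,
                high=high,
                icur_low=icur_low,
                icur_high=icur_high,
                variation=variation,
            )
        )
    return entries


def sa_table(entries: Sequence[SAEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "lower_limit": [e.low for e in entries],
            "base_case": [e.base for e in entries],
            "upper_limit": [e.high for e in entries],
            "icur_lower": [e.icur_low for e in entries],
            "icur_upper": [e.icur_high for e in entries],
            "variation": [e.variation for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis

def beta_mm(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters matching a mean and standard deviation.

    Raises when the moments are infeasible for a beta distribution
    (``sd**2 >= mean * (1 - mean)``).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must lie strictly in (0, 1)")
    var = sd * sd
    if var <= 0:
        raise ValueError("sd must be > 0")
    if var >= mean * (1.0 - mean):
        raise ValueError("variance infeasible for a beta distribution")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_mm(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard deviation."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma mean and sd must be > 0")
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


# (config path, distribution family) sampled in this order every draw
DEFAULT_PSA_PARAMS: list[tuple[str, str]] = [
    ("strategies.stenting.p_healed", "beta"),
    ("strategies.soc.p_healed", "beta"),
    ("utilities.healed", "beta"),
    ("utilities.active", "beta"),
    ("utilities.recurred", "beta"),
    ("strategies.stenting.procedure_cost", "gamma"),
    ("costs.monthly_active.{persp}", "gamma"),
    ("strategies.soc.t_heal", "gamma"),
    ("costs.first_visit.{persp}", "gamma"),
    ("strategies.stenting.p_recur", "beta"),
    ("strategies.soc.p_recur", "beta"),
]


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 1000
    seed: int = 42
    sd_fraction: float = 0.20
    wtp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 50_500.0, 500.0)
    )

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")


@dataclass
class PSAResult:
    draws: pd.DataFrame  # draw, cost_*, qaly_*, dcost, dqaly
    ceac: pd.DataFrame  # wtp, p_cost_effective


def _sample_param(rng: np.random.Generator, base: float, family: str, sd_fraction: float) -> float:
    """One method-of-moments draw around ``base`` with sd = fraction x base.

    Degenerate cases are held fixed: zero baselines (nothing to scale) and
    beta parameters whose moments are infeasible — in particular a utility
    at the ceiling of 1.0, which the one-way analysis likewise caps — are
    returned unchanged with a warning.
    """
    if sd_fraction == 0 or base == 0:
        return base
    sd = sd_fraction * base
    if family == "gamma":
        shape, scale = gamma_mm(base, sd)
        return float(rng.gamma(shape, scale))
    if family == "beta":
        if base >= 1.0 or sd * sd >= base * (1.0 - base):
            warnings.warn(
                f"beta moments infeasible for mean {base} with sd {sd:.4f}; "
                "parameter held at its baseline",
                RuntimeWarning,
                stacklevel=2,
            )
            return base
        a, b = beta_mm(base, sd)
        return float(rng.beta(a, b))
    raise ValueError(f"unknown distribution family {family!r}")


def psa(
    config: dict,
    psa_cfg: PSAConfig,
    params: Sequence[tuple[str, str]] | None = None,
    perspective: str | None = None,
) -> PSAResult:
    """Monte-Carlo PSA: sample parameters, run both arms, build the CEAC.

    Sampling order follows the declared parameter list with a single seeded
    generator, so results are bit-reproducible for a given seed.  Sampled
    healing times are floored at 1 month (the minimum cycle length).
    """
    persp = perspective or config["model"].get("perspective", "hospital")
    param_list = [(p.format(persp=persp), fam) for p, fam in (params or DEFAULT_PSA_PARAMS)]
    rng = np.random.default_rng(psa_cfg.seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("once", RuntimeWarning)
        for i in range(psa_cfg.n_draws):
            draw_cfg = config
            for path, family in param_list:
                base = float(cfgmod.get_path(config, path))
                value = _sample_param(rng, base, family, psa_cfg.sd_fraction)
                if "t_heal" in path:
                    value = max(1.0, value)
                draw_cfg = cfgmod.set_path(draw_cfg, path, value)
            res = run_cea(draw_cfg, persp)
            rows.append(
                {
                    "draw": i,
                    "cost_stenting": res.cost_stenting,
                    "cost_soc": res.cost_soc,
                    "qaly_stenting": res.qaly_stenting,
                    "qaly_soc": res.qaly_soc,
                    "dcost": res.delta_cost,
                    "dqaly": res.delta_qaly,
                }
            )
    draws = pd.DataFrame(rows)
    ceac = ceac_from_draws(draws, psa_cfg.wtp_grid)
    return PSAResult(draws=draws, ceac=ceac)


def ceac_from_draws(draws: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA draws: at each
    willingness-to-pay, the share of draws with non-negative incremental net
    monetary benefit."""
    dc = draws["dcost"].to_numpy()
    dq = draws["dqaly"].to_numpy()
    wtp = np.asarray(wtp_grid, dtype=float)
    prob = (wtp[:, None] * dq[None, :] - dc[None, :] >= 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp, "p_cost_effective": prob})


def ceac_crossing(ceac: pd.DataFrame, level: float = 0.5) -> float | None:
    """Smallest willingness-to-pay at which the acceptability reaches
    ``level`` (linear interpolation between grid points); None if never."""
    wtp = ceac["wtp"].to_numpy()
    p = ceac["p_cost_effective"].to_numpy()
    above = np.nonzero(p >= level)[0]
    if len(above) == 0:
        return None
    j = above[0]
    if j == 0 or p[j] == p[j - 1]:
        return float(wtp[j])
    frac = (level - p[j - 1]) / (p[j] - p[j - 1])
    return float(wtp[j - 1] + frac * (wtp[j] - wtp[j - 1]))


def ceac_plot(ceac: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["p_cost_effective"])
    ax.set_xlabel("Willingness to pay (EUR/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
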