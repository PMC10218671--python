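"""Random-effects meta-analysis of single-arm proportions.

Pools event proportions (ulcers healed, ulcers recurred) across studies on
the Freeman-Tukey double-arcsine scale, which stabilises the binomial
variance to 1/(4n+2) and behaves at the 0%/100% boundaries without
continuity corrections.  Between-study variance is estimated with the
DerSimonian-Laird moment estimator (truncated at zero) and the pooled
transformed mean is inverted with the Miller back-transformation using the
harmonic mean of the study sizes.  95% confidence limits use normal
quantiles on the transformed scale.  These are the defaults of the widely
used Stata ``metaprop`` routine, so pooled values are comparable with the
bulk of the published single-arm ulcer literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PooledProportion",
    "StudyOutcome",
    "ft_backtransform",
    "ft_transform",
    "load_studies",
    "pool",
]


@dataclass(frozen=True)
class StudyOutcome:
    """Event count out of a study's total (e.g. ulcers healed / ulcers)."""

    study_id: str
    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError(f"study {self.study_id!r}: total must be >= 1")
        if not 0 <= self.events <= self.total:
            raise ValueError(f"study {self.study_id!r}: events must lie in [0, total]")

    @property
    def proportion(self) -> float:
        return self.events / self.total


@dataclass(frozen=True)
class PooledProportion:
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float  # between-study variance on the transformed scale
    i2: float  # heterogeneity, percent of total variability
    k: int


def ft_transform(events: int, total: int) -> tuple[float, float]:
    """Freeman-Tukey double-arcsine transform of x events out of n.

    t = (asin sqrt(x/(n+1)) + asin sqrt((x+1)/(n+1))) / 2, with sampling
    variance 1/(4n+2) regardless of the underlying proportion.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= events <= total:
        raise ValueError("events must lie in [0, total]")
    n1 = total + 1
    t = 0.5 * (math.asin(math.sqrt(events / n1)) + math.asin(math.sqrt((events + 1) / n1)))
    return t, 1.0 / (4 * total + 2)


def ft_backtransform(t: float, n: float) -> float:
    """Invert the double-arcsine transform at (harmonic mean) size ``n``.

    Uses Miller's closed form; values of ``t`` beyond the transforms of 0
    and n events map to exactly 0 and 1.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    # attainable range of the transform at this n
    lo = 0.5 * math.asin(math.sqrt(1.0 / (n + 1)))
    hi = 0.5 * (math.asin(math.sqrt(n / (n + 1))) + math.pi / 2)
    if t <= lo:
        return 0.0
    if t >= hi:
        return 1.0
    s = math.sin(2 * t)
    v = s + (s - 1.0 / s) / n
    inner = max(0.0, 1.0 - v * v)
    p = 0.5 * (1.0 - math.copysign(1.0, math.cos(2 * t)) * math.sqrt(inner))
    return min(1.0, max(0.0, p))


def pool(studies: Sequence[StudyOutcome], ci_level: float = 0.95) -> PooledProportion:
    """Pool study proportions with a DerSimonian-Laird random-effects model.

    A single study is returned as its own proportion with tau2 = i2 = 0
    (its confidence interval still comes from the transformed scale).
    """
    studies = list(studies)
    k = len(studies)
    if k == 0:
        raise ValueError("cannot pool an empty study list")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ts, vs, ns = np.empty(k), np.empty(k), np.empty(k)
    for i, s in enumerate(studies):
        ts[i], vs[i] = ft_transform(s.events, s.total)
        ns[i] = s.total
    n_harm = stats.hmean(ns)

    if k == 1:
        se = math.sqrt(vs[0])
        return PooledProportion(
            estimate=studies[0].proportion,
            ci_low=ft_backtransform(ts[0] - z * se, n_harm),
            ci_high=ft_backtransform(ts[0] + z * se, n_harm),
            tau2=0.0,
            i2=0.0,
            k=1,
        )

    w = 1.0 / vs
    t_fixed = float(np.sum(w * ts) / np.sum(w))
    q = float(np.sum(w * (ts - t_fixed) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    i2 = 100.0 * max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0

    wr = 1.0 / (vs + tau2)
    t_pooled = float(np.sum(wr * ts) / np.sum(wr))
    se = math.sqrt(1.0 / float(np.sum(wr)))
    return PooledProportion(
        estimate=ft_backtransform(t_pooled, n_harm),
        ci_low=ft_backtransform(t_pooled - z * se, n_harm),
        ci_high=ft_backtransform(t_pooled + z * se, n_harm),
        tau2=tau2,
        i2=i2,
        k=k,
    )


def load_studies(path: str | Path) -> list[StudyOutcome]:
    """Read a study-outcome CSV with columns ``study_id,events,total``."""
    df = pd.read_csv(path)
    if not {"study_id", "events", "total"} <= set(df.columns):
        raise ValueError("study table needs columns study_id,events,total")
    return [
        StudyOutcome(str(r.study_id), int(r.events), int(r.total)) for r in df.itertuples()
    ]


def forest_plot(studies: Sequence[StudyOutcome], pooled: PooledProportion, path: str | Path) -> None:
    """Write a minimal forest plot (per-study proportions with exact binomial
    CIs, diamond for the pooled estimate) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * len(studies) + 1.5))
    for y, s in enumerate(studies):
        lo, hi = stats.beta.ppf([0.025, 0.975], s.events + 0.5, s.total - s.events + 0.5)
        ax.plot([lo, hi], [y, y], color="0.4")
        ax.plot(s.proportion, y, "s", color="0.2", markersize=5)
    ax.errorbar(
        pooled.estimate,
        len(studies),
        xerr=[[pooled.estimate - pooled.ci_low], [pooled.ci_high - pooled.estimate]],
        fmt="D",
        color="tab:red",
    )
    ax.set_yticks(range(len(studies) + 1))
    ax.set_yticklabels([s.study_id for s in studies] + ["Pooled (RE)"])
    ax.set_xlabel("Proportion")
    ax.set_xlim(-0.02, 1.02)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
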