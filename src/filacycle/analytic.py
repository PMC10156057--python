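"""Closed-form mutant fitness and adaptation theory.

Treating one iteration of the life cycle as a renewal event, a lineage
with traits ``(s_c, s_g)`` in a life cycle (N, k) produces

    f   = (1 + s_g) * p_s(x) * k        surviving daughters per cycle,
    tau = ln(k) / (lambda_c (1 + s_c))  time per cycle,

so its filament population grows exponentially at rate

    lambda_g = ln(f) / tau = lambda_c (1 + s_c) ln((1+s_g) p_s(x) k) / ln(k).

Fitness relative to the resident ancestor (traits (0, 0)) is the ratio of
growth rates,

    w = (1 + s_c) (1 + ln(1 + s_g) / ln(f_anc)),    f_anc = k p_s(x),

which makes the two trait channels exactly balanced when f_anc = e: below
e surviving daughters, improving group survival pays more than improving
cell division rate; above, the reverse.  From ``w`` follow the logistic
mutant-proportion trajectory, the 50%-takeover time, and the geometry of
the trait-space regions where altruistic (s_c < 0, s_g > 0) or selfish
(s_c > 0, s_g < 0) mutations invade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .selection import Environment, LifeCycle, Traits, survival_probability

__all__ = [
    "AncestorModel",
    "AdaptationQuery",
    "AnalyticSummary",
    "expected_surviving_offspring",
    "cycle_time",
    "lineage_growth_rate",
    "relative_fitness",
    "mutant_proportion",
    "takeover_time",
    "adaptation_rate",
    "adaptation_timescale",
    "balance_offspring_number",
    "spread_region_fraction",
    "adaptation_rate_map",
    "log_ratio_map",
    "summarize",
    "QUADRANTS",
]

#: (s_c, s_g) bounds of the two tradeoff quadrants studied throughout.
QUADRANTS = {
    "altruistic": ((-0.2, 0.0), (0.0, 0.2)),
    "selfish": ((0.0, 0.2), (-0.2, 0.0)),
}

Quadrant = Literal["altruistic", "selfish"]
Channel = Literal["cell", "group"]

_NEUTRAL = Traits(0.0, 0.0)


@dataclass(frozen=True)
class AncestorModel:
    """A resident life cycle in an environment, with intrinsic cell
    division rate ``lambda_c`` (default 1, fixing the unit of time)."""

    life_cycle: LifeCycle
    env: Environment
    lambda_c: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lambda_c > 0 and math.isfinite(self.lambda_c)):
            raise ValueError("lambda_c must be positive and finite")

    @property
    def f_ancestor(self) -> float:
        """Expected surviving daughters per cycle of the resident,
        f = k p_s(N/k)."""
        return expected_surviving_offspring(self, _NEUTRAL)


@dataclass(frozen=True)
class AdaptationQuery:
    """Initial mutant proportion and takeover threshold for invasion
    dynamics.  Defaults: p = 1/1000, threshold = 50%."""

    p: float = 1e-3
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.p < self.threshold <= 1.0):
            raise ValueError("need 0 < p < threshold <= 1")


@dataclass(frozen=True)
class AnalyticSummary:
    """Per-cycle and per-time summary of a mutant lineage."""

    f: float
    tau: float
    lambda_g: float
    w: float


def expected_surviving_offspring(ancestor: AncestorModel, traits: Traits) -> float:
    """f = (1 + s_g) p_s(N/k) k — surviving daughters per life-cycle
    iteration.  The ancestral value is obtained with s_g = 0."""
    lc = ancestor.life_cycle
    ps = survival_probability(lc.daughter_size, ancestor.env)
    return (1.0 + traits.s_g) * ps * lc.k


def cycle_time(ancestor: AncestorModel, traits: Traits) -> float:
    """tau = ln(k) / (lambda_c (1 + s_c)) — time for a daughter of x
    cells to regrow to the adult size N = k x."""
    if traits.s_c <= -1.0:
        raise ValueError("s_c <= -1 means non-growing cells; tau undefined")
    return math.log(ancestor.life_cycle.k) / (ancestor.lambda_c * (1.0 + traits.s_c))


def lineage_growth_rate(ancestor: AncestorModel, traits: Traits) -> float:
    """lambda_g = ln(f) / tau, the exponential growth rate of the
    lineage's filament population."""
    f = expected_surviving_offspring(ancestor, traits)
    if f <= 0.0:
        raise ValueError(f"f = {f} <= 0: lineage growth rate undefined")
    return math.log(f) / cycle_time(ancestor, traits)


def relative_fitness(
    ancestor: AncestorModel, traits: Traits, first_order: bool = False
) -> float:
    """w = (1 + s_c)(1 + ln(1 + s_g)/ln(f_anc)), the mutant's growth rate
    relative to the ancestor's.

    The exact-log form is the default; ``first_order=True`` opts into the
    small-``s_g`` approximation (1 + s_c)(1 + s_g/ln(f_anc)).  Requires a
    viable ancestor (f_anc > 1) and s_g > -1.
    """
    f_anc = ancestor.f_ancestor
    if f_anc <= 1.0:
        raise ValueError(
            f"ancestral f = {f_anc:.4g} <= 1: the resident is not an "
            "exponentially growing reference"
        )
    if traits.s_g <= -1.0:
        raise ValueError("s_g <= -1 gives non-positive survival")
    log_f = math.log(f_anc)
    group_term = traits.s_g / log_f if first_order else math.log1p(traits.s_g) / log_f
    return (1.0 + traits.s_c) * (1.0 + group_term)


def summarize(ancestor: AncestorModel, traits: Traits) -> AnalyticSummary:
    """Bundle f, tau, lambda_g and w for one mutant phenotype."""
    return AnalyticSummary(
        f=expected_surviving_offspring(ancestor, traits),
        tau=cycle_time(ancestor, traits),
        lambda_g=lineage_growth_rate(ancestor, traits),
        w=relative_fitness(ancestor, traits),
    )


def mutant_proportion(
    ancestor: AncestorModel,
    traits: Traits,
    t: float,
    query: AdaptationQuery = AdaptationQuery(),
) -> float:
    """Mutant proportion P(t) under logistic replacement dynamics.

    P(t) = r e^{g t} / (r e^{g t} + 1) with r = p/(1-p) and
    g = lambda_g^anc (w - 1): the ancestor's growth rate times the
    mutant's selective advantage.
    """
    g = lineage_growth_rate(ancestor, _NEUTRAL) * (relative_fitness(ancestor, traits) - 1.0)
    log_odds = math.log(query.p / (1.0 - query.p)) + g * t
    return 1.0 / (1.0 + math.exp(-log_odds))


def takeover_time(
    ancestor: AncestorModel,
    traits: Traits,
    query: AdaptationQuery = AdaptationQuery(),
) -> float:
    """Time for the mutant proportion to reach the takeover threshold.

    t = ln[ (threshold/(1-threshold)) * ((1-p)/p) ] / (lambda_g (w - 1)),
    which reduces to ln((1-p)/p) / (lambda_g (w-1)) at threshold 1/2.
    Returns ``inf`` when w <= 1 (the mutant never takes over).
    """
    w = relative_fitness(ancestor, traits)
    if w <= 1.0:
        return math.inf
    g = lineage_growth_rate(ancestor, _NEUTRAL) * (w - 1.0)
    numer = math.log(query.threshold / (1.0 - query.threshold)) + math.log(
        (1.0 - query.p) / query.p
    )
    return numer / g


def adaptation_rate(
    ancestor: AncestorModel,
    traits: Traits,
    query: AdaptationQuery = AdaptationQuery(),
) -> float:
    """1 / takeover_time; zero when the mutant cannot take over."""
    t = takeover_time(ancestor, traits, query)
    return 0.0 if math.isinf(t) else 1.0 / t


def adaptation_timescale(
    ancestor: AncestorModel, traits: Traits, channel: Channel
) -> float:
    """The selection timescale lambda_g (w - 1) for a single-channel
    mutation.

    channel="cell"  (s_g = 0):  (lambda_c / ln k) ln(f_anc) s_c
    channel="group" (s_c = 0):  (lambda_c / ln k) ln(1 + s_g)

    The two coincide for matched effects ln(1+s_g) = s_c exactly when
    ln(f_anc) = 1, i.e. f_anc = e.
    """
    lc = ancestor.life_cycle
    log_k = math.log(lc.k)
    if channel == "cell":
        if traits.s_g != 0.0:
            raise ValueError("cell channel requires s_g = 0")
        return ancestor.lambda_c / log_k * math.log(ancestor.f_ancestor) * traits.s_c
    if channel == "group":
        if traits.s_c != 0.0:
            raise ValueError("group channel requires s_c = 0")
        return ancestor.lambda_c / log_k * math.log1p(traits.s_g)
    raise ValueError(f"unknown channel {channel!r}")


def balance_offspring_number(effect: float = 1e-6) -> float:
    """The ancestral offspring number f at which the cell and group
    adaptation timescales coincide for matched effects s_c = s_g.

    Solved numerically: the root in f of
    ln(f) * s_c - ln(1 + s_g) at s_c = s_g = ``effect``, which tends to
    e as the effect size goes to zero.
    """
    from scipy.optimize import brentq

    def gap(f: float) -> float:
        return math.log(f) * effect - math.log1p(effect)

    return float(brentq(gap, 1.0 + 1e-9, 100.0, xtol=1e-12, rtol=1e-15))


def _quadrant_grid(quadrant: Quadrant, n_grid: int):
    """Cell-midpoint meshgrid over a tradeoff quadrant."""
    try:
        (sc_lo, sc_hi), (sg_lo, sg_hi) = QUADRANTS[quadrant]
    except KeyError:
        raise ValueError(
            f"unknown quadrant {quadrant!r}; expected one of {sorted(QUADRANTS)}"
        ) from None
    sc_step = (sc_hi - sc_lo) / n_grid
    sg_step = (sg_hi - sg_lo) / n_grid
    sc = sc_lo + sc_step * (np.arange(n_grid) + 0.5)
    sg = sg_lo + sg_step * (np.arange(n_grid) + 0.5)
    return np.meshgrid(sc, sg, indexing="ij")


def _w_grid(ancestor: AncestorModel, sc: np.ndarray, sg: np.ndarray) -> np.ndarray:
    f_anc = ancestor.f_ancestor
    if f_anc <= 1.0:
        raise ValueError(f"ancestral f = {f_anc:.4g} <= 1")
    return (1.0 + sc) * (1.0 + np.log1p(sg) / np.log(f_anc))


def spread_region_fraction(
    ancestor: AncestorModel, quadrant: Quadrant, n_grid: int = 500
) -> float:
    """Percentage of a tradeoff quadrant where the mutant invades (w > 1).

    Evaluated on an ``n_grid`` x ``n_grid`` cell-midpoint grid with a
    strict inequality, so the measure-zero neutral boundary never counts.
    """
    sc, sg = _quadrant_grid(quadrant, n_grid)
    w = _w_grid(ancestor, sc, sg)
    return float(100.0 * np.count_nonzero(w > 1.0) / w.size)


def adaptation_rate_map(
    ancestor: AncestorModel,
    quadrant: Quadrant,
    n_grid: int = 200,
    query: AdaptationQuery = AdaptationQuery(),
) -> pd.DataFrame:
    """Takeover rate 1/t across a tradeoff quadrant.

    Returns a tidy DataFrame (s_c, s_g, w, rate); rate is 0 where the
    mutant cannot take over (w <= 1).
    """
    sc, sg = _quadrant_grid(quadrant, n_grid)
    w = _w_grid(ancestor, sc, sg)
    g = lineage_growth_rate(ancestor, _NEUTRAL) * (w - 1.0)
    numer = math.log(query.threshold / (1.0 - query.threshold)) + math.log(
        (1.0 - query.p) / query.p
    )
    rate = np.where(w > 1.0, g / numer, 0.0)
    return pd.DataFrame(
        {
            "s_c": sc.ravel(),
            "s_g": sg.ravel(),
            "w": w.ravel(),
            "rate": rate.ravel(),
        }
    )


def log_ratio_map(
    ancestor_a: AncestorModel,
    ancestor_b: AncestorModel,
    quadrant: Quadrant,
    n_grid: int = 200,
    query: AdaptationQuery = AdaptationQuery(),
) -> pd.DataFrame:
    """log(rate_a / rate_b) across a quadrant; NaN where either life
    cycle cannot fix the mutation."""
    ma = adaptation_rate_map(ancestor_a, quadrant, n_grid, query)
    mb = adaptation_rate_map(ancestor_b, quadrant, n_grid, query)
    both = (ma["rate"].to_numpy() > 0) & (mb["rate"].to_numpy() > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(
            both, np.log(ma["rate"].to_numpy() / mb["rate"].to_numpy()), np.nan
        )
    return pd.DataFrame(
        {
            "s_c": ma["s_c"],
            "s_g": ma["s_g"],
            "rate_a": ma["rate"],
            "rate_b": mb["rate"],
            "log_ratio": log_ratio,
        }
    )
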