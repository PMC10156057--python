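"""Agent-based simulation of filament growth, fragmentation and survival.

Each cell carries its own phenotype and division clock; waiting times are
drawn from a normal distribution with mean ``1/(1 + s_c)`` and standard
deviation 0.1 (truncated below at 1e-6), so division is nearly periodic
rather than memoryless — desynchronisation builds up gradually, as in the
division-timer picture the model is built on.  Filaments fragment
instantaneously on reaching the adult size ``N`` into ``k`` contiguous
fragments of ``x = N/k`` cells; each fragment survives an independent
uniform draw against ``clamp(p_s(x) (1 + s̄_g), 0, 1)``, with ``s̄_g`` the
fragment's mean group trait.

Because the division clock is a timer rather than an exponential rate, a
neutral cell population grows at the Euler–Lotka rate of the timer
distribution (about ``ln 2`` per mean division interval), not at the unit
rate the analytic theory assigns to ``lambda_c = 1``.
:func:`stochastic_growth_rate` therefore converts measured slopes into
the analytic time unit via the timer's Euler–Lotka rate, making simulated
growth rates directly comparable with ``analytic.lineage_growth_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _engine
from .selection import Environment, LifeCycle, Traits, survival_probability

__all__ = [
    "Cell",
    "Filament",
    "SimState",
    "StopCondition",
    "single_cell_state",
    "filament_state",
    "mutant_invasion_state",
    "step_simulation",
    "estimate_extinction_rate",
    "stochastic_growth_rate",
    "cell_clock_rate",
    "ExtinctionEstimate",
    "GrowthRateEstimate",
]

DIVISION_SD = 0.1  # sd of the division-time draw; the mean scales with s_c


@dataclass(frozen=True)
class Cell:
    """A single cell: phenotype, lineage tag and pending division time."""

    traits: Traits
    next_division_time: float
    is_mutant: bool = False


@dataclass(frozen=True)
class Filament:
    """An ordered run of cells; order matters because fragmentation cuts
    contiguous runs."""

    cells: tuple[Cell, ...]

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def mean_s_g(self) -> float:
        return float(np.mean([c.traits.s_g for c in self.cells]))


@dataclass(frozen=True)
class StopCondition:
    """Structured stop rule for the next-event loop.

    The simulation halts at the first event after which the alive cell
    count reaches ``max_cells``, the clock passes ``max_time``, or (with
    ``on_mutant_extinct``) no tagged-lineage cells remain.  Extinction of
    the whole population always stops the run.
    """

    max_cells: int | None = None
    max_time: float | None = None
    on_mutant_extinct: bool = False

    def __post_init__(self) -> None:
        if self.max_cells is None and self.max_time is None and not self.on_mutant_extinct:
            raise ValueError("stop condition would never trigger")


@dataclass
class SimState:
    """Population state between engine runs.

    The cell population is stored as flat arrays (phenotypes, lineage
    tags, absolute division clocks, and filament boundaries); the
    ``filaments`` property materialises the object view for inspection.
    ``status`` records why the last engine run stopped, and the logs
    hold realized division waits and per-fragmentation survivor counts.
    """

    s_c: np.ndarray
    s_g: np.ndarray
    is_mutant: np.ndarray
    clock: np.ndarray
    fil_start: np.ndarray  # cells [fil_start[j], fil_start[j+1]) = filament j
    time: float = 0.0
    status: str = "initial"
    division_waits: np.ndarray = field(default_factory=lambda: np.empty(0))
    fragmentation_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    fragmentation_survivors: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    sampled_cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sampled_filaments: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    level_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    level_filaments: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    @property
    def n_cells(self) -> int:
        return int(self.s_c.shape[0])

    @property
    def n_filaments(self) -> int:
        return int(self.fil_start.shape[0] - 1)

    @property
    def n_mutants(self) -> int:
        return int(self.is_mutant.sum())

    @property
    def extinct(self) -> bool:
        return self.n_cells == 0

    @property
    def filaments(self) -> list[Filament]:
        out = []
        for j in range(self.n_filaments):
            lo, hi = self.fil_start[j], self.fil_start[j + 1]
            out.append(
                Filament(
                    cells=tuple(
                        Cell(
                            traits=Traits(float(self.s_c[i]), float(self.s_g[i])),
                            next_division_time=float(self.clock[i]),
                            is_mutant=bool(self.is_mutant[i]),
                        )
                        for i in range(lo, hi)
                    )
                )
            )
        return out


_STATUS_NAMES = {
    _engine.STATUS_REACHED_CELLS: "reached_cells",
    _engine.STATUS_REACHED_TIME: "reached_time",
    _engine.STATUS_EXTINCT: "extinct",
    _engine.STATUS_MUTANT_EXTINCT: "mutant_extinct",
    _engine.STATUS_CAPACITY: "capacity",
}


def _state_from_traits(
    trait_rows: Sequence[Sequence[Traits]],
    mutant_flags: Sequence[Sequence[bool]] | None = None,
    time: float = 0.0,
) -> SimState:
    sc, sg, mut, starts = [], [], [], [0]
    for j, row in enumerate(trait_rows):
        for p, tr in enumerate(row):
            sc.append(tr.s_c)
            sg.append(tr.s_g)
            mut.append(bool(mutant_flags[j][p]) if mutant_flags is not None else False)
        starts.append(len(sc))
    return SimState(
        s_c=np.array(sc, dtype=float),
        s_g=np.array(sg, dtype=float),
        is_mutant=np.array(mut, dtype=np.uint8),
        clock=np.full(len(sc), -1.0),  # negative: engine draws fresh clocks
        fil_start=np.array(starts, dtype=np.int64),
        time=time,
    )


def single_cell_state(traits: Traits = Traits()) -> SimState:
    """One filament containing one cell with the given phenotype."""
    return _state_from_traits([[traits]])


def filament_state(cell_traits: Sequence[Traits]) -> SimState:
    """One filament with the given per-cell phenotypes, in order."""
    return _state_from_traits([list(cell_traits)])


def mutant_invasion_state(
    life_cycle: LifeCycle, mutant: Traits, position: int | None = None, rng=None
) -> SimState:
    """The extinction-assay start: one filament of N/2 ancestral cells
    with exactly one mutant cell (tagged) at ``position`` (uniform random
    if None)."""
    size = life_cycle.N // 2
    if size < 1:
        raise ValueError("N/2 must be at least one cell")
    if position is None:
        position = int((rng or np.random.default_rng()).integers(size))
    if not 0 <= position < size:
        raise ValueError(f"mutant position {position} outside filament of {size}")
    row = [Traits() for _ in range(size)]
    row[position] = mutant
    flags = [[p == position for p in range(size)]]
    return _state_from_traits([row], flags)


def step_simulation(
    state: SimState,
    life_cycle: LifeCycle,
    env: Environment,
    stop: StopCondition,
    seed: int,
    p_m: float = 0.0,
    mutation_scale: float = 0.05,
    trait_bound: float = 0.2,
    coupled_signs: bool = True,
    mutate_daughter_only: bool = False,
    use_sc_rate: bool = True,
    use_sg_survival: bool = True,
    sample_times: np.ndarray | None = None,
    level_cells: np.ndarray | None = None,
    log_waits: int = 0,
    log_fragmentations: int = 0,
) -> SimState:
    """Run the next-event loop from ``state`` until ``stop`` triggers.

    All randomness (clocks, survival draws, mutations) comes from the
    single integer ``seed``; identical seed, state and configuration give
    an identical event sequence.  Returns a new ``SimState``; the input
    is not modified.
    """
    ps_x = survival_probability(life_cycle.daughter_size, env)
    stop_cells = stop.max_cells if stop.max_cells is not None else 2**62
    # Large finite sentinel: the kernel is compiled with fastmath, which
    # assumes finite floats in comparisons.
    stop_time = stop.max_time if stop.max_time is not None else 1e300
    cap = max(4096, 2 * (stop_cells if stop.max_cells is not None else state.n_cells * 64))

    while True:
        (
            status,
            t,
            n_cells,
            n_mut,
            n_fil,
            sc,
            sg,
            mut,
            alive,
            fil,
            pos,
            clock,
            wait_log,
            frag_t,
            frag_s,
            ser_c,
            ser_f,
            lev_t,
            lev_f,
        ) = _engine.run_growth(
            state.s_c,
            state.s_g,
            state.is_mutant.astype(np.uint8),
            state.clock,
            state.fil_start,
            life_cycle.N,
            life_cycle.k,
            ps_x,
            state.time,
            stop_cells,
            stop_time,
            stop.on_mutant_extinct,
            p_m,
            mutation_scale,
            trait_bound,
            coupled_signs,
            mutate_daughter_only,
            use_sc_rate,
            use_sg_survival,
            DIVISION_SD,
            int(seed) & 0x7FFFFFFF,
            int(cap),
            sample_times if sample_times is not None else np.empty(0),
            level_cells.astype(np.int64)
            if level_cells is not None
            else np.empty(0, dtype=np.int64),
            int(log_waits),
            int(log_fragmentations),
        )
        if status != _engine.STATUS_CAPACITY:
            break
        cap *= 2  # deterministic retry: same seed reproduces the same stream

    # Repack the survivors into contiguous filament order.
    live = alive.astype(bool)
    order = np.lexsort((pos[live], fil[live]))
    idx = np.nonzero(live)[0][order]
    fil_sorted = fil[idx]
    boundaries = np.nonzero(np.diff(fil_sorted))[0] + 1
    starts = np.concatenate(([0], boundaries, [idx.size])) if idx.size else np.array([0])
    return SimState(
        s_c=sc[idx],
        s_g=sg[idx],
        is_mutant=mut[idx],
        clock=clock[idx],
        fil_start=starts.astype(np.int64),
        time=float(t),
        status=_STATUS_NAMES[status],
        division_waits=wait_log,
        fragmentation_times=frag_t,
        fragmentation_survivors=frag_s,
        sampled_cells=ser_c,
        sampled_filaments=ser_f,
        level_times=lev_t,
        level_filaments=lev_f,
    )


def subsample_filaments(
    state: SimState, fraction: float, rng: np.random.Generator
) -> SimState:
    """Keep ``ceil(fraction * n_filaments)`` filaments, chosen uniformly
    without replacement (no size weighting); cells keep their phenotypes
    and pending clocks."""
    n_fil = state.n_filaments
    keep = max(1, math.ceil(fraction * n_fil))
    chosen = np.sort(rng.choice(n_fil, size=keep, replace=False))
    idx_parts, starts = [], [0]
    for j in chosen:
        lo, hi = state.fil_start[j], state.fil_start[j + 1]
        idx_parts.append(np.arange(lo, hi))
        starts.append(starts[-1] + (hi - lo))
    idx = np.concatenate(idx_parts)
    return SimState(
        s_c=state.s_c[idx],
        s_g=state.s_g[idx],
        is_mutant=state.is_mutant[idx],
        clock=state.clock[idx],
        fil_start=np.array(starts, dtype=np.int64),
        time=state.time,
        status="subsampled",
    )


@dataclass(frozen=True)
class ExtinctionEstimate:
    """Mutant-lineage extinction assay summary."""

    mean: float
    sd: float
    sample_fractions: np.ndarray
    n_samples: int
    reps_per_sample: int


def estimate_extinction_rate(
    life_cycle: LifeCycle,
    env: Environment,
    traits: Traits,
    reps_per_sample: int = 10,
    n_samples: int = 10,
    seed: int = 0,
    target_cells: int = 1000,
) -> ExtinctionEstimate:
    """Fraction of mutant lineages that die out before the population
    reaches ``target_cells``.

    Each replicate starts from one filament of N/2 cells containing a
    single mutant cell at a uniformly random position; the run ends when
    the population reaches ``target_cells`` (mutant survived) or the
    tagged lineage disappears (extinction).  Replicates are grouped into
    ``n_samples`` samples of ``reps_per_sample``; the mean and standard
    deviation are taken over the per-sample extinct fractions.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    fractions = np.empty(n_samples)
    stop = StopCondition(max_cells=target_cells, on_mutant_extinct=True)
    for s in range(n_samples):
        extinct = 0
        for _ in range(reps_per_sample):
            state = mutant_invasion_state(life_cycle, traits, rng=rng)
            out = step_simulation(
                state,
                life_cycle,
                env,
                stop,
                seed=int(rng.integers(2**31)),
            )
            if out.n_mutants == 0:
                extinct += 1
        fractions[s] = extinct / reps_per_sample
    return ExtinctionEstimate(
        mean=float(fractions.mean()),
        sd=float(fractions.std(ddof=1)) if n_samples > 1 else 0.0,
        sample_fractions=fractions,
        n_samples=n_samples,
        reps_per_sample=reps_per_sample,
    )


def cell_clock_rate(s_c: float = 0.0, sd: float = DIVISION_SD) -> float:
    """Euler–Lotka growth rate of a free cell population whose division
    waits are Normal(1/(1+s_c), sd).

    Solves ``2 E[exp(-r T)] = 1``, i.e. ``r mu - r^2 sd^2 / 2 = ln 2``
    (taking the smaller quadratic root, the one continuous in sd -> 0,
    where it reduces to ``ln(2) (1 + s_c)``).  Truncation of the clock at
    1e-6 is negligible at these parameter values.
    """
    mu = 1.0 / (1.0 + s_c)
    disc = mu * mu - 2.0 * sd * sd * math.log(2.0)
    if disc <= 0:
        raise ValueError("division-time spread too large for a real growth rate")
    # conjugate form of the smaller quadratic root: stable as sd -> 0
    return 2.0 * math.log(2.0) / (mu + math.sqrt(disc))


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Simulated lineage growth rate, in analytic time units."""

    rate: float
    ci_low: float
    ci_high: float
    raw_slope: float  # per simulation time unit, before conversion
    n_surviving: int
    n_reps: int
    per_rep: np.ndarray


def stochastic_growth_rate(
    life_cycle: LifeCycle,
    env: Environment,
    traits: Traits,
    reps: int = 100,
    seed: int = 0,
    max_cells: int = 20000,
    dilution: float = 0.05,
    burn_in: int = 10,
    horizon: float = 2000.0,
    n_bootstrap: int = 2000,
) -> GrowthRateEstimate:
    """Estimate lambda_g from log population growth in a serial-dilution
    culture.

    A population founded by a single clonal cell keeps its division
    phases correlated for many generations, which biases any short-run
    slope; the estimator therefore maintains one continuously growing
    culture, repeatedly diluted: grow to ``max_cells``, uniformly
    subsample a ``dilution`` fraction of filaments, and repeat.  After
    ``burn_in`` growth phases (discarded while the size and phase
    structure equilibrates), each subsequent growth phase is a replicate
    contributing a two-point fit of log cell count against time over that
    phase; consecutive phases start and end at first crossings of
    ``max_cells``, so the endpoints sit at matched phases of the
    fragmentation cycle.  Slopes are converted to the analytic clock (see
    :func:`cell_clock_rate`) and averaged; the 95% interval is a
    bootstrap over replicate phases.  ``horizon`` bounds each phase in
    time so non-growing configurations terminate.  Raises
    ``ArithmeticError`` if the culture cannot be kept alive.

    The ``dilution`` default keeps each phase's starting population large
    enough (about a thousand cells) that the downward log-growth bias
    from demographic fluctuations — roughly half the per-phase increase
    in Var(log population), inversely proportional to the starting
    filament count — stays well below the interval width.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    def stop_for(state: SimState) -> StopCondition:
        return StopCondition(max_cells=max_cells, max_time=state.time + horizon)

    slopes: list[float] = []
    state = None
    for _attempt in range(50):
        state = single_cell_state(traits)
        phase = 0
        while phase < burn_in + reps:
            if phase > 0:
                state = subsample_filaments(state, dilution, rng)
            t0, n0 = state.time, state.n_cells
            state = step_simulation(
                state, life_cycle, env, stop_for(state), seed=int(rng.integers(2**31))
            )
            if state.extinct:
                break
            if state.status != "reached_cells":
                raise ArithmeticError(
                    "population failed to reach the measurement size within "
                    f"the time horizon (status {state.status!r})"
                )
            if phase >= burn_in:
                slopes.append(math.log(state.n_cells / n0) / (state.time - t0))
            phase += 1
        if phase >= burn_in + reps:
            break
        slopes.clear()  # culture died: restart from a fresh founder
    if not slopes:
        raise ArithmeticError("all replicates went extinct; no growth-rate estimate")
    slopes = np.asarray(slopes)
    # Convert simulation time (division-timer units) to analytic units in
    # which the ancestral cell rate is lambda_c = 1.
    conversion = (1.0 + traits.s_c) / cell_clock_rate(traits.s_c)
    rates = slopes * conversion
    point = float(rates.mean())
    boot = rng.choice(rates, size=(n_bootstrap, rates.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return GrowthRateEstimate(
        rate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        raw_slope=float(slopes.mean()),
        n_surviving=int(rates.size),
        n_reps=reps,
        per_rep=rates,
    )
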