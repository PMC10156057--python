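# Methods

`filacycle` models the simplest clonal multicellular life cycle: a
filament of cells (think filamentous cyanobacteria) grows by cell
division to a fixed adult size of N cells and then fragments into k
equal daughters of x = N/k cells each, with k any divisor of N from 2
(binary fission) to N (complete dissociation into single cells).
Selection acts twice per cycle: continuously, through the division rate
of cells, and at fragmentation, when each daughter filament survives
with a size-dependent probability.

## Survival selection

The survival function is a shifted, scaled sigmoid

    p_s(x) = c / (1 + exp(-a (x - b))) - d,

clamped to [0, 1] (the raw form can leave the unit interval for extreme
parameters; probabilities must not).  The steepness `a` sets how steeply
survival rises with daughter size and `b` shifts the curve, effectively
setting survival of unicellular daughters.  Following the source
model's convention, `c = 1.7` and `d = 0.9` are fixed (the sigmoid then
saturates at `c - d = 0.8`) and environments are points in the (a, b)
plane.  Two presets matter throughout:

| preset | a | b | favours |
|---|---|---|---|
| `E_B` | 0.40 | 0 | binary fission (k = 2) |
| `E_C` | 0.89 | -4 | complete dissociation (k = 16) |

A `linear` variant (`clamp(a (x - b), 0, 1)`) is provided mainly as a
control (a steep ramp gives survival identically 1).  A
`modified_sigmoid` variant is accepted by the `Environment` type for
forward compatibility but has no defined parameterisation in this
release and raises on evaluation rather than guessing one.

Mutants carry two traits: `s_c` multiplies the cell division rate
(cells divide at rate `lambda_c (1 + s_c)`), and `s_g` multiplies
daughter survival, `clamp(p_s(x)(1 + s̄_g), 0, 1)`, where `s̄_g` is the
mean group trait over the fragment's cells.  Altruistic mutations have
`s_c < 0, s_g > 0`; selfish mutations the reverse.  The evolutionary
mutation kernel bounds both traits to [-0.2, 0.2], which keeps effective
survival strictly below 1 in the preset environments.

## Life-cycle fitness: multitype branching process

The expected number `z_i` of filaments of size i (i = 1..N-1; size-N
filaments fragment instantaneously and are never represented) obeys
`z' = zM` with a transition-rate matrix `M` whose growth band is
`m[i, i+1] = -m[i, i] = i` and whose last row returns mass to the
daughter size: `m[N-1, x] = (N-1) k p_s(x)`.  Fitness is the dominant
eigenvalue of `M` (real by Perron–Frobenius; the matrices are at most
31x31, so a dense eigen-solve is used without exploiting sparsity).
`ode_growth_oracle` provides an independent check by integrating
`z' = zM` (DOP853, rtol 1e-12, in 12 renormalised chunks to a default
t_max of 120, long enough that sub-dominant modes decay below the 1e-6
comparison tolerance) and reading the late-time slope of the log total.
The `fitness_landscape` sweep evaluates every divisor k >= 2 per (a, b)
point and reports the argmax, breaking eigen-solver-noise ties (within
1e-9) toward smaller k so output is deterministic.

## Closed-form mutant adaptation

Treating one life-cycle iteration as a renewal event:

    f        = (1 + s_g) p_s(x) k          surviving daughters per cycle
    tau      = ln k / (lambda_c (1 + s_c)) cycle time
    lambda_g = ln f / tau                  lineage growth rate
    w        = (1 + s_c)(1 + ln(1 + s_g) / ln f_anc)

with `f_anc = k p_s(x)` the resident's offspring number.  The exact-log
form of `w` is the default everywhere; the first-order approximation
`(1 + s_c)(1 + s_g/ln f_anc)` is available behind an explicit flag and
never silently substituted.  `lambda_c` defaults to 1, fixing the unit
of time; the initial mutant proportion defaults to p = 1/1000.

Mutant frequency follows logistic dynamics with selection intensity
`lambda_g^anc (w - 1)`; the takeover time to a threshold P is
`ln[P/(1-P) * (1-p)/p] / (lambda_g (w - 1))`, infinite when w <= 1
(maps over trait space need a total function, so w <= 1 yields rate 0
rather than an error).  The single-channel selection intensities

    cell channel  (s_g = 0): (lambda_c / ln k) ln(f_anc) s_c
    group channel (s_c = 0): (lambda_c / ln k) ln(1 + s_g)

coincide for matched effects `ln(1+s_g) = s_c` exactly when
`f_anc = e ≈ 2.7`: below e surviving daughters, improving group survival
pays more than improving cell division rate.  These shortcut forms are
required (and tested) to agree with `lambda_g (w - 1)` computed from the
general expressions to 1e-12 — the binding contract that resolves any
ambiguity in their algebraic layout.

Spread-region fractions — the share of the altruistic quadrant
[-0.2, 0] x [0, 0.2] (or the mirrored selfish quadrant) where w > 1 —
are measured on a cell-midpoint uniform grid, 500x500 by default, with a
strict inequality so the measure-zero neutral boundary never counts.
Doubling the resolution moves the result by well under 0.1 percentage
points.

## Stochastic engine

The agent simulation tracks every cell: a phenotype, a lineage tag, and
an absolute next-division time drawn from Normal(mean 1/(1+s_c),
sd 0.1), truncated below at 1e-6 — only the mean scales with `s_c`, the
spread stays 0.1.  A binary min-heap over division times drives the
next-event loop (compiled with numba; stale heap entries of dead cells
are skipped lazily, and cell slots are never reused within a run).  The
daughter is inserted adjacent to its mother, so filaments remain
contiguous runs of related cells; on reaching size N — within the same
event as the triggering division — the filament splits into k contiguous
fragments, each surviving an independent uniform draw against
`clamp(p_s(x)(1 + s̄_g), 0, 1)`.  Surviving cells keep their pending
clocks (fragmentation does not resynchronise division).  Stop rules are
structured (cell-count target, time horizon, tagged-lineage extinction)
and checked after the event fully resolves.  A single integer seed fixes
the entire event sequence.

### Time units and the division-timer clock

The analytic theory measures time so the ancestral cell population
e-folds at rate `lambda_c = 1`.  The simulation's clock is a
near-deterministic timer with mean interval 1, under which a free cell
population grows at the Euler–Lotka rate r solving `2 E[e^{-rT}] = 1`,
i.e. `r mu - r^2 sd^2/2 = ln 2` — about 0.6956, not 1.  Simulated slopes
are therefore converted to analytic units by `(1 + s_c)/r(s_c)`.  With
that conversion the simulation's long-run growth rate matches the
closed-form `lambda_g` to better than 0.1% in high-survival settings
(the `E_C` combinations) and sits a reproducible 0.2–0.4% below it in
low-survival ones (`E_B`): the closed form is a renewal approximation,
and whole-fragment mortality is where it is roughest.

### Growth-rate estimation

A population founded by one clonal cell keeps its division phases
correlated for far longer than any feasible simulation (phase spread
grows only as sd * sqrt(generations)), which biases short-run slopes by
up to several percent.  `stochastic_growth_rate` therefore measures a
serial-dilution culture: grow to 2e4 cells, keep a uniform 2% of
filaments, repeat.  The first 10 phases are discarded as burn-in; each
later phase contributes one replicate slope of log cell count over the
phase (endpoints sit at first crossings of the cell-count target, hence
at matched phases of the fragmentation cycle).  The point estimate is
the replicate mean and the interval is a bootstrap over phases.  In the
validation battery the six-combination simultaneous check uses 99%
intervals — six independent 95% intervals would jointly fail roughly one
run in four by chance.

### Extinction assay

Each replicate starts from one filament of N/2 cells containing exactly
one mutant cell at a uniformly random position (the filament is the
whole population; nothing else is modelled, so a resident background
would be inert anyway) and runs until 1000 cells or loss of the tagged
lineage.  Replicates are grouped into 10 samples of 10; the summary is
the mean and standard deviation of per-sample extinct fractions.  A
caveat worth stating: with the preset parameters, complete dissociation
in `E_B` faces single-cell survival p_s(1) = 0.118, which pins its
lineage-extinction probability near 0.8 — higher than binary fission's,
so the often-quoted "binary fission loses mutants more often" ordering
holds in `E_C` but genuinely reverses in `E_B` under this model.

## Serial-passage evolution

Populations grow to a carrying capacity of 1e5 cells (checked after each
division event), then 1% of filaments — sampled uniformly, without size
weighting — reseed the next transfer; cells retain traits and pending
clocks across the bottleneck.  At each division a mutation occurs with
probability p_m = 0.01, hitting mother or daughter with equal
probability (a switch restricts it to the daughter).  A mutation
replaces the cell's phenotype: |s_c| and |s_g| are independent
Exp(rate 20) draws (mean 0.05 — a rate-20 reading; a mean-20 reading
would clip essentially every draw at the 0.2 bound) clipped to 0.2,
with the sign of s_c uniform and s_g opposite by default (every mutant
is altruistic or selfish; an independent-signs switch exists for
sensitivity analysis).  Populations start from a single ancestral cell.
Per transfer the trajectory records cell-weighted mean traits and
mutant-class proportions; a population's final classification reads the
signs of its last-transfer means: altruistic (-, +), selfish (+, -),
polymorphic when coexisting opposite-sign classes pull both means to
the same side (both positive, or the mirror case of both negative), and
ancestral inside a 1e-3 dead band.  Neutral-control switches can sever
either trait's selection pathway (clocks ignoring s_c, survival draws
ignoring s_g) to verify that mutation-drift alone is directionless.

Seeding is hierarchical (`numpy.random.SeedSequence`): the master seed
spawns one stream per population, which supplies engine seeds and
bottleneck draws, so ensembles are reproducible and populations
independent.

## Problem sizes used in the checks

The validation suite runs scaled-down ensembles chosen for desk-scale
reproducibility: growth-rate validation uses 200 replicate phases per
combination at 2e4 cells; extinction curves use 100 replicates per
(k, environment, s_g) point; evolutionary direction uses 20 populations
x 50 transfers at the full 1e5-cell carrying capacity, asserting the
sign structure of final trait means (in at least 80% of populations)
rather than exact trajectories, which at the source's scale (100
populations, unprinted horizon) are intrinsically stochastic.

## Known limitations

- Even fragmentation only; uneven or mixed fragmentation patterns,
  cell death as a link-severing mechanism, and aggregative group
  formation are out of scope.
- The analytic layer is deterministic renewal theory: it ignores
  demographic stochasticity (handled by the stochastic modules) and
  treats the resident as an infinite exponential background.
- The division-timer simulation agrees with the analytic growth rate
  asymptotically; finite single-founder populations show transient
  synchrony effects, which the estimators above are designed around.
- `modified_sigmoid` selection is declared but not parameterised.
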