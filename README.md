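# filacycle

Fitness and adaptation of filamentous multicellular life cycles that
reproduce by even fragmentation.

Early multicellular organisms — filamentous cyanobacteria are the
motivating example — grow as chains of cells to a fixed adult size N and
then fragment into k equal daughter filaments of N/k cells.  Binary
fission (k = 2) and complete dissociation into single cells (k = N) are
the extremes of the same one-parameter family.  `filacycle` asks how
this single life-cycle parameter shapes later evolution: which
fragmentation mode is fittest in a given environment, and whether
mutations that trade cell growth against group survival — altruistic
(slower cells, hardier groups) or selfish (faster cells, frailer
groups) — can spread, how fast, and which kind eventually dominates.

The package is aimed at researchers in the evolution of multicellularity
who want a complete, seedable implementation of this model family: the
closed forms for desk calculations, and the agent-based engine for
everything the closed forms idealise away.

## Model core

Daughter filaments of x cells survive fragmentation with probability

    p_s(x) = c / (1 + e^{-a(x-b)}) - d,            clamped to [0, 1],

with c = 1.7, d = 0.9 fixed and (a, b) defining the selective
environment (presets: `E_B` = (0.4, 0) favouring binary fission,
`E_C` = (0.89, -4) favouring complete dissociation).  A life cycle's
fitness is the dominant eigenvalue of the multitype branching process
z' = zM over filament sizes 1..N-1.  A mutant with traits (s_c, s_g)
produces f = (1+s_g) p_s(x) k surviving daughters per cycle of duration
tau = ln k / (lambda_c (1+s_c)), grows as lambda_g = ln f / tau, and has
relative fitness

    w = (1 + s_c) (1 + ln(1+s_g) / ln f_anc),      f_anc = k p_s(x),

so the two trait channels balance exactly at f_anc = e ≈ 2.7: below e
surviving daughters per cycle, group survival is the more valuable
currency; above it, cell growth rate.  The stochastic layer simulates
every cell (division timers Normal(1/(1+s_c), 0.1), whole-fragment
survival draws) and the evolution layer runs serial-passage experiments
(grow to 1e5 cells, bottleneck 1% of filaments, recurrent tradeoff
mutations with |s| ~ Exp(20) clipped to 0.2).

## Worked example

```python
from filacycle import (
    AncestorModel, Environment, LifeCycle, Traits,
    long_term_growth_rate, lineage_growth_rate, relative_fitness,
    takeover_time, spread_region_fraction,
)

env = Environment.preset("E_B")         # favours binary fission
lc = LifeCycle(N=16, k=2)
anc = AncestorModel(lc, env)

print(long_term_growth_rate(lc, env))   # 0.5415564889134746
print(anc.f_ancestor)                   # 1.466836542491001
print(lineage_growth_rate(anc, Traits()))  # 0.5527081126769803

mutant = Traits(s_c=0.0, s_g=0.1)       # pure group-survival benefit
print(relative_fitness(anc, mutant))    # 1.2487814464744367
print(takeover_time(anc, mutant))       # 50.22965659563191
print(spread_region_fraction(anc, "altruistic"))  # 77.1388
```

Reading the numbers: in `E_B` the k = 2 life cycle grows at 0.542 per
unit time (eigenvalue fitness; the renewal approximation gives 0.553);
the resident expects f ≈ 1.47 surviving daughters per cycle, so a 10%
group-survival mutant is 24.9% fitter and needs about 50 time units to
go from 0.1% to half the population.  77.14% of the altruistic quadrant
(s_c in [-0.2, 0], s_g in [0, 0.2]) can invade this life cycle.

The same machinery is scriptable from the shell:

```bash
filacycle fitness --N 16 --k 2 --env E_B
filacycle spread-area --k 16 --env E_C --quadrant altruistic --grid 500
filacycle landscape --N 16 --out landscape.csv
filacycle extinct --k 16 --env E_C --sg 0.1 --seed 42 --out ext.csv
filacycle evolve --k 2 --env E_B --transfers 50 --populations 20 --seed 7 --out traj.csv
```

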