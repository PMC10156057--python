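"""Compiled event-driven kernel for filament growth simulations.

The kernel tracks individual cells in flat arrays.  Every cell carries a
phenotype (s_c, s_g), a lineage tag, and an absolute next-division time
drawn from a truncated normal clock; a binary min-heap over division
times drives the next-event loop.  When a filament reaches the adult
size N it fragments instantaneously into k contiguous runs of N/k cells;
each fragment survives an independent uniform draw against
clamp(p_s(x) * (1 + mean s_g), 0, 1), and the cells of failed fragments
die in whole-fragment units.  Cell slots are never reused within one run,
so stale heap entries are skipped lazily via the alive flag.

Exposed through :mod:`filacycle.stochastic`; not part of the public API.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Status codes returned by run_growth.
STATUS_REACHED_CELLS = 0
STATUS_REACHED_TIME = 1
STATUS_EXTINCT = 2
STATUS_MUTANT_EXTINCT = 3
STATUS_CAPACITY = 4

MIN_WAIT = 1e-6  # division clocks truncated below at this wait


@njit(cache=True, fastmath=True)
def _heap_push(ht, hi, n, t, i):
    # hole-style sift-up: move parents down, place once
    j = n
    while j > 0:
        parent = (j - 1) >> 1
        if ht[parent] <= t:
            break
        ht[j] = ht[parent]
        hi[j] = hi[parent]
        j = parent
    ht[j] = t
    hi[j] = i
    return n + 1


@njit(cache=True, fastmath=True)
def _heap_pop(ht, hi, n):
    t = ht[0]
    i = hi[0]
    n -= 1
    tl = ht[n]
    il = hi[n]
    j = 0
    while True:
        left = 2 * j + 1
        if left >= n:
            break
        small = left
        right = left + 1
        if right < n and ht[right] < ht[left]:
            small = right
        if ht[small] >= tl:
            break
        ht[j] = ht[small]
        hi[j] = hi[small]
        j = small
    if n > 0:
        ht[j] = tl
        hi[j] = il
    return t, i, n


@njit(cache=True, fastmath=True)
def _grow_f64(a):
    b = np.empty(2 * a.shape[0])
    b[: a.shape[0]] = a
    return b


@njit(cache=True, fastmath=True)
def _grow_i64(a):
    b = np.empty(2 * a.shape[0], dtype=np.int64)
    b[: a.shape[0]] = a
    return b


@njit(cache=True, fastmath=True)
def _grow_u8(a):
    b = np.zeros(2 * a.shape[0], dtype=np.uint8)
    b[: a.shape[0]] = a
    return b


@njit(cache=True, fastmath=True)
def _grow_2d_i64(a):
    b = np.empty((2 * a.shape[0], a.shape[1]), dtype=np.int64)
    b[: a.shape[0], :] = a
    return b


@njit(cache=True, fastmath=True)
def _draw_wait(mean, sd):
    w = mean + sd * np.random.standard_normal()
    if w < MIN_WAIT:
        w = MIN_WAIT
    return w


@njit(cache=True, fastmath=True)
def run_growth(
    init_sc,
    init_sg,
    init_mut,
    init_clock,  # absolute next-division times; negative => draw fresh
    init_fil_start,  # filament boundaries: cells [start[j], start[j+1]) form filament j
    N,
    k,
    ps_x,  # baseline survival probability of a daughter of size x = N/k
    t0,
    stop_cells,  # stop once alive cells >= this (use huge value to disable)
    stop_time,  # stop at this absolute time (use huge value to disable)
    stop_on_mutant_extinct,
    p_m,  # per-division mutation probability
    mut_scale,  # exponential scale (1/rate) of trait-magnitude draws
    trait_bound,
    coupled_signs,  # s_g takes the sign opposite s_c (tradeoff kernel)
    mutate_daughter_only,
    use_sc_rate,  # False: division clocks ignore s_c (neutral control)
    use_sg_survival,  # False: survival draws ignore s_g (neutral control)
    sd_wait,
    seed,
    cap_cells,
    sample_times,  # population size is recorded just before each of these
    level_cells,  # first-crossing times of these cell counts are recorded
    max_wait_log,  # capacity of the division-wait log (0 disables)
    max_frag_log,  # capacity of the fragmentation log (0 disables)
):
    np.random.seed(seed)
    x = N // k

    n_init = init_sc.shape[0]
    cap = cap_cells
    sc = np.empty(cap)
    sg = np.empty(cap)
    mut = np.zeros(cap, dtype=np.uint8)
    alive = np.zeros(cap, dtype=np.uint8)
    fil = np.empty(cap, dtype=np.int64)
    pos = np.empty(cap, dtype=np.int64)
    clock = np.empty(cap)

    n_init_fil = init_fil_start.shape[0] - 1
    cap_f = (cap // max(N - x, 1) + 2) * k + n_init_fil + 64
    fcells = np.empty((cap_f, N), dtype=np.int64)
    fsize = np.zeros(cap_f, dtype=np.int64)
    falive = np.zeros(cap_f, dtype=np.uint8)

    ht = np.empty(2 * cap + 16)
    hi = np.empty(2 * cap + 16, dtype=np.int64)
    heap_n = 0

    # Logs.
    wait_log = np.empty(max_wait_log)
    n_wait_log = 0
    frag_time_log = np.empty(max_frag_log)
    frag_surv_log = np.empty(max_frag_log, dtype=np.int64)
    n_frag_log = 0
    ns = sample_times.shape[0]
    series_cells = np.full(ns, -1, dtype=np.int64)
    series_fils = np.full(ns, -1, dtype=np.int64)
    sp = 0
    nlev = level_cells.shape[0]
    level_times = np.full(nlev, -1.0)
    level_fils = np.full(nlev, -1, dtype=np.int64)
    lp = 0

    # Seed the population.
    n_cells = 0
    n_mut = 0
    n_fil = 0
    next_cell = 0
    next_fil = 0
    for j in range(n_init_fil):
        start = init_fil_start[j]
        end = init_fil_start[j + 1]
        size = end - start
        fidx = next_fil
        next_fil += 1
        falive[fidx] = 1
        fsize[fidx] = size
        n_fil += 1
        for p_in in range(size):
            src = start + p_in
            i = next_cell
            next_cell += 1
            sc[i] = init_sc[src]
            sg[i] = init_sg[src]
            mut[i] = init_mut[src]
            alive[i] = 1
            fil[i] = fidx
            pos[i] = p_in
            fcells[fidx, p_in] = i
            if init_clock[src] >= 0.0:
                clock[i] = init_clock[src]
            else:
                mean_i = 1.0 / (1.0 + sc[i]) if use_sc_rate else 1.0
                clock[i] = t0 + _draw_wait(mean_i, sd_wait)
            heap_n = _heap_push(ht, hi, heap_n, clock[i], i)
            n_cells += 1
            if mut[i] != 0:
                n_mut += 1

    t = t0
    status = STATUS_REACHED_TIME
    if n_cells >= stop_cells:
        status = STATUS_REACHED_CELLS
        heap_n = 0  # nothing to do

    while heap_n > 0:
        t_ev, i, heap_n = _heap_pop(ht, hi, heap_n)
        if alive[i] == 0:
            continue
        if t_ev > stop_time:
            t = stop_time
            status = STATUS_REACHED_TIME
            break
        # Flush population-size samples falling strictly before this event.
        while sp < ns and sample_times[sp] < t_ev:
            series_cells[sp] = n_cells
            series_fils[sp] = n_fil
            sp += 1
        t = t_ev

        # Amortised dynamic growth: cell slots are never reused, so the
        # arrays track total divisions, not the live population.
        if next_cell >= cap:
            sc = _grow_f64(sc)
            sg = _grow_f64(sg)
            clock = _grow_f64(clock)
            mut = _grow_u8(mut)
            alive = _grow_u8(alive)
            fil = _grow_i64(fil)
            pos = _grow_i64(pos)
            cap = 2 * cap
        if heap_n + 2 > ht.shape[0]:
            ht = _grow_f64(ht)
            hi = _grow_i64(hi)
        if next_fil + k + 1 > fsize.shape[0]:
            fcells = _grow_2d_i64(fcells)
            fsize = _grow_i64(fsize)
            falive = _grow_u8(falive)

        # Division of cell i: daughter j inherits traits and lineage tag,
        # and is inserted adjacently so filaments stay contiguous runs.
        jcell = next_cell
        next_cell += 1
        sc[jcell] = sc[i]
        sg[jcell] = sg[i]
        mut[jcell] = mut[i]
        alive[jcell] = 1
        if mut[jcell] != 0:
            n_mut += 1

        if p_m > 0.0 and np.random.random() < p_m:
            if mutate_daughter_only or np.random.random() < 0.5:
                target = jcell
            else:
                target = i
            mag_c = np.random.exponential(mut_scale)
            if mag_c > trait_bound:
                mag_c = trait_bound
            mag_g = np.random.exponential(mut_scale)
            if mag_g > trait_bound:
                mag_g = trait_bound
            if np.random.random() < 0.5:
                sign_c = 1.0
            else:
                sign_c = -1.0
            if coupled_signs:
                sign_g = -sign_c
            else:
                if np.random.random() < 0.5:
                    sign_g = 1.0
                else:
                    sign_g = -1.0
            sc[target] = sign_c * mag_c
            sg[target] = sign_g * mag_g
            if mut[target] == 0:
                n_mut += 1
                mut[target] = 1

        fidx = fil[i]
        p_i = pos[i]
        size = fsize[fidx]
        for q in range(size - 1, p_i, -1):
            c = fcells[fidx, q]
            fcells[fidx, q + 1] = c
            pos[c] = q + 1
        fcells[fidx, p_i + 1] = jcell
        fil[jcell] = fidx
        pos[jcell] = p_i + 1
        fsize[fidx] = size + 1
        n_cells += 1

        # Fresh clocks for mother and daughter.
        w_i = _draw_wait(1.0 / (1.0 + sc[i]) if use_sc_rate else 1.0, sd_wait)
        clock[i] = t + w_i
        heap_n = _heap_push(ht, hi, heap_n, clock[i], i)
        w_j = _draw_wait(1.0 / (1.0 + sc[jcell]) if use_sc_rate else 1.0, sd_wait)
        clock[jcell] = t + w_j
        heap_n = _heap_push(ht, hi, heap_n, clock[jcell], jcell)
        if n_wait_log + 2 <= max_wait_log:
            wait_log[n_wait_log] = w_i
            wait_log[n_wait_log + 1] = w_j
            n_wait_log += 2

        # Instantaneous fragmentation at adult size.
        if fsize[fidx] == N:
            survivors = 0
            for frag in range(k):
                base = frag * x
                mean_sg = 0.0
                for q in range(x):
                    mean_sg += sg[fcells[fidx, base + q]]
                mean_sg /= x
                p_surv = ps_x * (1.0 + mean_sg) if use_sg_survival else ps_x
                if p_surv < 0.0:
                    p_surv = 0.0
                elif p_surv > 1.0:
                    p_surv = 1.0
                if np.random.random() < p_surv:
                    g = next_fil
                    next_fil += 1
                    falive[g] = 1
                    fsize[g] = x
                    n_fil += 1
                    survivors += 1
                    for q in range(x):
                        c = fcells[fidx, base + q]
                        fcells[g, q] = c
                        fil[c] = g
                        pos[c] = q
                else:
                    for q in range(x):
                        c = fcells[fidx, base + q]
                        alive[c] = 0
                        n_cells -= 1
                        if mut[c] != 0:
                            n_mut -= 1
            falive[fidx] = 0
            fsize[fidx] = 0
            n_fil -= 1
            if n_frag_log < max_frag_log:
                frag_time_log[n_frag_log] = t
                frag_surv_log[n_frag_log] = survivors
                n_frag_log += 1

        # First-crossing times of the requested population levels.
        while lp < nlev and n_cells >= level_cells[lp]:
            level_times[lp] = t
            level_fils[lp] = n_fil
            lp += 1

        # Stop checks, after the event (division + fragmentation) resolves.
        if n_cells == 0:
            status = STATUS_EXTINCT
            break
        if stop_on_mutant_extinct and n_mut == 0:
            status = STATUS_MUTANT_EXTINCT
            break
        if n_cells >= stop_cells:
            status = STATUS_REACHED_CELLS
            break
    else:
        if n_cells == 0:
            status = STATUS_EXTINCT

    # Flush any remaining sample points not later than the stop time.
    while sp < ns and sample_times[sp] <= t:
        series_cells[sp] = n_cells
        series_fils[sp] = n_fil
        sp += 1

    return (
        status,
        t,
        n_cells,
        n_mut,
        n_fil,
        sc[:next_cell],
        sg[:next_cell],
        mut[:next_cell],
        alive[:next_cell],
        fil[:next_cell],
        pos[:next_cell],
        clock[:next_cell],
        wait_log[:n_wait_log],
        frag_time_log[:n_frag_log],
        frag_surv_log[:n_frag_log],
        series_cells,
        series_fils,
        level_times,
        level_fils,
    )
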