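"""Compiled event kernel: the six stochastic event kinds and the sweep loop.

All state lives in flat arrays (``idx = x * Ly + y``) and neighbourhood
lookups go through a precomputed Moore-neighbour table (``-1`` marks an open
x edge in strip geometry).  A sweep visits every occupied site in a freshly
shuffled permutation and evaluates, in fixed order: decay, diffusion, then
the state-dependent event (association for an unbound replicator;
dissociation then replication for the replicase of a complex).  The clock
advances by dt per sweep and surviving complexes age by one sweep.

Per molecule the sweep consumes one base uniform draw that is chained through
the successive Bernoulli decisions by exact inverse-CDF rescaling
(``u' = (u - p) / (1 - p)`` after a failed test at probability ``p``,
``u' = u / p`` after a success), which preserves the independent-events
semantics while keeping the RNG cost low.  Randomness comes from an explicit
PCG32 state (uint64[2]) so that snapshots can serialise it and resumed runs
replay exactly.
"""

import math

import numpy as np
from numba import njit

# Counter slots
C_ASSOC = 0
C_DISS = 1
C_REPL_R = 2
C_REPL_P = 3
C_DECAY_R = 4
C_DECAY_P = 5
C_DIFF = 6
C_MUT = 7
N_COUNTERS = 8

_DX = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_DY = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)

_MULT = np.uint64(6364136223846793005)
_MASK32 = np.uint64(0xFFFFFFFF)
_INV32 = np.float64(2.3283064365386963e-10)  # 2**-32


def neighbor_table(Lx: int, Ly: int, periodic_x: bool) -> np.ndarray:
    """(n_sites, 8) flat Moore-neighbour indices; -1 beyond an open x edge."""
    x = np.arange(Lx)[:, None, None]
    y = np.arange(Ly)[None, :, None]
    nx = x + _DX[None, None, :]
    ny = (y + _DY[None, None, :]) % Ly
    if periodic_x:
        tab = (nx % Lx) * Ly + ny
    else:
        off = (nx < 0) | (nx >= Lx)
        tab = np.where(off, -1, np.clip(nx, 0, Lx - 1) * Ly + ny)
    return np.ascontiguousarray(tab.reshape(Lx * Ly, 8).astype(np.int32))


@njit(inline="always", cache=True, fastmath=True)
def _next32(rng):
    old = rng[0]
    rng[0] = old * _MULT + rng[1]
    xs = (((old >> np.uint64(18)) ^ old) >> np.uint64(27)) & _MASK32
    rot = old >> np.uint64(59)
    return ((xs >> rot) | (xs << ((np.uint64(32) - rot) & np.uint64(31)))) & _MASK32


@njit(inline="always", cache=True, fastmath=True)
def _rand(rng):
    return np.float64(_next32(rng)) * _INV32


@njit(cache=True)
def draw_u(rng):
    """One uniform [0,1) variate from the kernel RNG (wrapper entry point)."""
    return _rand(rng)


@njit(inline="always", cache=True, fastmath=True)
def _swap_cells(kind, trait, bond, role, age, i, j):
    k = kind[i]; kind[i] = kind[j]; kind[j] = k
    tv = trait[i]; trait[i] = trait[j]; trait[j] = tv
    b = bond[i]; bond[i] = bond[j]; bond[j] = b
    r = role[i]; role[i] = role[j]; role[j] = r
    a = age[i]; age[i] = age[j]; age[j] = a


@njit(inline="always", cache=True, fastmath=True)
def _clear_cell(kind, trait, bond, role, age, i):
    kind[i] = 0
    trait[i] = 0.0
    bond[i] = -1
    role[i] = 0
    age[i] = 0


@njit(inline="always", cache=True, fastmath=True)
def event_decay(kind, trait, bond, role, age, idx, counters):
    """The molecule at idx decays, leaving empty space; a bonded partner
    survives and returns to the unbound state."""
    partner = bond[idx]
    if partner >= 0:
        bond[partner] = -1
        role[partner] = 0
        age[partner] = 0
    if kind[idx] == 1:
        counters[C_DECAY_R] += 1
    else:
        counters[C_DECAY_P] += 1
    _clear_cell(kind, trait, bond, role, age, idx)


@njit(inline="always", cache=True, fastmath=True)
def event_diffusion(kind, trait, bond, role, age, nbr, idx, rng, counters):
    """Move the molecule at idx one Moore step (or, gated on the replicase,
    the whole complex as a rigid pair in a random unit translation).  Moves
    that would disturb another complex are skipped.  Returns the molecule's
    (possibly new) index."""
    partner = np.int64(bond[idx])
    if partner < 0:
        k8 = np.int64(_rand(rng) * 8)
        nidx = nbr[idx, k8]
        if nidx < 0:
            return idx
        if kind[nidx] != 0 and bond[nidx] >= 0:
            return idx  # never disturb a complex
        _swap_cells(kind, trait, bond, role, age, idx, nidx)
        counters[C_DIFF] += 1
        return nidx
    if role[idx] != 1:
        return idx  # complex moves are gated on the replicase member
    k8 = np.int64(_rand(rng) * 8)
    da = nbr[idx, k8]
    db = nbr[partner, k8]
    if da < 0 or db < 0:
        return idx
    if da != partner and kind[da] != 0 and bond[da] >= 0:
        return idx
    if db != idx and kind[db] != 0 and bond[db] >= 0:
        return idx
    if da == partner and db == idx:
        _swap_cells(kind, trait, bond, role, age, idx, partner)
    elif da == partner:
        # chain: partner -> db, replicase -> partner's old site
        _swap_cells(kind, trait, bond, role, age, partner, db)
        _swap_cells(kind, trait, bond, role, age, idx, partner)
    elif db == idx:
        _swap_cells(kind, trait, bond, role, age, idx, da)
        _swap_cells(kind, trait, bond, role, age, partner, idx)
    else:
        _swap_cells(kind, trait, bond, role, age, idx, da)
        _swap_cells(kind, trait, bond, role, age, partner, db)
    bond[da] = np.int32(db)
    bond[db] = np.int32(da)
    counters[C_DIFF] += 1
    return da


@njit(inline="always", cache=True, fastmath=True)
def event_association(kind, trait, bond, role, age, nbr, idx, dt, w_max, u,
                      rng, counters, cand, wts):
    """Attempt complex formation by the unbound replicator at idx, using the
    pre-drawn uniform u for the firing decision.

    Candidate templates are the unbound neighbouring molecules; a replicator
    template weighs 1 (the fixed template rate), a parasite weighs its beta.
    The total propensity is R = k_a * mean(weights) over the free neighbours
    (so a lone replicator template is bound at rate k_a, a lone parasite at
    k_a * beta) and the event fires when u < 1 - exp(-R*dt); the partner is
    then drawn proportionally to its weight.  Returns True if a complex
    formed."""
    ka = trait[idx]
    # 1 - exp(-R*dt) <= R*dt <= ka * w_max * dt: cheap rejection
    if u >= ka * w_max * dt:
        return False
    wsum = 0.0
    nc = 0
    for k8 in range(8):
        nidx = nbr[idx, k8]
        if nidx < 0:
            continue
        nk = kind[nidx]
        if nk == 0 or bond[nidx] >= 0:
            continue
        w = 1.0 if nk == 1 else trait[nidx]
        if w > 0.0:
            cand[nc] = nidx
            wts[nc] = w
            wsum += w
            nc += 1
    if nc == 0:
        return False
    R = ka * wsum / nc
    if u >= -math.expm1(-R * dt):
        return False
    v = _rand(rng) * wsum
    acc = 0.0
    chosen = cand[nc - 1]
    for q in range(nc):
        acc += wts[q]
        if v < acc:
            chosen = cand[q]
            break
    bond[idx] = np.int32(chosen)
    bond[chosen] = np.int32(idx)
    role[idx] = 1
    role[chosen] = 2
    age[idx] = 0
    counters[C_ASSOC] += 1
    return True


@njit(inline="always", cache=True, fastmath=True)
def event_dissociation(kind, trait, bond, role, age, idx, counters):
    """The complex whose replicase sits at idx breaks; both members return to
    the unbound state at their current sites."""
    partner = bond[idx]
    bond[idx] = -1
    role[idx] = 0
    age[idx] = 0
    bond[partner] = -1
    role[partner] = 0
    age[partner] = 0
    counters[C_DISS] += 1


@njit(inline="always", cache=True, fastmath=True)
def event_replication(kind, trait, bond, role, age, nbr, idx, min_age,
                      mu, half_dmu, ka_lo, ka_hi, beta_lo, beta_hi,
                      evolve_ka, evolve_beta, rng, counters, scratch):
    """Template copying by the complex whose replicase sits at idx (the
    copying-rate gate has already fired).

    Eligible only once the complex age has reached the replication duration
    and at least one empty site exists in the template's Moore
    neighbourhood — the copy appears next to the molecule being copied, so a
    template buried in a dense clump of its own kind cannot be replicated.
    The template (not the replicase!) is copied onto a uniformly chosen
    eligible empty site, the copy passes through mutation, and the complex
    breaks.  Returns the offspring kind (0 if ineligible)."""
    if age[idx] < min_age:
        return 0
    partner = np.int64(bond[idx])
    nc = 0
    for k8 in range(8):
        n1 = nbr[partner, k8]
        if n1 >= 0 and kind[n1] == 0:
            scratch[nc] = n1
            nc += 1
    if nc == 0:
        return 0
    tgt = scratch[np.int64(_rand(rng) * nc)]
    tkind = kind[partner]
    tv = trait[partner]
    if (tkind == 1 and evolve_ka) or (tkind == 2 and evolve_beta):
        if mu > 0.0 and _rand(rng) < mu:
            tv += (_rand(rng) * 2.0 - 1.0) * half_dmu
            if tkind == 1:
                lo, hi = ka_lo, ka_hi
            else:
                lo, hi = beta_lo, beta_hi
            if tv < lo:
                tv = lo
            elif tv > hi:
                tv = hi
            counters[C_MUT] += 1
    kind[tgt] = tkind
    trait[tgt] = tv
    bond[tgt] = -1
    role[tgt] = 0
    age[tgt] = 0
    # the complex breaks after replication
    bond[idx] = -1
    role[idx] = 0
    age[idx] = 0
    bond[partner] = -1
    role[partner] = 0
    age[partner] = 0
    if tkind == 1:
        counters[C_REPL_R] += 1
    else:
        counters[C_REPL_P] += 1
    return tkind


@njit(cache=True, fastmath=True)
def run_sweeps(kind, trait, bond, role, age, nbr, periodic_x, mix,
               n_sweeps, dt, p_decay, p_diff, p_diss, p_rho,
               mu, half_dmu, ka_lo, ka_hi, beta_lo, beta_hi,
               min_age, evolve_ka, evolve_beta, stop_no_parasites,
               rng, counters, occ):
    """Run up to n_sweeps sweeps; stops early on total extinction (or, when
    requested, parasite extinction).  Returns (sweeps_done, n_repl, n_par)."""
    n = kind.shape[0]
    w_max = max(1.0, beta_hi)
    n_repl = 0
    n_par = 0
    for i in range(n):
        if kind[i] == 1:
            n_repl += 1
        elif kind[i] == 2:
            n_par += 1
    scratch = np.empty(16, dtype=np.int64)
    cand = np.empty(8, dtype=np.int64)
    wts = np.empty(8, dtype=np.float64)
    sweeps_done = 0
    for _s in range(n_sweeps):
        # occupied-site scan; surviving complexes age by one sweep here,
        # before any event of the new sweep is evaluated
        m = 0
        for i in range(n):
            if kind[i] != 0:
                occ[m] = i
                m += 1
                if role[i] == 1:
                    age[i] += 1
        for i in range(m - 1, 0, -1):
            j = np.int64(_rand(rng) * (i + 1))
            tmp = occ[i]
            occ[i] = occ[j]
            occ[j] = tmp
        for q in range(m):
            idx = np.int64(occ[q])
            k = kind[idx]
            if k == 0:
                continue
            u = _rand(rng)
            if u < p_decay:
                event_decay(kind, trait, bond, role, age, idx, counters)
                if k == 1:
                    n_repl -= 1
                else:
                    n_par -= 1
                continue
            u = (u - p_decay) / (1.0 - p_decay)
            if u < p_diff:
                idx = event_diffusion(kind, trait, bond, role, age, nbr, idx,
                                      rng, counters)
                u = u / p_diff
            else:
                u = (u - p_diff) / (1.0 - p_diff)
            if bond[idx] >= 0:
                if role[idx] == 1:
                    if u < p_diss:
                        event_dissociation(kind, trait, bond, role, age, idx,
                                           counters)
                    else:
                        u = (u - p_diss) / (1.0 - p_diss)
                        if u < p_rho:
                            off = event_replication(
                                kind, trait, bond, role, age, nbr, idx,
                                min_age, mu, half_dmu, ka_lo, ka_hi,
                                beta_lo, beta_hi, evolve_ka, evolve_beta,
                                rng, counters, scratch)
                            if off == 1:
                                n_repl += 1
                            elif off == 2:
                                n_par += 1
            elif k == 1:
                event_association(kind, trait, bond, role, age, nbr, idx, dt,
                                  w_max, u, rng, counters, cand, wts)
        if mix:
            # well-mixed mode: permute the contents of all non-complex sites
            m2 = 0
            for i in range(n):
                if bond[i] < 0:
                    occ[m2] = i
                    m2 += 1
            for i in range(m2 - 1, 0, -1):
                j = np.int64(_rand(rng) * (i + 1))
                if j != i:
                    _swap_cells(kind, trait, bond, role, age, occ[i], occ[j])
        sweeps_done += 1
        if n_repl + n_par == 0:
            break
        if stop_no_parasites and n_par == 0:
            break
    return sweeps_done, n_repl, n_par
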