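"""The stochastic event layer: single-event operations, the sweep, and the
run loop that samples trajectories.

Six event kinds act on the lattice each sweep, converted from continuous
rates to per-step probabilities ``1 - exp(-rate * dt)``:

* association — an unbound replicator binds an unbound neighbour at rate
  k_a times the mean template weight of its free neighbours (replicator
  templates weigh 1, parasites their beta; the partner is drawn
  proportionally to weight);
* dissociation — a complex breaks spontaneously at rate ``k_diss``;
* replication — an old-enough complex with empty space next to the template
  copies the *template* onto such a site (the copy passes through mutation)
  and then breaks;
* mutation — offspring traits shift by U(-delta_mu/2, +delta_mu/2) with
  probability mu, clipped to the trait bounds;
* decay — any molecule vanishes at rate ``d`` (a bonded partner survives,
  unbound);
* diffusion — site contents swap with a neighbour at rate ``D``; complexes
  translate as rigid pairs and moves disturbing another complex are skipped.

The heavy lifting happens in :mod:`repliwave._kernel` (numba); the wrappers
here validate contracts and expose each event for direct testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernel as K
from .core import (EMPTY, REPLICASE, REPLICATOR, LatticeState,
                   SimulationParams, event_probability)
from .observables import TraitSummary, population_counts, trait_distribution


class ContractError(ValueError):
    """An event was applied to a site that violates its precondition."""


@dataclass
class EventCounters:
    """Per-sweep event bookkeeping (also aggregated between samples)."""

    associations: int = 0
    dissociations: int = 0
    replications_replicator: int = 0
    replications_parasite: int = 0
    decays_replicator: int = 0
    decays_parasite: int = 0
    diffusion_moves: int = 0
    mutations: int = 0

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "EventCounters":
        return cls(
            associations=int(arr[K.C_ASSOC]),
            dissociations=int(arr[K.C_DISS]),
            replications_replicator=int(arr[K.C_REPL_R]),
            replications_parasite=int(arr[K.C_REPL_P]),
            decays_replicator=int(arr[K.C_DECAY_R]),
            decays_parasite=int(arr[K.C_DECAY_P]),
            diffusion_moves=int(arr[K.C_DIFF]),
            mutations=int(arr[K.C_MUT]),
        )

    @property
    def replications(self) -> int:
        return self.replications_replicator + self.replications_parasite

    @property
    def decays(self) -> int:
        return self.decays_replicator + self.decays_parasite


def _flat(state: LatticeState):
    return (state.kind.reshape(-1), state.trait.reshape(-1),
            state.bond.reshape(-1), state.role.reshape(-1),
            state.age.reshape(-1))


_NBR_CACHE: dict[tuple[int, int, bool], np.ndarray] = {}


def _nbr_table(state: LatticeState) -> np.ndarray:
    key = (state.Lx, state.Ly, bool(state.periodic_x))
    tab = _NBR_CACHE.get(key)
    if tab is None:
        tab = K.neighbor_table(*key)
        if len(_NBR_CACHE) > 8:
            _NBR_CACHE.clear()
        _NBR_CACHE[key] = tab
    return tab


def _min_age_sweeps(params: SimulationParams) -> int:
    import math
    return max(0, math.ceil(params.dt_repl / params.dt - 1e-9))


def _probs(params: SimulationParams):
    return (event_probability(params.d, params.dt),
            event_probability(params.D, params.dt),
            event_probability(params.k_diss, params.dt),
            event_probability(params.rho, params.dt))


def _check_site(state, site):
    x, y = site
    if not (0 <= x < state.Lx and 0 <= y < state.Ly):
        raise ContractError(f"site {site} outside the lattice")
    return state.site_index(site)


def attempt_association(state: LatticeState, site, params: SimulationParams) -> bool:
    """Complex formation attempt by the unbound replicator at ``site``."""
    idx = _check_site(state, site)
    x, y = site
    if state.kind[x, y] != REPLICATOR:
        raise ContractError(f"site {site} does not hold a replicator")
    if state.bond[x, y] >= 0:
        raise ContractError(f"replicator at {site} is already in a complex")
    counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
    u = K.draw_u(state.rng)
    w_max = max(1.0, params.beta_bounds[1], params.beta_fixed)
    fired = K.event_association(*_flat(state), _nbr_table(state), idx,
                                params.dt, w_max, u, state.rng, counters,
                                np.empty(8, dtype=np.int64),
                                np.empty(8, dtype=np.float64))
    return bool(fired)


def attempt_dissociation(state: LatticeState, site, params: SimulationParams) -> bool:
    """Spontaneous break-up attempt of the complex whose replicase is at ``site``."""
    idx = _check_site(state, site)
    x, y = site
    if state.bond[x, y] < 0:
        raise ContractError(f"site {site} holds no complex member")
    if state.role[x, y] != REPLICASE:
        raise ContractError(f"dissociation is gated on the replicase; {site} is not one")
    counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
    p_diss = event_probability(params.k_diss, params.dt)
    if K.draw_u(state.rng) >= p_diss:
        return False
    K.event_dissociation(*_flat(state), idx, counters)
    return True


def attempt_replication(state: LatticeState, site, params: SimulationParams) -> int:
    """Template-copy attempt by the complex whose replicase is at ``site``.

    Returns the offspring kind (0 if no replication happened)."""
    idx = _check_site(state, site)
    x, y = site
    if state.bond[x, y] < 0 or state.role[x, y] != REPLICASE:
        raise ContractError(f"site {site} is not the replicase of a complex")
    counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
    scratch = np.empty(16, dtype=np.int64)
    p_rho = event_probability(params.rho, params.dt)
    if K.draw_u(state.rng) >= p_rho:
        return 0
    return int(K.event_replication(
        *_flat(state), _nbr_table(state), idx,
        _min_age_sweeps(params), params.mu, params.delta_mu / 2.0,
        params.ka_bounds[0], params.ka_bounds[1],
        params.beta_bounds[0], params.beta_bounds[1],
        params.evolve_ka, params.evolve_beta, state.rng, counters, scratch))


def attempt_decay(state: LatticeState, site, params: SimulationParams) -> bool:
    """Decay attempt on the molecule at ``site``."""
    idx = _check_site(state, site)
    x, y = site
    if state.kind[x, y] == EMPTY:
        raise ContractError(f"site {site} is empty")
    counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
    p_decay = event_probability(params.d, params.dt)
    if K.draw_u(state.rng) >= p_decay:
        return False
    K.event_decay(*_flat(state), idx, counters)
    return True


def attempt_diffusion(state: LatticeState, site, params: SimulationParams) -> tuple[int, int]:
    """Diffusion attempt on the molecule at ``site``; returns its new site."""
    idx = _check_site(state, site)
    x, y = site
    if state.kind[x, y] == EMPTY:
        raise ContractError(f"site {site} is empty")
    counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
    p_diff = event_probability(params.D, params.dt)
    if K.draw_u(state.rng) >= p_diff:
        return (int(idx) // state.Ly, int(idx) % state.Ly)
    new_idx = K.event_diffusion(*_flat(state), _nbr_table(state), idx,
                                state.rng, counters)
    return (int(new_idx) // state.Ly, int(new_idx) % state.Ly)


def mutate_trait(value: float, mu: float, delta_mu: float,
                 bounds: tuple[float, float], rng: np.random.Generator) -> float:
    """Offspring trait mutation: with probability mu add U(-delta_mu/2,
    +delta_mu/2), clipped to the closed bounds; otherwise unchanged."""
    if mu > 0 and rng.random() < mu:
        value = value + rng.uniform(-delta_mu / 2.0, delta_mu / 2.0)
        value = min(max(value, bounds[0]), bounds[1])
    return value


def run_sweeps(state: LatticeState, params: SimulationParams, n_sweeps: int,
               mix: bool = False, stop_no_parasites: bool = False,
               counters: np.ndarray | None = None) -> tuple[int, int, int]:
    """Advance the state by up to ``n_sweeps`` sweeps (in place).

    Returns ``(sweeps_done, n_replicators, n_parasites)``; stops early on
    total extinction, or on parasite extinction when requested.
    """
    if counters is None:
        counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
    p_decay, p_diff, p_diss, p_rho = _probs(params)
    occ = np.empty(state.n_sites, dtype=np.int64)
    done, n_repl, n_par = K.run_sweeps(
        *_flat(state), _nbr_table(state), state.periodic_x, mix,
        n_sweeps, params.dt, p_decay, p_diff, p_diss, p_rho,
        params.mu, params.delta_mu / 2.0,
        params.ka_bounds[0], params.ka_bounds[1],
        params.beta_bounds[0], params.beta_bounds[1],
        _min_age_sweeps(params), params.evolve_ka, params.evolve_beta,
        stop_no_parasites, state.rng, counters, occ)
    state.sweeps += int(done)
    return int(done), int(n_repl), int(n_par)


def sweep(state: LatticeState, params: SimulationParams) -> EventCounters:
    """One full sweep: every occupied site visited once in random order."""
    counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
    run_sweeps(state, params, 1, counters=counters)
    return EventCounters.from_array(counters)


@dataclass
class Trajectory:
    """Time-stamped series of population counts and trait summaries.

    ``counts[i]`` sums to the number of lattice sites at all times.
    ``counters[i]`` aggregates events since the previous sample.  ``extras``
    holds observer outputs (empty-space index, front statistics, ...).
    ``status`` is one of ``completed | extinct``.
    """

    n_sites: int
    times: list[float] = field(default_factory=list)
    counts: list[dict] = field(default_factory=list)
    ka: list[TraitSummary] = field(default_factory=list)
    beta: list[TraitSummary] = field(default_factory=list)
    counters: list[EventCounters] = field(default_factory=list)
    extras: list[dict] = field(default_factory=list)
    status: str = "completed"
    parasite_extinction_t: float | None = None
    final_state: "LatticeState | None" = None

    def __len__(self) -> int:
        return len(self.times)

    @property
    def extinct(self) -> bool:
        return self.status == "extinct"

    @property
    def parasites_extinct(self) -> bool:
        return self.parasite_extinction_t is not None

    def final_counts(self) -> dict:
        return self.counts[-1]

    def ka_median_tail(self, fraction: float = 0.1) -> float:
        """Median of the per-sample k_a medians over the trailing fraction
        of samples (NaN-safe)."""
        k = max(1, int(round(fraction * len(self.times))))
        meds = [s.median for s in self.ka[-k:] if s.n > 0]
        return float(np.median(meds)) if meds else float("nan")

    def beta_median_tail(self, fraction: float = 0.1) -> float:
        k = max(1, int(round(fraction * len(self.times))))
        meds = [s.median for s in self.beta[-k:] if s.n > 0]
        return float(np.median(meds)) if meds else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times):
            c = self.counts[i]
            ka, beta = self.ka[i], self.beta[i]
            ev = self.counters[i]
            row = {
                "t": t,
                "replicators": c["replicators"],
                "parasites": c["parasites"],
                "complexes": c["complexes"],
                "empty": c["empty"],
                "ka_n": ka.n, "ka_q1": ka.q1, "ka_median": ka.median, "ka_q3": ka.q3,
                "beta_n": beta.n, "beta_q1": beta.q1,
                "beta_median": beta.median, "beta_q3": beta.q3,
                "associations": ev.associations,
                "dissociations": ev.dissociations,
                "replications_replicator": ev.replications_replicator,
                "replications_parasite": ev.replications_parasite,
                "decays_replicator": ev.decays_replicator,
                "decays_parasite": ev.decays_parasite,
                "diffusion_moves": ev.diffusion_moves,
                "mutations": ev.mutations,
            }
            for key, val in self.extras[i].items():
                if np.isscalar(val):
                    row[key] = val
            rows.append(row)
        return pd.DataFrame(rows)


def _sample(traj: Trajectory, state: LatticeState, params: SimulationParams,
            counters: np.ndarray, observers) -> None:
    traj.times.append(state.t)
    traj.counts.append(population_counts(state))
    traj.ka.append(trait_distribution(state, "k_a", params.ka_bounds))
    traj.beta.append(trait_distribution(state, "beta", params.beta_bounds))
    traj.counters.append(EventCounters.from_array(counters))
    extra = {}
    for obs in observers:
        out = obs(state)
        if out:
            extra.update(out)
    traj.extras.append(extra)
    counters[:] = 0


def run_simulation(state: LatticeState, params: SimulationParams, t_end: float,
                   observers: Sequence[Callable[[LatticeState], dict]] = (),
                   sample_every: float = 50.0, mix: bool = False,
                   stop_on_parasite_extinction: bool = False) -> Trajectory:
    """Advance ``state`` to ``t_end``, sampling the trajectory on the way.

    Observers are callables ``state -> dict`` merged into the per-sample
    extras.  Extinction terminates the run early with ``status='extinct'``
    (it is recorded, not raised).  Fixed seed implies a reproducible
    trajectory.
    """
    if t_end < state.t:
        raise ValueError("t_end must not precede the current clock")
    counters = np.zeros(K.N_COUNTERS, dtype=np.int64)
    traj = Trajectory(n_sites=state.n_sites)
    had_parasites = population_counts(state)["parasites"] > 0
    _sample(traj, state, params, counters, observers)
    sweeps_per_sample = max(1, int(round(sample_every / params.dt)))
    target_sweeps = int(round(t_end / params.dt))
    while state.sweeps < target_sweeps:
        chunk = min(sweeps_per_sample, target_sweeps - state.sweeps)
        stop_flag = stop_on_parasite_extinction and had_parasites
        done, n_repl, n_par = run_sweeps(state, params, chunk, mix=mix,
                                         stop_no_parasites=stop_flag,
                                         counters=counters)
        _sample(traj, state, params, counters, observers)
        if had_parasites and n_par == 0 and traj.parasite_extinction_t is None:
            traj.parasite_extinction_t = state.t
        if n_repl + n_par == 0:
            traj.status = "extinct"
            break
        if stop_flag and n_par == 0:
            break
        if done < chunk:
            break
    traj.final_state = state
    return traj
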