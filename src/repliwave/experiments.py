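"""Experiment drivers: reproducible, seeded protocols over the event layer.

Each driver wires initial conditions, parameter overrides and observers into
:func:`repliwave.dynamics.run_simulation` and returns a
:class:`~repliwave.dynamics.Trajectory` or a tidy :class:`pandas.DataFrame`.
Sub-seeds for scan replicates are derived as ``seed + replicate_index``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel as _K
from .core import (EMPTY, InitSpec, LatticeState, SimulationParams,
                   ValidationError, init_lattice)
from .dynamics import Trajectory, _sample, run_simulation
from .dynamics import run_sweeps as _run
from .observables import (detect_speciation, empty_space_index,
                          front_statistics)


@dataclass(frozen=True)
class AblationSpec:
    """Periodic large-scale disruption protocol: every ``period`` AUT,
    ``n_patches`` square patches of side ``patch_side`` are emptied at
    uniformly random (torus-wrapped) positions."""

    period: float = 50.0
    n_patches: int = 4
    patch_side: int = 200

    def __post_init__(self):
        if self.period <= 0:
            raise ValidationError("ablation period must be positive")
        if self.n_patches < 0 or self.patch_side < 0:
            raise ValidationError("patch counts and sizes must be non-negative")


@dataclass(frozen=True)
class ScanSpec:
    """Parameter scan descriptor (over beta or dt_repl)."""

    parameter: str
    values: Sequence[float]
    replicates: int = 1
    t_end: float = 5000.0
    L: int | None = None

    def __post_init__(self):
        if self.parameter not in ("beta", "dt_repl"):
            raise ValidationError(f"unknown scan parameter {self.parameter!r}")
        if len(self.values) == 0:
            raise ValidationError("scan grid must be non-empty")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


def run_evolutionary(params: SimulationParams, init_spec: InitSpec,
                     t_end: float, seed: int | None = None,
                     sample_every: float = 50.0,
                     observers=()) -> Trajectory:
    """Evolution of k_a at fixed parasite advantage (or without parasites).

    ``evolve_ka`` must be on and ``evolve_beta`` off; parasites, if present,
    all carry ``params.beta_fixed`` unless the init spec says otherwise.
    """
    if not params.evolve_ka or params.evolve_beta:
        raise ValidationError("run_evolutionary needs evolve_ka=True, evolve_beta=False")
    state = init_lattice(params, init_spec, seed=seed)
    return run_simulation(state, params, t_end, observers=observers,
                          sample_every=sample_every)


def run_to_steady_state(params: SimulationParams, init_spec: InitSpec,
                        t_min: float, t_max: float, block: float,
                        seed: int | None = None, drift_tol: float = 0.02,
                        sample_every: float = 500.0,
                        trait: str = "ka") -> tuple[float, float]:
    """Evolve until the trait median stops drifting, then report it.

    Runs to ``t_min``, then extends in blocks of ``block`` AUT until the
    median of the recent per-sample medians moves by less than ``drift_tol``
    (one histogram bin by default) between blocks, or ``t_max`` is reached.
    Returns ``(final_median, t_reached)``; the median is NaN on extinction.
    """
    state = init_lattice(params, init_spec, seed=seed)
    block_medians: list[float] = []
    t_target = t_min
    while True:
        traj = run_simulation(state, params, t_target,
                              sample_every=sample_every)
        series = traj.ka if trait == "ka" else traj.beta
        meds = [s.median for s in series if s.n > 0]
        if not meds:
            return float("nan"), state.t
        block_medians.append(float(np.median(meds[-10:])))
        if len(block_medians) >= 2 and \
                abs(block_medians[-1] - block_medians[-2]) < drift_tol:
            break
        if t_target >= t_max:
            break
        t_target = min(t_target + block, t_max)
    return block_medians[-1], state.t


def run_beta_scan(params: SimulationParams, scan: ScanSpec, init_spec: InitSpec,
                  seed: int = 0, sample_every: float = 50.0,
                  stop_on_parasite_extinction: bool = False) -> pd.DataFrame:
    """Fixed-beta runs over a grid: one row per (beta, replicate).

    Extinctions are rows with flags, never errors.
    """
    if scan.parameter != "beta":
        raise ValidationError("run_beta_scan requires a beta scan")
    rows = []
    for beta in scan.values:
        p = dataclasses.replace(params, beta_fixed=float(beta),
                                **({"L": scan.L} if scan.L else {}))
        spec = dataclasses.replace(init_spec, beta_init=float(beta))
        for rep in range(scan.replicates):
            run_seed = seed + rep
            state = init_lattice(p, spec, seed=run_seed)
            traj = run_simulation(
                state, p, scan.t_end, sample_every=sample_every,
                stop_on_parasite_extinction=stop_on_parasite_extinction)
            counts = traj.final_counts()
            ka = traj.ka[-1]
            rows.append({
                "beta": float(beta),
                "replicate": rep,
                "seed": run_seed,
                "t_final": traj.times[-1],
                "replicators": counts["replicators"],
                "parasites": counts["parasites"],
                "complexes": counts["complexes"],
                "empty": counts["empty"],
                "ka_median": ka.median,
                "ka_q1": ka.q1,
                "ka_q3": ka.q3,
                "parasites_extinct": counts["parasites"] == 0,
                "extinct": traj.extinct,
                "status": traj.status,
            })
    return pd.DataFrame(rows)


def run_ecological_grid(params: SimulationParams, ka_grid: Sequence[float],
                        beta_grid: Sequence[float], t_measure: float,
                        seed: int = 0, replicates: int = 1,
                        init_spec: InitSpec | None = None,
                        sample_every: float = 50.0) -> pd.DataFrame:
    """Ecological (mutation-free) sweep over (k_a, beta) combinations.

    Mutations are forced off regardless of ``params.mu``; every replicator in
    a grid cell shares one k_a.  Per cell: time-averaged front-contact
    empty-space index and mean occupancy fractions, averaged over the second
    half of the run (extinct cells are flagged).
    """
    eco = dataclasses.replace(params, mu=0.0, evolve_ka=False, evolve_beta=False)
    rows = []
    for ka in ka_grid:
        for beta in beta_grid:
            for rep in range(replicates):
                run_seed = seed + rep
                spec = init_spec or InitSpec(density_replicators=0.2,
                                             density_parasites=0.2)
                spec = dataclasses.replace(spec, ka_init=float(ka),
                                           beta_init=float(beta))
                p = dataclasses.replace(eco, beta_fixed=float(beta))
                state = init_lattice(p, spec, seed=run_seed)
                obs = lambda s: {"esi": empty_space_index(s).index}
                traj = run_simulation(state, p, t_measure, observers=[obs],
                                      sample_every=sample_every)
                # average over the coexistence window only: samples taken
                # after either class has died out measure a different system
                alive = [i for i, c in enumerate(traj.counts)
                         if c["replicators"] > 0 and c["parasites"] > 0]
                half = alive[len(alive) // 2:] if alive else []
                esi = [traj.extras[i]["esi"] for i in half] or [float("nan")]
                n = traj.n_sites
                fr = [traj.counts[i]["replicators"] / n for i in half] or [float("nan")]
                fp = [traj.counts[i]["parasites"] / n for i in half] or [float("nan")]
                fe = [traj.counts[i]["empty"] / n for i in half] or [float("nan")]
                rows.append({
                    "ka": float(ka), "beta": float(beta), "replicate": rep,
                    "esi_mean": float(np.mean(esi)),
                    "frac_replicators": float(np.mean(fr)),
                    "frac_parasites": float(np.mean(fp)),
                    "frac_empty": float(np.mean(fe)),
                    "extinct": traj.extinct,
                    "parasites_extinct": traj.counts[-1]["parasites"] == 0,
                })
    return pd.DataFrame(rows)


def ablate_patches(state: LatticeState, spec: AblationSpec,
                   rng: np.random.Generator) -> LatticeState:
    """Empty ``n_patches`` random axis-aligned squares (torus wrap), in place.

    Bonded partners of ablated molecules that survive outside a patch return
    to the unbound state.
    """
    Lx, Ly = state.Lx, state.Ly
    s = min(spec.patch_side, Lx, Ly)
    mask = np.zeros((Lx, Ly), dtype=bool)
    for _ in range(spec.n_patches):
        x0 = int(rng.integers(0, Lx))
        y0 = int(rng.integers(0, Ly))
        xs = (np.arange(x0, x0 + s)) % Lx
        ys = (np.arange(y0, y0 + s)) % Ly
        mask[np.ix_(xs, ys)] = True
    if not mask.any():
        return state
    bond = state.bond
    flat_mask = mask.reshape(-1)
    # release surviving partners of ablated complex members
    ablated_bonds = bond[mask & (bond >= 0)]
    for partner in ablated_bonds:
        if not flat_mask[partner]:
            b = state.bond.reshape(-1)
            r = state.role.reshape(-1)
            a = state.age.reshape(-1)
            b[partner] = -1
            r[partner] = 0
            a[partner] = 0
    state.kind[mask] = EMPTY
    state.trait[mask] = 0.0
    state.bond[mask] = -1
    state.role[mask] = 0
    state.age[mask] = 0
    return state


def run_disruption(params: SimulationParams, init_spec: InitSpec,
                   spec: AblationSpec, t_end: float, seed: int | None = None,
                   sample_every: float = 50.0) -> Trajectory:
    """Replicator-only evolution under periodic large-scale ablations.

    Per-sample extras carry the speciation classification of the k_a
    distribution.
    """
    if init_spec.density_parasites > 0:
        raise ValidationError("disruption runs are replicator-only")
    if seed is None:
        seed = params.seed
    state = init_lattice(params, init_spec, seed=seed)
    ablation_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xAB1A7E]))
    sample_every = min(sample_every, spec.period)
    traj = None
    t = 0.0
    segments = []
    # advance period by period, ablating between segments
    while t < t_end:
        t_next = min(t + spec.period, t_end)
        seg = run_simulation(state, params, t_next, sample_every=sample_every)
        segments.append(seg)
        t = t_next
        if seg.extinct:
            break
        if t < t_end:
            ablate_patches(state, spec, ablation_rng)
    traj = _concat_trajectories(segments)
    for i, summary in enumerate(traj.ka):
        if summary.n > 0:
            res = detect_speciation(summary)
            traj.extras[i]["speciation"] = res.modality
            traj.extras[i]["modes"] = res.modes
    return traj


def _concat_trajectories(segments: list[Trajectory]) -> Trajectory:
    out = segments[0]
    for seg in segments[1:]:
        # drop the duplicated boundary sample
        out.times.extend(seg.times[1:])
        out.counts.extend(seg.counts[1:])
        out.ka.extend(seg.ka[1:])
        out.beta.extend(seg.beta[1:])
        out.counters.extend(seg.counters[1:])
        out.extras.extend(seg.extras[1:])
        out.status = seg.status
        out.final_state = seg.final_state
        if out.parasite_extinction_t is None:
            out.parasite_extinction_t = seg.parasite_extinction_t
    return out


def shift_window(state: LatticeState, k: int) -> LatticeState:
    """Shift an expansion window: drop the k leftmost columns, append k empty
    columns on the right and advance the absolute origin.  Population counts
    are otherwise preserved exactly; complexes cut by the drop release their
    surviving member."""
    if k <= 0:
        return state
    Lx, Ly = state.Lx, state.Ly
    flat_bond = state.bond.reshape(-1)
    flat_role = state.role.reshape(-1)
    flat_age = state.age.reshape(-1)
    # unbind survivors whose partner is being dropped
    for x in range(k):
        for y in range(Ly):
            p = state.bond[x, y]
            if p >= 0 and (p // Ly) >= k:
                flat_bond[p] = -1
                flat_role[p] = 0
                flat_age[p] = 0
    for arr, fill in ((state.kind, 0), (state.trait, 0.0), (state.role, 0),
                      (state.age, 0)):
        arr[:Lx - k] = arr[k:]
        arr[Lx - k:] = fill
    b = state.bond
    b[:Lx - k] = b[k:]
    b[Lx - k:] = -1
    keep = b >= 0
    b[keep] = b[keep] - k * Ly
    state.offset_x += k
    return state


def run_expansion(params: SimulationParams, strip: dict, init_spec: InitSpec,
                  t_end: float, seed: int | None = None,
                  sample_every: float = 10.0, margin: int = 24,
                  front_depth: int = 10) -> Trajectory:
    """Expansion of a replicator-only population into open space.

    The geometry is a strip, periodic in y and open in x, realised as a
    moving window of ``window_L_x`` columns: whenever the front comes within
    ``margin`` of the right edge the window shifts (left columns dropped,
    empty columns appended) while the absolute front coordinate is preserved.
    Per-sample extras carry :func:`front_statistics`.
    """
    if init_spec.density_parasites > 0:
        raise ValidationError("expansion runs are replicator-only")
    Ly = int(strip["L_y"])
    Lx = int(strip["window_L_x"])
    if init_spec.region is None:
        init_spec = dataclasses.replace(init_spec, region=(0, min(8, Lx), 0, Ly))
    if seed is None:
        seed = params.seed
    state = init_lattice(params, init_spec, seed=seed, shape=(Lx, Ly),
                         periodic_x=False)
    traj = Trajectory(n_sites=state.n_sites)
    counters = np.zeros(_K.N_COUNTERS, dtype=np.int64)

    def front_obs(s):
        if (s.kind != EMPTY).any():
            fs = front_statistics(s, axis=0, depth=front_depth,
                                  bounds=params.ka_bounds)
            return {"front_position": fs["front_position"],
                    "front_ka_median": fs["ka_summary"].median,
                    "front_ka_n": fs["ka_summary"].n}
        return {}

    _sample(traj, state, params, counters, [front_obs])
    sweeps_per_sample = max(1, int(round(sample_every / params.dt)))
    target = int(round(t_end / params.dt))
    while state.sweeps < target:
        chunk = min(sweeps_per_sample, target - state.sweeps)
        done, n_repl, n_par = _run(state, params, chunk, counters=counters)
        occ_x = np.nonzero((state.kind != EMPTY).any(axis=1))[0]
        if occ_x.size and occ_x.max() >= state.Lx - margin:
            shift_window(state, state.Lx // 4)
        _sample(traj, state, params, counters, [front_obs])
        if n_repl + n_par == 0:
            traj.status = "extinct"
            break
        if done < chunk:
            break
    traj.final_state = state
    return traj


def run_coevolution(params: SimulationParams, init_spec: InitSpec,
                    dt_repl: float | None = None, t_end: float = 5000.0,
                    seed: int | None = None,
                    sample_every: float = 50.0) -> Trajectory:
    """Co-evolution of replicator k_a and parasite beta.

    Both traits mutate; parasite extinction is flagged
    (``parasite_extinction_t``) but does not end the run — only total
    extinction does.
    """
    overrides = {"evolve_ka": True, "evolve_beta": True}
    if dt_repl is not None:
        overrides["dt_repl"] = float(dt_repl)
    p = dataclasses.replace(params, **overrides)
    state = init_lattice(p, init_spec, seed=seed)
    return run_simulation(state, p, t_end, sample_every=sample_every)


def run_well_mixed(params: SimulationParams, init_spec: InitSpec, t_end: float,
                   seed: int | None = None,
                   sample_every: float = 50.0) -> Trajectory:
    """Negative control: positions of all unbound molecules are randomly
    permuted every sweep (complexes keep their adjacency)."""
    state = init_lattice(params, init_spec, seed=seed)
    return run_simulation(state, params, t_end, sample_every=sample_every,
                          mix=True)
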