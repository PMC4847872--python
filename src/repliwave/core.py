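"""Domain types, lattice geometry, parameter validation and seeded initialisation.

The model world is a two-dimensional square lattice with eight-neighbour
(Moore) adjacency and wrapped boundaries.  Each site is either empty or holds
one molecule: a *replicator*, which can both catalyse replication (acting as
a replicase) and serve as a template, or a *parasite*, which only ever serves
as a template.  Replicators carry a heritable association rate ``k_a``
(propensity to bind a neighbouring template); parasites carry a heritable
template advantage ``beta`` (their binding weight relative to a replicator
template's fixed weight of 1).  A bound replicase-template pair is a
*complex* occupying two adjacent sites.

All rates are expressed per arbitrary unit of time (AUT); the simulation
advances in fixed steps of ``dt`` AUT using random sequential updating, with
each continuous rate ``r`` converted to a per-step probability
``1 - exp(-r * dt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np

# Cell kinds
EMPTY = 0
REPLICATOR = 1
PARASITE = 2

# Roles within a complex
UNBOUND = 0
REPLICASE = 1
TEMPLATE = 2

KIND_NAMES = {EMPTY: "empty", REPLICATOR: "replicator", PARASITE: "parasite"}
ROLE_NAMES = {UNBOUND: "unbound", REPLICASE: "replicase", TEMPLATE: "template"}

#: Fixed deterministic Moore-neighbourhood order (row-major offsets).
MOORE_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))

#: Template availability of a replicator.  Parasite templates are weighted
#: ``beta`` relative to this; it is a model constant and never evolves.
TEMPLATE_RATE = 1.0


class ValidationError(ValueError):
    """A parameter or configuration value violates its contract."""


def event_probability(rate: float, dt: float) -> float:
    """Per-timestep firing probability of a Poisson event with the given rate.

    Returns ``1 - exp(-rate * dt)``, the exact probability that a
    constant-rate event fires at least once within ``dt``.  Monotone in both
    arguments; ``~ rate * dt`` when ``rate * dt << 1``.
    """
    if rate < 0:
        raise ValidationError(f"rate must be non-negative, got {rate}")
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    return -math.expm1(-rate * dt)


@dataclass(frozen=True)
class SimulationParams:
    """All model rates, bounds and discretisation settings.

    Defaults are the reference parameter set used throughout:
    ``k_diss=0.25, rho=1, d=0.03, D=0.1, mu=0.005, delta_mu=0.05,
    dt_repl=0, k_a in [0, 2], beta in [0, 2]``.

    Attributes
    ----------
    L:
        Lattice side, in sites.
    k_diss:
        Spontaneous complex dissociation rate (AUT^-1).
    rho:
        Replication (template copying) rate of a complex (AUT^-1).
    d:
        Decay rate of every molecule (AUT^-1).
    D:
        Diffusion rate (AUT^-1); diffusion swaps neighbouring site contents
        and moves complexes as rigid pairs.
    mu:
        Mutation probability per replication event.
    delta_mu:
        Mutation step width: a mutated trait moves by U(-delta_mu/2, +delta_mu/2).
    beta_fixed:
        Parasite template advantage used when ``evolve_beta`` is off.
    dt_repl:
        Replication duration (AUT): minimum complex age before copying can
        complete.  A complex that breaks earlier yields no product.
    ka_bounds, beta_bounds:
        Closed intervals confining the heritable traits.
    dt:
        Integration timestep (AUT).  One sweep advances the clock by ``dt``.
    evolve_ka, evolve_beta:
        Whether offspring k_a (replicators) / beta (parasites) mutate.
    seed:
        Default RNG seed for runs driven by these parameters.
    """

    L: int = 256
    k_diss: float = 0.25
    rho: float = 1.0
    d: float = 0.03
    D: float = 0.1
    mu: float = 0.005
    delta_mu: float = 0.05
    beta_fixed: float = 1.4
    dt_repl: float = 0.0
    ka_bounds: tuple[float, float] = (0.0, 2.0)
    beta_bounds: tuple[float, float] = (0.0, 2.0)
    dt: float = 0.1
    evolve_ka: bool = True
    evolve_beta: bool = False
    seed: int = 0
    #: Template availability of replicators; fixed model constant.
    template_rate: float = field(default=TEMPLATE_RATE, init=False)

    def __post_init__(self) -> None:
        if self.L < 3:
            raise ValidationError(f"L must be >= 3, got {self.L}")
        for name in ("k_diss", "rho", "d", "D", "delta_mu", "beta_fixed"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValidationError(f"mu must be a probability in [0, 1], got {self.mu}")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.dt_repl < 0:
            raise ValidationError(f"dt_repl must be non-negative, got {self.dt_repl}")
        for name in ("ka_bounds", "beta_bounds"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValidationError(f"{name} must be a non-empty closed interval, got {(lo, hi)}")
            if lo < 0:
                raise ValidationError(f"{name} lower bound must be non-negative, got {lo}")
        # dt must be small enough that no single-event per-step probability
        # exceeds 0.5 (the discretisation would otherwise distort kinetics).
        beta_max = max(self.beta_bounds[1], self.beta_fixed)
        single_rates = {
            "k_diss": self.k_diss,
            "rho": self.rho,
            "d": self.d,
            "D": self.D,
            "ka_bounds[1] * beta": self.ka_bounds[1] * max(1.0, beta_max),
        }
        for name, r in single_rates.items():
            if event_probability(r, self.dt) > 0.5:
                raise ValidationError(
                    f"dt={self.dt} too large: per-step probability for {name}={r} exceeds 0.5"
                )

    @property
    def n_sites(self) -> int:
        return self.L * self.L


_PARAM_FIELDS = None


def build_params(config: Mapping) -> SimulationParams:
    """Build validated :class:`SimulationParams` from a key-value mapping.

    Missing keys take the reference defaults; unknown keys raise
    :class:`ValidationError` naming the key.
    """
    global _PARAM_FIELDS
    if _PARAM_FIELDS is None:
        _PARAM_FIELDS = {f.name for f in fields(SimulationParams) if f.init}
    kwargs = {}
    for key, value in config.items():
        if key not in _PARAM_FIELDS:
            raise ValidationError(f"unknown parameter: {key!r}")
        if key in ("ka_bounds", "beta_bounds"):
            value = tuple(float(v) for v in value)
        kwargs[key] = value
    return SimulationParams(**kwargs)


def moore_neighbors(site: tuple[int, int], L: int) -> list[tuple[int, int]]:
    """The 8 Moore neighbours of ``site`` on an L x L torus, in fixed order."""
    x, y = site
    return [((x + dx) % L, (y + dy) % L) for dx, dy in MOORE_OFFSETS]


# ---------------------------------------------------------------------------
# PCG32 — the simulation's own serialisable RNG.
#
# The event kernel needs a generator whose state is two integers so that
# snapshots can capture it losslessly and resumed runs replay bit-for-bit.
# ---------------------------------------------------------------------------

_PCG_MULT = 6364136223846793005
_U64 = (1 << 64) - 1


def pcg32_init(seed: int, stream: int = 1) -> np.ndarray:
    """Seed a PCG32 generator; returns ``uint64[2]`` = (state, increment)."""
    inc = ((int(stream) << 1) | 1) & _U64
    state = (inc + (int(seed) & _U64)) & _U64
    state = (state * _PCG_MULT + inc) & _U64
    return np.array([state, inc], dtype=np.uint64)


@dataclass
class Molecule:
    """Read-only view of one individual on the lattice."""

    kind: str
    k_a: float | None
    beta: float | None
    bond_site: tuple[int, int] | None
    role: str
    complex_age: float | None


@dataclass
class LatticeState:
    """A toroidal (or x-open strip) lattice of molecules plus the run clock.

    Arrays are shape ``(Lx, Ly)``; ``bond`` stores the flat index
    (``x * Ly + y``) of the complex partner, or -1 when unbound.  ``age``
    counts sweeps since complex formation and is kept on the replicase
    member.  ``rng`` is the PCG32 state driving all stochastic events.
    """

    kind: np.ndarray
    trait: np.ndarray
    bond: np.ndarray
    role: np.ndarray
    age: np.ndarray
    dt: float
    rng: np.ndarray
    sweeps: int = 0
    offset_x: int = 0
    periodic_x: bool = True

    @property
    def Lx(self) -> int:
        return self.kind.shape[0]

    @property
    def Ly(self) -> int:
        return self.kind.shape[1]

    @property
    def L(self) -> int:
        if self.Lx != self.Ly:
            raise ValueError("lattice is not square")
        return self.Lx

    @property
    def n_sites(self) -> int:
        return self.kind.size

    @property
    def t(self) -> float:
        """Simulation clock in AUT."""
        return self.sweeps * self.dt

    def copy(self) -> "LatticeState":
        return LatticeState(
            kind=self.kind.copy(),
            trait=self.trait.copy(),
            bond=self.bond.copy(),
            role=self.role.copy(),
            age=self.age.copy(),
            dt=self.dt,
            rng=self.rng.copy(),
            sweeps=self.sweeps,
            offset_x=self.offset_x,
            periodic_x=self.periodic_x,
        )

    def equals(self, other: "LatticeState") -> bool:
        return (
            self.kind.shape == other.kind.shape
            and np.array_equal(self.kind, other.kind)
            and np.array_equal(self.trait, other.trait)
            and np.array_equal(self.bond, other.bond)
            and np.array_equal(self.role, other.role)
            and np.array_equal(self.age, other.age)
            and np.array_equal(self.rng, other.rng)
            and self.sweeps == other.sweeps
            and self.dt == other.dt
            and self.offset_x == other.offset_x
            and self.periodic_x == other.periodic_x
        )

    def site_index(self, site: tuple[int, int]) -> int:
        return site[0] * self.Ly + site[1]

    def molecule_at(self, site: tuple[int, int]) -> Molecule | None:
        x, y = site
        k = int(self.kind[x, y])
        if k == EMPTY:
            return None
        bond = int(self.bond[x, y])
        bond_site = None if bond < 0 else (bond // self.Ly, bond % self.Ly)
        role = int(self.role[x, y])
        age = None
        if role == REPLICASE:
            age = float(self.age[x, y]) * self.dt
        elif role == TEMPLATE and bond_site is not None:
            age = float(self.age[bond_site]) * self.dt
        return Molecule(
            kind=KIND_NAMES[k],
            k_a=float(self.trait[x, y]) if k == REPLICATOR else None,
            beta=float(self.trait[x, y]) if k == PARASITE else None,
            bond_site=bond_site,
            role=ROLE_NAMES[role],
            complex_age=age,
        )


def empty_lattice(params: SimulationParams, seed: int | None = None,
                  shape: tuple[int, int] | None = None,
                  periodic_x: bool = True) -> LatticeState:
    """An all-empty lattice with a freshly seeded event RNG."""
    if shape is None:
        shape = (params.L, params.L)
    if seed is None:
        seed = params.seed
    return LatticeState(
        kind=np.zeros(shape, dtype=np.int8),
        trait=np.zeros(shape, dtype=np.float64),
        bond=np.full(shape, -1, dtype=np.int32),
        role=np.zeros(shape, dtype=np.int8),
        age=np.zeros(shape, dtype=np.int32),
        dt=params.dt,
        rng=pcg32_init(seed),
        periodic_x=periodic_x,
    )


def place(state: LatticeState, site: tuple[int, int], kind: int, trait: float = 0.0) -> None:
    """Put a single unbound molecule on an empty site (fixture helper)."""
    x, y = site
    if state.kind[x, y] != EMPTY:
        raise ValueError(f"site {site} is already occupied")
    state.kind[x, y] = kind
    state.trait[x, y] = trait
    state.bond[x, y] = -1
    state.role[x, y] = UNBOUND
    state.age[x, y] = 0


def bind(state: LatticeState, replicase_site: tuple[int, int],
         template_site: tuple[int, int], age: float = 0.0) -> None:
    """Join two adjacent unbound molecules into a complex (fixture helper).

    The replicase must be a replicator; parasites never catalyse.
    """
    if tuple(template_site) not in _rect_neighbors(replicase_site, state):
        raise ValueError("complex members must be Moore-adjacent")
    rx, ry = replicase_site
    tx, ty = template_site
    if state.kind[rx, ry] != REPLICATOR:
        raise ValueError("the replicase member must be a replicator")
    if state.kind[tx, ty] == EMPTY:
        raise ValueError("template site is empty")
    if state.bond[rx, ry] >= 0 or state.bond[tx, ty] >= 0:
        raise ValueError("both molecules must be unbound")
    state.bond[rx, ry] = state.site_index(template_site)
    state.bond[tx, ty] = state.site_index(replicase_site)
    state.role[rx, ry] = REPLICASE
    state.role[tx, ty] = TEMPLATE
    state.age[rx, ry] = int(round(age / state.dt))


def _rect_neighbors(site, state):
    x, y = site
    out = []
    for dx, dy in MOORE_OFFSETS:
        nx = x + dx
        if state.periodic_x:
            nx %= state.Lx
        elif not (0 <= nx < state.Lx):
            continue
        out.append((nx, (y + dy) % state.Ly))
    return out


@dataclass(frozen=True)
class InitSpec:
    """Initial-condition descriptor for seeded lattice construction.

    Trait initialisers may be a single value or a ``(lo, hi)`` range sampled
    uniformly.  ``region`` is ``None`` (whole lattice) or a half-open
    rectangle ``(x0, x1, y0, y1)``.
    """

    density_replicators: float = 0.3
    density_parasites: float = 0.0
    ka_init: float | tuple[float, float] = 1.0
    beta_init: float | tuple[float, float] = 1.4
    region: tuple[int, int, int, int] | None = None


def _draw_traits(init, lo, hi, n, rng):
    if isinstance(init, (tuple, list)):
        a, b = init
    else:
        a = b = float(init)
    if not (lo <= a <= hi and lo <= b <= hi):
        raise ValidationError(f"trait initialiser {init} outside bounds [{lo}, {hi}]")
    if a == b:
        return np.full(n, a)
    return rng.uniform(a, b, size=n)


def init_lattice(params: SimulationParams, init_spec: InitSpec | None = None,
                 seed: int | None = None,
                 shape: tuple[int, int] | None = None,
                 periodic_x: bool = True) -> LatticeState:
    """Seeded random initial lattice: unbound molecules placed uniformly.

    Identical ``(params, init_spec, seed)`` yield a bitwise-identical state.
    """
    if init_spec is None:
        init_spec = InitSpec()
    dr, dp = init_spec.density_replicators, init_spec.density_parasites
    if dr < 0 or dp < 0:
        raise ValidationError("densities must be non-negative")
    if dr + dp > 1:
        raise ValidationError(f"densities sum to {dr + dp} > 1")
    if seed is None:
        seed = params.seed
    state = empty_lattice(params, seed=seed, shape=shape, periodic_x=periodic_x)
    Lx, Ly = state.Lx, state.Ly
    if init_spec.region is None:
        region_flat = np.arange(Lx * Ly)
    else:
        x0, x1, y0, y1 = init_spec.region
        if not (0 <= x0 < x1 <= Lx and 0 <= y0 < y1 <= Ly):
            raise ValidationError(f"region {init_spec.region} outside the lattice")
        xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1), indexing="ij")
        region_flat = (xs * Ly + ys).ravel()
    n_region = region_flat.size
    n_r = int(round(dr * n_region))
    n_p = int(round(dp * n_region))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(region_flat, size=n_r + n_p, replace=False)
    kind = state.kind.ravel()
    trait = state.trait.ravel()
    kind[chosen[:n_r]] = REPLICATOR
    trait[chosen[:n_r]] = _draw_traits(init_spec.ka_init, *params.ka_bounds, n_r, rng)
    kind[chosen[n_r:]] = PARASITE
    trait[chosen[n_r:]] = _draw_traits(init_spec.beta_init, *params.beta_bounds, n_p, rng)
    return state
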