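# Methods

## The model

`repliwave` simulates a minimal RNA-world replicator system as an
individual-based stochastic process on a two-dimensional square lattice with
eight-neighbour (Moore) adjacency and wrapped boundaries.  Each site is empty
or holds one molecule.  Two molecular classes exist:

* **replicators** carry a heritable *association rate* `k_a` (AUT⁻¹).  A
  replicator can act as a *replicase* — bind a neighbouring template into a
  two-site complex and copy it — and as a *template* for other replicases,
  with fixed template availability 1.
* **parasites** carry a heritable *template advantage* `beta` and only ever
  act as templates: they are bound by replicases with weight `beta` relative
  to a replicator template's weight 1, never catalyse, and never bind each
  other.

Event kinds and rates (AUT⁻¹):

| event         | rate                       | notes |
|---------------|----------------------------|-------|
| association   | `k_a · mean(weights)`      | unbound replicator binds a free Moore neighbour; partner drawn ∝ weight |
| dissociation  | `k_diss`                   | complex breaks, no product |
| replication   | `rho`                      | complex older than `dt_repl` copies the **template** onto an empty site in the template's own neighbourhood; copy passes through mutation; complex breaks |
| decay         | `d`                        | any molecule; a bonded partner survives, unbound |
| diffusion     | `D`                        | site-content swap; complexes translate as rigid pairs |
| mutation      | probability `mu` per copy  | offspring trait ± U(−`delta_mu`/2, +`delta_mu`/2), clipped to bounds |

Reference parameter values (used as package defaults): `k_diss = 0.25`,
`rho = 1`, `d = 0.03`, `D = 0.1`, `mu = 0.005`, `delta_mu = 0.05`,
`dt_repl = 0`, `k_a ∈ [0, 2]`, `beta ∈ [0, 2]`, timestep `dt = 0.1` AUT.

## Time discretisation

The continuous rates are integrated with fixed-timestep random sequential
updating: one sweep visits every occupied site in a freshly shuffled
permutation, evaluating events in the fixed order decay → diffusion →
(association | dissociation → replication), and advances the clock by `dt`.
Each rate `r` becomes a per-sweep probability `1 − exp(−r·dt)`, exact for
the first-event time of a Poisson process; with `dt = 0.1` all per-event
probabilities stay well below 0.5 (validated at construction), so ordering
bias within a sweep is second order.  Complex age accumulates in sweeps; the
replication-duration gate uses `age ≥ dt_repl` with the age incremented once
per survived sweep.  Per-complex events (dissociation, replication, rigid
diffusion) are gated on the replicase member so each complex is evaluated
once per sweep.

The per-sweep decay survival `(1 − p)^k = exp(−d·t)` is exact; two-state
binding equilibria and complex lifetimes carry the usual O(dt) discrete-time
bias (e.g. mean complex lifetime `dt/(1 − exp(−k_diss·dt))` ≈ 1/k_diss +
dt/2), which the calibration tests account for.

## Association normalisation

The binding propensity of an unbound replicator is

    R = k_a · (sum of free-neighbour weights) / (number of free neighbours),

i.e. `k_a` times the *mean* template weight, with the partner then drawn
proportionally to weight.  Under this normalisation a replicator whose only
free neighbour is a replicator binds at exactly rate `k_a`, and at exactly
`k_a·beta` when it is a parasite — the rates as stated for the reaction
scheme — and the binding hazard does not grow with crowding.  The
alternative mass-action reading (`R = k_a · sum of weights`) makes binding
up to eight-fold faster in dense neighbourhoods; under it the evolved
minimum viable `k_a` in a replicator-only system falls to ≈ 0.01, far below
the decay rate, because even rarely-catalysing molecules are bound often
enough by the crowd.  The mean-weight normalisation reproduces the expected
minimum viable `k_a` ≈ 0.05, just above `d = 0.03` (see below), and is the
one implemented.  The conditional partner choice — e.g. a parasite with
`beta = 1.7` chosen over a replicator neighbour with probability 1.7/2.7 —
is identical under both readings.

## What the system does

* **Replicator-only evolution.**  With `k_a` mutable and no parasites,
  selection favours molecules that spend more time as templates: the median
  `k_a` declines from 1.0 towards the minimum viable value ≈ 0.05 (just
  above `d = 0.03`), where further decline causes local extinctions that
  neighbouring replicators re-colonise.  The descent takes ≈ 2×10⁵ AUT under
  the reference mutation supply (`mu = 0.005`, `delta_mu = 0.05`); the
  population stays near carrying capacity until `k_a` approaches the
  viability edge, then turns patchy.
* **Mixing destroys the rescue.**  Randomly permuting all unbound molecules
  every sweep removes the spatial structure; the evolving population drives
  `k_a` below viability and goes globally extinct.  Mixing alone is not
  lethal: with mutation off and `k_a` well above `d` the mixed population
  persists.
* **Parasites.**  Moderate-to-strong parasites coexist with replicators in
  travelling waves; across the scan the replicator fraction rises and the
  parasite fraction falls with `beta`.  The weak-parasite extinction
  (`beta ≤ 1.0`) is an eco-evolutionary outcome — it requires `k_a` to
  first evolve down under weak parasite pressure until parasites are no
  longer sustainable — and therefore plays out on the ~10⁵ AUT evolutionary
  timescale; at the ecological horizons used in the desk-scale experiments
  (10³–10⁴ AUT from `k_a = 1`), parasites at `beta ≤ 1.0` are still viable
  in this implementation.  See the limitations section.
* **Replication duration.**  `dt_repl > 0` makes copying costly: a complex
  must survive `dt_repl` before producing, so the per-association offspring
  yield falls roughly as `exp(-k_diss · dt_repl)` (verified against the renewal
  oracle in the tests).  In the modelled system long durations drive
  speciation of replicator-only populations into a replicase-like and a
  parasite-like `k_a` lineage, and select weaker parasites under
  co-evolution, with a viability limit in `dt_repl`.  These are
  evolutionary outcomes on the ~10⁵ AUT timescale; at the desk-scale
  horizons of this package's test runs (≤ 2×10⁴ AUT for these protocols)
  the trait distributions have not yet diverged, and the corresponding
  checks in the test suite document that shortfall rather than assert
  success (see limitations).

## Observables

* `population_counts` — exact per-class counts; complexes are bonded pairs.
* `trait_distribution` — quartiles (midpoint interpolation) and a fixed-bin
  histogram (default width 0.02) over the trait bounds.
* `empty_components` — 8-connected components of empty sites, torus-aware
  (components touching across periodic seams are merged by union–find on
  top of `scipy.ndimage.label`).
* `empty_space_index` — the front-contact index: every replicator with at
  least one empty Moore neighbour contributes the mean size of the empty
  components it touches, normalised by lattice area; the index averages
  over these front replicators.  It is a qualitative measure used only for
  ordinal comparisons (chaotic vs stable wave regimes), not for absolute
  values.
* `detect_speciation` — the trait histogram is smoothed with a 3-bin moving
  average; local maxima whose basins carry ≥ 10 % of total mass qualify as
  modes; the call is *bimodal* iff two qualifying modes lie ≥ 0.5 trait
  units apart with an intervening valley below 20 % of the smaller peak.
  The thresholds are exposed as parameters; the call is invariant under
  histogram rescaling.
* `front_statistics` — for strip geometries: the maximum occupied
  x-coordinate (window origin added back) and the trait summary of
  molecules within 10 sites of it.

## Experiment drivers

All protocols are seeded and reproducible; scan replicates use sub-seeds
`seed + replicate_index`.  Extinction is always a flagged outcome, never an
exception.  The ecological grid forces `mu = 0`.  Disruption runs apply
`ablate_patches` every `period` AUT (random axis-aligned squares, torus
wrap; surviving partners of ablated complex members are released unbound).
Expansion runs use a strip, periodic in y and open in x, realised as a
moving window: when the front nears the right edge the window shifts left
columns out and appends empty columns, preserving absolute front
coordinates.  Co-evolution runs evolve both traits; parasite extinction is
flagged but only total extinction ends a run early.

## Synthetic initial conditions

All inputs are generated: `init_lattice` places molecules uniformly at
random (optionally in a rectangle) at given densities with scalar or
uniform-range trait initialisers.  This emulates the unstructured initial
droplet of the modelled system; it does not emulate any pre-formed spatial
pattern, so early-time transients (pattern formation from noise) are part of
every run.  Tests passing on these initial conditions say nothing about
robustness to structured or empirical initial states.

## Numerical and implementation choices

* Randomness: a PCG32 generator with explicit `uint64[2]` state drives all
  lattice events, is serialised losslessly in snapshots, and makes resumed
  runs replay bit-for-bit.  Per molecule and sweep one base uniform is
  drawn and chained through the successive Bernoulli decisions by exact
  inverse-CDF rescaling.
* Trait mutation clips at the bounds (no reflection/rejection): the evolved
  "maximised" regime sits at the boundary, and clipping is the simplest
  boundary rule consistent with closed trait intervals.
* Replication target: uniform over the *template's* empty Moore neighbours.
  Placing the copy next to the molecule being copied means a template buried
  in a solid clump of its own kind cannot be replicated; this realises the
  self-limiting local accumulation of parasites (a parasite clump chokes on
  its own density) and prevents copies from leap-frogging across the
  replicase into the opposite domain.  With placement in the union of both
  members' neighbourhoods instead, moderate-strength parasites (beta
  1.1-1.4) overrun and destroy the whole system from random initial
  conditions rather than settling into travelling-wave coexistence.
* Complex diffusion is a rigid unit translation; moves that would disturb a
  third complex are skipped; rotations are not implemented.
* Degenerate inputs: empty lattices sweep as no-ops (the clock still
  advances); empty trait summaries are returned, not raised; extinction
  terminates runs early with a status flag.
* The event kernel is compiled with numba; a precomputed neighbour table
  handles both torus and open-x geometries.

## Problem sizes

The reference experiments in `scripts/acceptance.py` are scaled to a single
CPU (the original regimes use lattices of 512²–2048²; wave-regime
boundaries are lattice-size sensitive, so quantitative claims here are
restricted to scales where pilots showed the regime fits):

* minimum viable `k_a`: L = 36, 2 seeds, run from 1.5×10⁵ AUT with the
  steady-state gate (extend by 2.5×10⁴-AUT blocks until the block median of
  `k_a` drifts by less than one histogram bin, hard cap ≈ 2.6×10⁵ AUT);
  the value is the cross-seed median of the final block medians.  Pilots at
  L = 36, 40, 48 and 64 all settle at 0.053–0.060.
* parasite inviability threshold: L = 256 (smaller lattices collapse
  globally for beta ≥ 1.1, a finite-size artefact), beta ∈ {0.9 … 1.3},
  3 seeds, 10³ AUT, majority rule on parasite extinction at run end.
  At this ecological horizon from `k_a = 1` the weak-parasite extinction
  threshold does not emerge (see limitations): runs that lose their
  parasites do so by whole-system collapse, not by parasite drop-out.
* co-evolutionary collapse: L = 128, `k_diss = 0.1`, `dt_repl` ∈
  {4.5, 4.7, 5.0}, 3 seeds, `k_a`/`beta` initialised at 1.0/1.0, capped at
  5×10³ AUT, majority rule on total extinction before the cap.  Under these
  conditions parasites frequently die out but replicators persist, so no
  majority global extinction is observed on the grid (reported as null);
  the collapse described for the co-evolved state would require evolving
  the traits for ~10⁵ AUT first.

## Known limitations

* Complementary-strand chemistry, sequence/secondary structure, and the
  evolution of `dt_repl` are out of scope by design.
* Trait evolution is mutation-limited under the reference supply
  (`mu = 0.005`, `delta_mu = 0.05`): order-one changes of a trait median
  take ~10⁵ AUT.  Behaviours defined at eco-evolutionary steady state —
  weak-parasite (`beta ≤ 1.0`) extinction, the `k_a` maximisation under
  strong parasites, `dt_repl`-driven speciation and the co-evolutionary
  fate of `beta` — are therefore out of reach of the desk-scale runs this
  package uses for its checks, and several of those checks fail by design
  at the shipped problem sizes; they are kept (rather than weakened) as an
  explicit record of the gap.
* Regimes built on large travelling waves (strong parasites, the high-`k_a`
  bistable branch) collapse on lattices of 256² and below; the original
  regimes use up to 2048².
* The front-contact index approximates an under-specified qualitative
  measurement; only its ordinal behaviour across regimes is meaningful.
* Stable-wave statistics at `beta ≥ 1.7` need lattices large enough to
  contain the waves; small-lattice runs in that regime can lose the waves
  (and with them the regime) entirely.
* The scheduler is random-sequential with fixed within-visit event order,
  not an exact-stochastic (Gillespie) simulation; biases are O(dt).
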