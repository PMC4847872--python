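"""Measurements on lattice states: population structure, trait distributions,
empty-space statistics, speciation and expansion-front detection.

The empty-space index quantifies how much uninterrupted empty space the
replicators at wave fronts are exposed to: for every replicator with at least
one empty Moore neighbour, the sizes of the empty connected components it
touches are averaged and normalised by the lattice area, and the index is the
mean of that value over all such front replicators.  In the chaotic-wave
regime empty space is fragmented and the index is small; in the stable-wave
regime waves leave large contiguous voids behind them and the index is large.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .core import EMPTY, PARASITE, REPLICATOR, LatticeState

#: Default histogram bin width, in trait units.
DEFAULT_BIN_WIDTH = 0.02


@dataclass
class TraitSummary:
    """Distribution summary of one heritable trait over one subpopulation.

    Quartiles use midpoint interpolation; the histogram covers the trait
    bounds at fixed bin width, so its mass always equals ``n``.
    """

    n: int
    median: float
    q1: float
    q3: float
    hist: np.ndarray
    bin_edges: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_values(cls, values: np.ndarray, bounds: tuple[float, float],
                    bin_width: float = DEFAULT_BIN_WIDTH) -> "TraitSummary":
        lo, hi = bounds
        n_bins = max(1, int(round((hi - lo) / bin_width)))
        edges = np.linspace(lo, hi, n_bins + 1)
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return cls(0, float("nan"), float("nan"), float("nan"),
                       np.zeros(n_bins, dtype=np.int64), edges)
        hist, _ = np.histogram(np.clip(values, lo, hi), bins=edges)
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="midpoint")
        return cls(int(values.size), float(med), float(q1), float(q3),
                   hist.astype(np.int64), edges)

    @property
    def empty(self) -> bool:
        return self.n == 0


@dataclass
class EmptySpaceReport:
    """Empty-space structure of a snapshot: 8-connected component sizes, the
    total empty fraction, and the front-contact index in [0, 1]."""

    component_sizes: np.ndarray
    empty_fraction: float
    index: float


@dataclass
class SpeciationResult:
    modality: str  # "unimodal" | "bimodal"
    modes: list[float] = field(default_factory=list)

    @property
    def bimodal(self) -> bool:
        return self.modality == "bimodal"


def population_counts(state: LatticeState) -> dict[str, int]:
    """Exact molecule/complex/empty counts.  Replicators + parasites + empty
    always equals the number of sites; a complex is one bonded pair."""
    kind = state.kind
    n_repl = int(np.count_nonzero(kind == REPLICATOR))
    n_par = int(np.count_nonzero(kind == PARASITE))
    n_complex = int(np.count_nonzero(state.bond >= 0)) // 2
    return {
        "replicators": n_repl,
        "parasites": n_par,
        "complexes": n_complex,
        "empty": state.n_sites - n_repl - n_par,
    }


def trait_distribution(state: LatticeState, trait: str,
                       bounds: tuple[float, float] | None = None,
                       bin_width: float = DEFAULT_BIN_WIDTH) -> TraitSummary:
    """Summary of k_a over replicators or beta over parasites.

    An empty subpopulation yields an empty summary, not an error.
    """
    if trait == "k_a":
        mask = state.kind == REPLICATOR
        if bounds is None:
            bounds = (0.0, 2.0)
    elif trait == "beta":
        mask = state.kind == PARASITE
        if bounds is None:
            bounds = (0.0, 2.0)
    else:
        raise ValueError(f"unknown trait {trait!r} (expected 'k_a' or 'beta')")
    return TraitSummary.from_values(state.trait[mask], bounds, bin_width)


_STRUCT8 = np.ones((3, 3), dtype=bool)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _labeled_empty(state: LatticeState):
    """8-connected components of empty sites, merged across periodic seams.

    Returns ``(labels, sizes)`` where ``labels`` maps each empty site to a
    component id in ``[0, n_components)`` (occupied sites get -1) and
    ``sizes[c]`` is the number of sites in component c.
    """
    empty = state.kind == EMPTY
    labels, n_lab = ndimage.label(empty, structure=_STRUCT8)
    if n_lab == 0:
        return np.full(state.kind.shape, -1, dtype=np.int64), np.zeros(0, dtype=np.int64)
    uf = _UnionFind(n_lab + 1)
    Lx, Ly = state.Lx, state.Ly

    def merge_rows(a_row, b_row):
        # a_row and b_row are adjacent across a periodic seam (all 3 diagonal
        # shifts of the Moore neighbourhood)
        for shift in (-1, 0, 1):
            la = labels[a_row]
            lb = np.roll(labels[b_row], shift)
            both = (la > 0) & (lb > 0)
            for p, q in zip(la[both], lb[both]):
                uf.union(int(p), int(q))

    if state.periodic_x and Lx > 1:
        merge_rows(0, Lx - 1)
    if Ly > 1:
        lt = labels[:, 0]
        for shift in (-1, 0, 1):
            lb = np.roll(labels[:, Ly - 1], shift)
            both = (lt > 0) & (lb > 0)
            for p, q in zip(lt[both], lb[both]):
                uf.union(int(p), int(q))

    root = np.array([uf.find(i) for i in range(n_lab + 1)], dtype=np.int64)
    uniq, compact = np.unique(root[1:], return_inverse=True)
    remap = np.full(n_lab + 1, -1, dtype=np.int64)
    remap[1:] = compact
    out = remap[labels]
    sizes = np.bincount(out[out >= 0], minlength=uniq.size).astype(np.int64)
    return out, sizes


def empty_components(state: LatticeState) -> np.ndarray:
    """Sizes of the 8-connected components of empty sites (torus-aware)."""
    _, sizes = _labeled_empty(state)
    return np.sort(sizes)[::-1]


def _neighbor_label_stack(labels: np.ndarray, periodic_x: bool) -> np.ndarray:
    """(8, Lx, Ly) array of each site's Moore-neighbour component labels."""
    out = np.full((8,) + labels.shape, -1, dtype=np.int64)
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (dx, dy) in enumerate(shifts):
        rolled = np.roll(np.roll(labels, -dx, axis=0), -dy, axis=1)
        if not periodic_x:
            if dx == 1:
                rolled[-1, :] = -1
            elif dx == -1:
                rolled[0, :] = -1
        out[i] = rolled
    return out


def empty_space_index(state: LatticeState) -> EmptySpaceReport:
    """Front-contact empty-space index of a snapshot.

    Front replicators are replicators (bound or unbound) with at least one
    empty Moore neighbour.  Each contributes the mean size of the distinct
    empty components it touches, normalised by the lattice area; the index is
    the average over front replicators (0 when there are none).  Deterministic
    given the state.
    """
    labels, sizes = _labeled_empty(state)
    n_sites = state.n_sites
    empty_fraction = float(sizes.sum()) / n_sites if sizes.size else 0.0
    if sizes.size == 0:
        return EmptySpaceReport(sizes, 0.0, 0.0)
    nb = _neighbor_label_stack(labels, state.periodic_x)
    repl = state.kind == REPLICATOR
    touches = nb[:, repl]  # (8, n_repl)
    values = []
    for col in range(touches.shape[1]):
        labs = touches[:, col]
        labs = np.unique(labs[labs >= 0])
        if labs.size == 0:
            continue
        values.append(sizes[labs].mean() / n_sites)
    index = float(np.mean(values)) if values else 0.0
    return EmptySpaceReport(np.sort(sizes)[::-1], empty_fraction, index)


def detect_speciation(summary: TraitSummary, min_mode_mass: float = 0.1,
                      min_gap: float = 0.5,
                      valley_fraction: float = 0.2) -> SpeciationResult:
    """Classify a trait histogram as unimodal or bimodal.

    The histogram is smoothed with a 3-bin moving average; local maxima whose
    basins carry at least ``min_mode_mass`` of the total mass qualify as
    modes.  The distribution is bimodal iff two qualifying modes are at least
    ``min_gap`` trait units apart with an intervening valley below
    ``valley_fraction`` of the smaller peak.  Invariant under rescaling of
    the histogram by a positive constant.
    """
    if summary.empty or summary.hist.sum() == 0:
        raise ValueError("cannot classify an empty trait summary")
    h = summary.hist.astype(float)
    total = h.sum()
    smooth = np.convolve(h, np.ones(3) / 3.0, mode="same")
    centers = summary.bin_centers
    padded = np.concatenate(([-1.0], smooth, [-1.0]))
    peak_idx, _ = find_peaks(padded)
    peak_idx = peak_idx - 1  # undo padding
    peak_idx = [int(i) for i in peak_idx if smooth[i] > 0]
    if not peak_idx:
        return SpeciationResult("unimodal", [float(centers[int(np.argmax(smooth))])])

    def basin_masses(peaks):
        # split the histogram at the minimum between consecutive peaks
        bounds = [0]
        for a, b in zip(peaks[:-1], peaks[1:]):
            bounds.append(a + 1 + int(np.argmin(smooth[a + 1:b + 1])))
        bounds.append(len(h))
        return [h[bounds[i]:bounds[i + 1]].sum() for i in range(len(peaks))]

    peaks = sorted(peak_idx)
    while len(peaks) > 1:
        masses = basin_masses(peaks)
        weakest = int(np.argmin(masses))
        if masses[weakest] >= min_mode_mass * total:
            break
        del peaks[weakest]
    modes = [float(centers[p]) for p in peaks]
    if len(peaks) < 2:
        return SpeciationResult("unimodal", modes)
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            a, b = peaks[i], peaks[j]
            if abs(centers[b] - centers[a]) < min_gap:
                continue
            valley = smooth[a + 1:b].min() if b - a > 1 else smooth[a]
            if valley < valley_fraction * min(smooth[a], smooth[b]):
                return SpeciationResult("bimodal", modes)
    return SpeciationResult("unimodal", modes)


def front_statistics(state: LatticeState, axis: int = 0, depth: int = 10,
                     bounds: tuple[float, float] = (0.0, 2.0)) -> dict:
    """Position and trait summary of an expansion front.

    The front position is the maximum occupied coordinate along ``axis``
    (offset by the moving-window origin for strip geometries); front
    molecules are those within ``depth`` sites of it.
    """
    occ = np.argwhere(state.kind != EMPTY)
    if occ.size == 0:
        raise ValueError("extinct population: no occupied sites")
    coords = occ[:, axis]
    front_local = int(coords.max())
    sel = coords > front_local - depth
    front_cells = occ[sel]
    repl = state.kind[front_cells[:, 0], front_cells[:, 1]] == REPLICATOR
    values = state.trait[front_cells[repl, 0], front_cells[repl, 1]]
    offset = state.offset_x if axis == 0 else 0
    return {
        "front_position": front_local + offset,
        "ka_summary": TraitSummary.from_values(values, bounds),
    }
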