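"""Seeded generators for network structures, DC input patterns and noise.

This is the study's synthetic-data layer: everything the simulator consumes
is produced here from integer seeds, so that a network realization or an
input pattern is a pure, bit-reproducible function of its seed.

The network is two interconnected ring lattices — one excitatory
(default 300 neurons) and one inhibitory (default 75).  Each excitatory
neuron projects onto a randomly chosen 3% of the neurons on each lattice;
each inhibitory neuron onto 6% of each lattice.  No self-connections.
Fractional target counts round half up (0.06 x 75 = 4.5 -> 5).

The per-neuron external drive is a constant current drawn uniformly over a
2.0 uA/cm^2-wide band whose mean is calibrated so that an isolated neuron
fires at 10 Hz (:func:`calibrate_mean_input`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .params import CellParams

__all__ = [
    "NetworkStructure",
    "InputPattern",
    "OffsetSpec",
    "NoiseSpec",
    "generate_network",
    "generate_input_pattern",
    "calibrate_mean_input",
    "CalibrationError",
]

E_OUT_FRACTION = 0.03  # excitatory out-degree fraction of each lattice
I_OUT_FRACTION = 0.06  # inhibitory out-degree fraction of each lattice


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class NetworkStructure:
    """Directed E/I adjacency; ``adjacency[i, j] == 1`` iff j synapses onto i."""

    adjacency: np.ndarray
    ei_labels: np.ndarray  # True = excitatory, first n_e entries
    structure_seed: int
    n_e: int
    n_i: int

    @property
    def n_neurons(self) -> int:
        return self.n_e + self.n_i

    def out_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def excitatory_ids(self) -> np.ndarray:
        return np.flatnonzero(self.ei_labels)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for i in range(self.n_neurons):
            g.add_node(i, kind="E" if self.ei_labels[i] else "I")
        src, dst = np.nonzero(self.adjacency.T)
        g.add_edges_from(zip(src.tolist(), dst.tolist()))
        return g

    def to_edgelist_csv(self, path: str | Path) -> None:
        src, dst = np.nonzero(self.adjacency.T)
        wclass = np.where(self.ei_labels[src], "E", "I")
        pd.DataFrame({"source": src, "target": dst, "weight_class": wclass}).to_csv(
            path, index=False
        )

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), path)

    @classmethod
    def from_edgelist_csv(
        cls, path: str | Path, n_e: int, n_i: int, structure_seed: int = -1
    ) -> "NetworkStructure":
        df = pd.read_csv(path)
        n = n_e + n_i
        a = np.zeros((n, n), dtype=np.uint8)
        a[df["target"].to_numpy(), df["source"].to_numpy()] = 1
        labels = np.arange(n) < n_e
        return cls(a, labels, structure_seed, n_e, n_i)


@dataclass
class InputPattern:
    """Per-neuron constant external current (uA/cm^2)."""

    i_ext: np.ndarray
    mean: float
    range: float
    pattern_seed: int

    def __post_init__(self) -> None:
        self.i_ext = np.asarray(self.i_ext, dtype=float)
        spread = self.i_ext.max() - self.i_ext.min() if self.i_ext.size else 0.0
        if spread > self.range + 1e-12:
            raise ValueError("input pattern spread exceeds the configured range")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"neuron_id": np.arange(self.i_ext.size), "i_ext": self.i_ext}
        ).to_csv(path, index=False)


@dataclass
class OffsetSpec:
    """Extra constant current injected into a small excitatory subset."""

    subset: np.ndarray
    i_offset: float
    subset_seed: int

    def __post_init__(self) -> None:
        self.subset = np.asarray(self.subset, dtype=int)
        if not 0.0 <= self.i_offset <= 1.95:
            raise ValueError("i_offset must lie in [0, 1.95] uA/cm^2")

    @classmethod
    def draw(
        cls,
        net: NetworkStructure,
        i_offset: float,
        subset_seed: int,
        subset_size: int = 20,
    ) -> "OffsetSpec":
        """Choose ``subset_size`` excitatory neurons uniformly at random."""
        rng = np.random.default_rng(subset_seed)
        subset = np.sort(rng.choice(net.excitatory_ids(), size=subset_size, replace=False))
        return cls(subset=subset, i_offset=i_offset, subset_seed=subset_seed)


@dataclass
class NoiseSpec:
    """Rate of randomly induced spikes, independently per neuron (Hz)."""

    rate: float = 1.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("noise rate must be non-negative")


def _ring_targets(rng, pos: float, pool: np.ndarray, base: int, k: int,
                  rewire_p: float) -> np.ndarray:
    """k nearest ring neighbours of a (possibly fractional) position, each
    rewired to a uniform random member of the pool with probability p."""
    size = pool.size
    idx = pool - base  # positions on this ring, 0..size-1
    d = np.abs(idx - pos)
    d = np.minimum(d, size - d)
    order = np.lexsort((idx, d))
    chosen = list(pool[order[:k]])
    for m in range(k):
        if rng.random() < rewire_p:
            free = np.setdiff1d(pool, chosen, assume_unique=False)
            if free.size:
                chosen[m] = int(rng.choice(free))
    return np.asarray(chosen)


def generate_network(
    structure_seed: int,
    n_e: int = 300,
    n_i: int = 75,
    topology: str = "random",
    rewire_p: float = 0.1,
) -> NetworkStructure:
    """Seeded E/I structure at the fixed 3%/6% out-degree densities.

    ``topology="random"`` (default): each source neuron picks its targets
    uniformly without replacement on each lattice, excluding itself.
    ``topology="ring"``: a small-world variant — targets start as the
    nearest neighbours on each ring (cross-lattice positions mapped
    proportionally) and each edge is rewired uniformly with probability
    ``rewire_p``.  Either way the structure is a pure function of
    ``structure_seed`` and satisfies the exact degree rules.
    """
    if structure_seed < 0:
        raise ValueError("structure_seed must be a non-negative integer")
    if topology not in ("random", "ring"):
        raise ValueError("topology must be 'random' or 'ring'")
    rng = np.random.default_rng(structure_seed)
    n = n_e + n_i
    labels = np.arange(n) < n_e
    a = np.zeros((n, n), dtype=np.uint8)
    e_ids = np.arange(n_e)
    i_ids = np.arange(n_e, n)
    for j in range(n):
        frac = E_OUT_FRACTION if labels[j] else I_OUT_FRACTION
        for lattice, base in ((e_ids, 0), (i_ids, n_e)):
            k = _round_half_up(frac * lattice.size)
            pool = lattice[lattice != j]
            if topology == "random":
                targets = rng.choice(pool, size=k, replace=False)
            else:
                own_size = n_e if labels[j] else n_i
                own_pos = j if labels[j] else j - n_e
                pos = own_pos * lattice.size / own_size  # map onto target ring
                targets = _ring_targets(rng, pos, pool, base, k, rewire_p)
            a[targets, j] = 1
    return NetworkStructure(a, labels, structure_seed, n_e, n_i)


def generate_input_pattern(
    pattern_seed: int,
    mean: float,
    n_neurons: int = 375,
    range_: float = 2.0,
) -> InputPattern:
    """Uniform per-neuron DC currents on [mean - range/2, mean + range/2]."""
    if range_ < 0:
        raise ValueError("range must be non-negative")
    rng = np.random.default_rng(pattern_seed)
    i_ext = rng.uniform(mean - range_ / 2.0, mean + range_ / 2.0, size=n_neurons)
    return InputPattern(i_ext=i_ext, mean=mean, range=range_, pattern_seed=pattern_seed)


class CalibrationError(RuntimeError):
    """Raised when no constant current attains the requested firing rate."""


def calibrate_mean_input(
    cell: CellParams,
    target_rate: float = 10.0,
    rel_tol: float = 0.02,
    bounds: tuple[float, float] = (-2.0, 10.0),
    duration: float = 7000.0,
    analysis_window: float = 5000.0,
    dt: float = 0.05,
    max_iter: int = 60,
) -> float:
    """Constant current at which an isolated neuron fires at ``target_rate``.

    Bisection on the steady firing rate (counted over the final
    ``analysis_window`` ms of a ``duration`` ms run) against the injected
    current.  For strongly Type 2 cells the onset of firing is
    discontinuous; a target rate below the onset frequency is unreachable
    and raises :class:`CalibrationError` rather than returning the nearest
    attainable current.
    """
    from .simulator import single_neuron_spikes  # local import avoids a cycle

    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    lo, hi = bounds

    def rate(i: float) -> float:
        t = single_neuron_spikes(cell, i, duration=duration, dt=dt)
        w0 = duration - analysis_window
        n_win = int(np.count_nonzero(t >= w0))
        # near the Type 2 bifurcation a transient volley can fire and die
        # out; demand sustained firing through the window before counting it
        n_late = int(np.count_nonzero(t >= duration - analysis_window / 2.0))
        if n_win and n_late < 0.3 * n_win:
            return 0.0
        return n_win / (analysis_window / 1000.0)

    # Coarse upward scan to bracket the target: the f/I curve is only
    # monotone between onset and depolarisation block, so a blind bracket at
    # the bound can land past the block.
    grid = np.linspace(lo, hi, 25)
    r_prev = rate(grid[0])
    if r_prev > target_rate:
        raise CalibrationError(
            f"target {target_rate} Hz below rate {r_prev:.2f} Hz at I = {lo} uA/cm^2"
        )
    for i_lo, i_hi in zip(grid[:-1], grid[1:]):
        r_next = rate(i_hi)
        if r_prev < target_rate <= r_next:
            lo, hi = i_lo, i_hi
            break
        r_prev = r_next
    else:
        raise CalibrationError(
            f"no current in [{grid[0]}, {grid[-1]}] uA/cm^2 reaches "
            f"{target_rate} Hz before depolarisation block"
        )
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate) <= rel_tol * target_rate:
            best = mid
            break
        if r < target_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-7:
            break
    if best is None:
        # interval collapsed without hitting the tolerance: discontinuous f/I
        raise CalibrationError(
            f"firing rate jumps across {target_rate} Hz near I = {0.5 * (lo + hi):.4f} "
            "uA/cm^2 (Type 2 onset above the target rate)"
        )
    return best
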