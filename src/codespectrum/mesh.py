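"""2D mesh topology and random directed synaptic weights.

Neurons sit on a ``rows x cols`` lattice (default 33 x 33, 1089 neurons).
Each neuron connects to and from its eight Chebyshev-distance-1 neighbours;
there is no wraparound and nothing outside the lattice, so edge neurons have
five neighbours and corner neurons three.

Each directed edge i -> j carries an independent weight

    w_ij = F[(1 + c) u - c],   u ~ Uniform[0, 1),

where F truncates to [-1, 1].  The balance parameter ``c`` (0 < c <= 3)
controls the fraction of negative (inhibitory-like) weights:
P(w > 0) = 1 / (1 + c), so c = 1/3 gives the 3:1 positive-to-negative ratio
typical of biological networks and c = 1 a symmetric 1:1 split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NEIGHBOR_OFFSETS",
    "MeshTopology",
    "WeightConfig",
    "SynapticWeights",
    "build_topology",
    "truncate",
    "sample_weight",
    "generate_weights",
    "weight_sign_ratio",
]

#: Clockwise from north: (drow, dcol).  This fixed order, together with
#: row-major iteration over source neurons, defines the canonical RNG
#: consumption order so a seed reproduces weight maps bit-identically.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


@dataclass(frozen=True)
class MeshTopology:
    """A rows x cols lattice with 8-neighbour (Chebyshev-1) connectivity."""

    rows: int = 33
    cols: int = 33

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError(f"mesh must be at least 2x2, got {self.rows}x{self.cols}")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def flat(self, row: int | np.ndarray, col: int | np.ndarray) -> int | np.ndarray:
        """Flat (row-major) index of neuron at 0-based (row, col)."""
        return row * self.cols + col

    def coords(self, idx: int | np.ndarray) -> tuple:
        """0-based (row, col) of a flat index."""
        return np.divmod(idx, self.cols)

    def neighbors(self, row: int, col: int) -> list[tuple[int, int]]:
        """Neighbours of (row, col), clockwise from north, clipped at edges."""
        out = []
        for dr, dc in NEIGHBOR_OFFSETS:
            r, c = row + dr, col + dc
            if 0 <= r < self.rows and 0 <= c < self.cols:
                out.append((r, c))
        return out

    def directed_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """All ordered neighbour pairs (source, target) as flat-index arrays.

        Order is canonical: row-major over the source neuron, then clockwise
        over its neighbours.  Both directions of every undirected edge appear.
        """
        src, dst = [], []
        for row in range(self.rows):
            for col in range(self.cols):
                i = self.flat(row, col)
                for r, c in self.neighbors(row, col):
                    src.append(i)
                    dst.append(self.flat(r, c))
        return np.asarray(src, dtype=np.int64), np.asarray(dst, dtype=np.int64)


@dataclass(frozen=True)
class WeightConfig:
    """Weight-generation settings: balance parameter c and RNG seed."""

    c: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.c <= 3.0):
            raise ValueError(f"c must satisfy 0 < c <= 3, got {self.c}")


@dataclass
class SynapticWeights:
    """Weights for every ordered neighbour pair of a topology.

    ``values[k]`` is the weight of the k-th pair of
    ``topology.directed_pairs()``; w_ij and w_ji are independent draws.
    """

    topology: MeshTopology
    values: np.ndarray
    source: np.ndarray = field(repr=False)
    target: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.values)
        if len(self.source) != n or len(self.target) != n:
            raise ValueError("source/target/values length mismatch")
        if np.any(np.abs(self.values) > 1.0):
            raise ValueError("weights must lie in [-1, 1]")

    @property
    def n_edges(self) -> int:
        return len(self.values)

    def input_matrix(self) -> sp.csr_matrix:
        """Sparse (n, n) matrix M with M[j, i] = w_ij.

        ``M @ spikes`` gives each neuron's summed weighted input from the
        neurons spiking in the current bin.
        """
        n = self.topology.n_neurons
        return sp.csr_matrix(
            (self.values, (self.target, self.source)), shape=(n, n)
        )


def build_topology(rows: int = 33, cols: int = 33) -> MeshTopology:
    """Build a rows x cols mesh (validated); 33 x 33 = 1089 neurons by default."""
    return MeshTopology(rows, cols)


def truncate(x):
    """Truncation F: 1 for x >= 1, x for -1 < x < 1, -1 for x <= -1."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("truncate requires finite input")
    out = np.clip(x, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def sample_weight(c: float, u):
    """One weight draw w = F[(1 + c) u - c] from a uniform variate u in [0, 1)."""
    if not (0.0 < c <= 3.0):
        raise ValueError(f"c must satisfy 0 < c <= 3, got {c}")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u >= 1.0)):
        raise ValueError("u must lie in [0, 1)")
    return truncate((1.0 + c) * u - c)


def generate_weights(topology: MeshTopology, config: WeightConfig) -> SynapticWeights:
    """Draw one independent weight per ordered neighbour pair.

    Reproducible: the same seed and topology yield a bit-identical map
    because pairs are enumerated in the canonical order.
    """
    src, dst = topology.directed_pairs()
    rng = np.random.default_rng(config.seed)
    u = rng.random(len(src))
    values = sample_weight(config.c, u)
    return SynapticWeights(topology=topology, values=values, source=src, target=dst)


def weight_sign_ratio(weights: SynapticWeights | np.ndarray) -> float:
    """Ratio (#positive weights) / (#negative weights); exact zeros in neither.

    Raises ZeroDivisionError when no negative weight exists.
    """
    w = weights.values if isinstance(weights, SynapticWeights) else np.asarray(weights)
    n_pos = int(np.count_nonzero(w > 0))
    n_neg = int(np.count_nonzero(w < 0))
    if n_neg == 0:
        raise ZeroDivisionError("no negative weights; sign ratio undefined")
    return n_pos / n_neg
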