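"""Virtual 8x8 multielectrode array over the mesh.

Each electrode sits on a regular subgrid of the 33x33 mesh (pitch 4 neuron
rows, centres at 0-based rows/cols 2, 6, ..., 30) and captures the spikes of
``m`` member neurons sampled from the 3x3 block around its centre (4x4 in
the expanded layout, allowing m up to 16).  Pooling is unsorted multiunit
recording: the electrode train has a 1 at bin t iff at least one member
emitted at t.

The number of captured neurons varies electrode by electrode; ``m_spec``
accepts a fixed count, an explicit probability distribution over m, or the
default uniform draw on {2, ..., 9}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import MeshTopology
from .neurons import SpikeRaster

__all__ = [
    "ELECTRODE_GRID",
    "ELECTRODE_PITCH",
    "ElectrodeLayout",
    "ElectrodeTrains",
    "build_layout",
    "pool_spikes",
]

ELECTRODE_GRID: tuple[int, int] = (8, 8)
ELECTRODE_PITCH: int = 4
_FIRST_CENTER: int = 2  # 0-based; 1-based row 3


@dataclass
class ElectrodeLayout:
    """Electrode centres and per-electrode capture sets (flat neuron indices)."""

    topology: MeshTopology
    centers: np.ndarray  # (n_electrodes, 2) 0-based mesh (row, col)
    members: list[np.ndarray]
    expanded: bool = False
    grid: tuple[int, int] = ELECTRODE_GRID

    def __post_init__(self) -> None:
        if len(self.members) != len(self.centers):
            raise ValueError("one member set per electrode required")
        cap = 16 if self.expanded else 9
        for mem in self.members:
            if not (1 <= len(mem) <= cap):
                raise ValueError(f"capture-set size {len(mem)} outside [1, {cap}]")

    @property
    def n_electrodes(self) -> int:
        return len(self.members)

    @property
    def m(self) -> np.ndarray:
        """Capture-set size of each electrode."""
        return np.array([len(mem) for mem in self.members])

    def electrode_index(self, row: int, col: int) -> int:
        """Flat index of electrode at 0-based grid (row, col)."""
        return row * self.grid[1] + col

    def electrode_coords(self, idx: int) -> tuple[int, int]:
        return divmod(idx, self.grid[1])


@dataclass
class ElectrodeTrains:
    """Pooled binary trains, one row per electrode."""

    trains: np.ndarray  # bool (n_electrodes, horizon)
    layout: ElectrodeLayout

    @property
    def horizon(self) -> int:
        return self.trains.shape[1]


def _capture_block(
    topology: MeshTopology, center: tuple[int, int], expanded: bool
) -> np.ndarray:
    """Flat indices of the 3x3 (or 4x4 expanded) block around a centre."""
    row, col = center
    if expanded:
        rows = range(row - 1, row + 3)
        cols = range(col - 1, col + 3)
    else:
        rows = range(row - 1, row + 2)
        cols = range(col - 1, col + 2)
    idx = [
        topology.flat(r, c)
        for r in rows
        for c in cols
        if 0 <= r < topology.rows and 0 <= c < topology.cols
    ]
    return np.asarray(idx, dtype=np.int64)


def _draw_m(
    m_spec, block_size: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(m_spec, (int, np.integer)):
        m = np.full(n, int(m_spec))
    elif isinstance(m_spec, dict):
        ms = np.array(sorted(m_spec))
        p = np.array([m_spec[k] for k in ms], dtype=float)
        p = p / p.sum()
        m = rng.choice(ms, size=n, p=p)
    elif m_spec == "uniform":
        m = rng.integers(2, 10, size=n)
    else:
        raise ValueError(f"unrecognised m_spec: {m_spec!r}")
    if np.any(m > block_size):
        raise ValueError(f"m exceeds capture-block size {block_size}")
    if np.any(m < 1):
        raise ValueError("m must be >= 1")
    return m


def build_layout(
    topology: MeshTopology,
    m_spec="uniform",
    expanded: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ElectrodeLayout:
    """Place the 8x8 array and sample each electrode's capture set.

    ``m_spec``: fixed int, dict {m: probability}, or "uniform" (on {2..9}).
    Members are sampled without replacement from the electrode's capture
    block; blocks of neighbouring electrodes are disjoint (block width 3 or
    4 at pitch 4).
    """
    rows, cols = ELECTRODE_GRID
    need = _FIRST_CENTER + ELECTRODE_PITCH * (rows - 1) + (3 if expanded else 2)
    if topology.rows < need or topology.cols < need:
        raise ValueError(f"topology too small for the 8x8 array (needs {need})")
    if rng is None:
        rng = np.random.default_rng(seed)
    centers = np.array(
        [
            (_FIRST_CENTER + ELECTRODE_PITCH * r, _FIRST_CENTER + ELECTRODE_PITCH * c)
            for r in range(rows)
            for c in range(cols)
        ]
    )
    block_size = 16 if expanded else 9
    m = _draw_m(m_spec, block_size, len(centers), rng)
    members = []
    for center, mi in zip(centers, m):
        block = _capture_block(topology, tuple(center), expanded)
        members.append(np.sort(rng.choice(block, size=int(mi), replace=False)))
    return ElectrodeLayout(
        topology=topology, centers=centers, members=members, expanded=expanded
    )


def pool_spikes(raster: SpikeRaster, layout: ElectrodeLayout) -> ElectrodeTrains:
    """OR-pool member-neuron rows of the raster into per-electrode trains."""
    if raster.topology != layout.topology:
        raise ValueError("raster and layout must share the same topology")
    trains = np.zeros((layout.n_electrodes, raster.horizon), dtype=bool)
    for e, mem in enumerate(layout.members):
        trains[e] = raster.spikes[mem].any(axis=0)
    return ElectrodeTrains(trains=trains, layout=layout)
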