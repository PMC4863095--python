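"""Plain-text readers and writers for every pipeline artifact.

All on-disk coordinates are 1-based — neuron positions in {1..33},
electrode grid positions in {(1,1)..(8,8)}, bins starting at 1 — matching
the conventional labelling of mesh and array positions.  In-memory objects
are 0-based throughout; conversion happens only here.

Formats: TSV for event tables (rasters, trains, detections, weights), CSV
for spectra, JSON for layouts / libraries / fit results / run manifests,
YAML for configuration.  Everything round-trips: read(write(x)) == x.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codes import CODES, N_CODES, CodeSpectrum
from .electrodes import ElectrodeLayout, ElectrodeTrains
from .fitting import ComponentLibrary, FitResult
from .mesh import MeshTopology, SynapticWeights
from .neurons import SpikeRaster

__all__ = [
    "write_weights", "read_weights",
    "write_raster", "read_raster",
    "write_trains", "read_trains",
    "write_detections", "read_detections",
    "write_spectrum", "read_spectrum",
    "write_layout", "read_layout",
    "write_library", "read_library",
    "write_fit_result", "read_fit_result",
    "write_manifest", "load_config",
    "file_digest",
]


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# --- synaptic weights -------------------------------------------------------

def write_weights(weights: SynapticWeights, path) -> None:
    topo = weights.topology
    sr, sc = topo.coords(weights.source)
    tr, tc = topo.coords(weights.target)
    df = pd.DataFrame(
        {
            "i_x": sr + 1, "i_y": sc + 1,
            "j_x": tr + 1, "j_y": tc + 1,
            "w": [f"{v:.10g}" for v in weights.values],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_weights(path, topology: MeshTopology) -> SynapticWeights:
    df = pd.read_csv(path, sep="\t")
    src = topology.flat(df["i_x"].to_numpy() - 1, df["i_y"].to_numpy() - 1)
    dst = topology.flat(df["j_x"].to_numpy() - 1, df["j_y"].to_numpy() - 1)
    return SynapticWeights(
        topology=topology,
        values=df["w"].to_numpy(dtype=float),
        source=np.asarray(src),
        target=np.asarray(dst),
    )


# --- spike rasters ----------------------------------------------------------

def write_raster(raster: SpikeRaster, path) -> None:
    neuron, t = raster.events()
    r, c = raster.topology.coords(neuron)
    pd.DataFrame({"neuron_x": r + 1, "neuron_y": c + 1, "bin": t + 1}).to_csv(
        path, sep="\t", index=False
    )


def read_raster(path, topology: MeshTopology, horizon: int) -> SpikeRaster:
    df = pd.read_csv(path, sep="\t")
    spikes = np.zeros((topology.n_neurons, horizon), dtype=bool)
    flat = topology.flat(df["neuron_x"].to_numpy() - 1, df["neuron_y"].to_numpy() - 1)
    spikes[flat, df["bin"].to_numpy() - 1] = True
    return SpikeRaster(spikes=spikes, topology=topology)


# --- electrode trains -------------------------------------------------------

def write_trains(trains: ElectrodeTrains, path) -> None:
    e, t = np.nonzero(trains.trains)
    cols = trains.layout.grid[1]
    pd.DataFrame(
        {"electrode_row": e // cols + 1, "electrode_col": e % cols + 1, "bin": t + 1}
    ).to_csv(path, sep="\t", index=False)


def read_trains(path, layout: ElectrodeLayout, horizon: int) -> ElectrodeTrains:
    df = pd.read_csv(path, sep="\t")
    arr = np.zeros((layout.n_electrodes, horizon), dtype=bool)
    e = (df["electrode_row"].to_numpy() - 1) * layout.grid[1] + (
        df["electrode_col"].to_numpy() - 1
    )
    arr[e, df["bin"].to_numpy() - 1] = True
    return ElectrodeTrains(trains=arr, layout=layout)


# --- detections -------------------------------------------------------------

def write_detections(detections: pd.DataFrame, path, grid_cols: int = 8) -> None:
    e = detections["electrode"].to_numpy()
    out = pd.DataFrame(
        {
            "electrode_row": e // grid_cols + 1,
            "electrode_col": e % grid_cols + 1,
            "code_number": detections["code_number"],
            "pattern": [CODES[c - 1] for c in detections["code_number"]],
            "start_bin": detections["start_bin"] + 1,
            "width_bins": detections["width"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_detections(path, grid_cols: int = 8) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "electrode": (df["electrode_row"] - 1) * grid_cols
            + (df["electrode_col"] - 1),
            "code_number": df["code_number"],
            "start_bin": df["start_bin"] - 1,
            "width": df["width_bins"],
        }
    )


# --- spectra ----------------------------------------------------------------

def write_spectrum(spectrum: CodeSpectrum, path) -> None:
    spectrum.to_frame().to_csv(path, index=False)


def read_spectrum(path) -> CodeSpectrum:
    df = pd.read_csv(path)
    counts = np.zeros(N_CODES)
    counts[df["code_number"].to_numpy() - 1] = df["count"].to_numpy(dtype=float)
    return CodeSpectrum(counts=counts)


# --- layouts ----------------------------------------------------------------

def write_layout(layout: ElectrodeLayout, path) -> None:
    cols = layout.topology.cols
    data = {
        "topology": {"rows": layout.topology.rows, "cols": layout.topology.cols},
        "grid": list(layout.grid),
        "expanded": layout.expanded,
        "electrodes": [
            {
                "id": [e // layout.grid[1] + 1, e % layout.grid[1] + 1],
                "center": [int(r) + 1, int(c) + 1],
                "members": [
                    [int(m) // cols + 1, int(m) % cols + 1] for m in layout.members[e]
                ],
            }
            for e, (r, c) in enumerate(layout.centers)
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_layout(path) -> ElectrodeLayout:
    data = json.loads(Path(path).read_text())
    topo = MeshTopology(data["topology"]["rows"], data["topology"]["cols"])
    centers = np.array([[e["center"][0] - 1, e["center"][1] - 1] for e in data["electrodes"]])
    members = [
        np.array(sorted(topo.flat(r - 1, c - 1) for r, c in e["members"]), dtype=np.int64)
        for e in data["electrodes"]
    ]
    return ElectrodeLayout(
        topology=topo,
        centers=centers,
        members=members,
        expanded=data["expanded"],
        grid=tuple(data["grid"]),
    )


# --- component library ------------------------------------------------------

def write_library(library: ComponentLibrary, directory) -> None:
    """One CSV per (a0, c) cell plus a JSON metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "a0_grid_bins": list(library.a0_grid),
        "c_grid": list(library.c_grid),
        "m_values": list(library.m_values),
        "n_trials": library.n_trials,
        "seed": library.seed,
        "missing_threshold": library.missing_threshold,
        "totals": {f"{a0}_{c:g}": library.totals.get((a0, c), 0.0) for a0, c in library.cells()},
        "missing": [f"{a0}_{c:g}" for a0, c in library.cells() if library.is_missing((a0, c))],
    }
    (directory / "library.json").write_text(json.dumps(meta, indent=1))
    for (a0, c), spec in library.spectra.items():
        df = pd.DataFrame(spec, columns=[f"E{m}" for m in library.m_values])
        df.insert(0, "code_number", np.arange(1, N_CODES + 1))
        df.to_csv(directory / f"cell_a0-{a0}_c-{c:g}.csv", index=False)


def read_library(directory) -> ComponentLibrary:
    directory = Path(directory)
    meta = json.loads((directory / "library.json").read_text())
    lib = ComponentLibrary(
        a0_grid=tuple(meta["a0_grid_bins"]),
        c_grid=tuple(meta["c_grid"]),
        m_values=tuple(meta["m_values"]),
        n_trials=meta["n_trials"],
        seed=meta["seed"],
        missing_threshold=meta["missing_threshold"],
    )
    for a0 in lib.a0_grid:
        for c in lib.c_grid:
            path = directory / f"cell_a0-{a0}_c-{c:g}.csv"
            if path.exists():
                df = pd.read_csv(path)
                lib.spectra[(a0, c)] = df[[f"E{m}" for m in lib.m_values]].to_numpy()
                lib.totals[(a0, c)] = meta["totals"][f"{a0}_{c:g}"]
    return lib


# --- fit results ------------------------------------------------------------

def write_fit_result(result: FitResult, path) -> None:
    data = {
        "best_cell": {"a0_bins": result.best_cell[0], "c": result.best_cell[1]},
        "second_cell": (
            {"a0_bins": result.second_cell[0], "c": result.second_cell[1]}
            if result.second_cell
            else None
        ),
        "error": result.error,
        "m_values": list(result.m_values),
        "weights": list(map(float, result.weights)),
        "error_grid": [
            {"a0_bins": a0, "c": c, "error": e}
            for (a0, c), e in sorted(result.error_grid.items())
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_fit_result(path) -> FitResult:
    data = json.loads(Path(path).read_text())
    grid = {(d["a0_bins"], d["c"]): d["error"] for d in data["error_grid"]}
    return FitResult(
        best_cell=(data["best_cell"]["a0_bins"], data["best_cell"]["c"]),
        weights=np.array(data["weights"]),
        error=data["error"],
        error_grid=grid,
        second_cell=(
            (data["second_cell"]["a0_bins"], data["second_cell"]["c"])
            if data["second_cell"]
            else None
        ),
        m_values=tuple(data["m_values"]),
    )


# --- manifest & config ------------------------------------------------------

def write_manifest(path, seed: int, parameters: dict, outputs: dict) -> None:
    """Run manifest: seed, parameters, package version, timestamps, digests."""
    manifest = {
        "package": "codespectrum",
        "version": __version__,
        "seed": seed,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "parameters": parameters,
        "outputs": {name: file_digest(p) for name, p in outputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
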