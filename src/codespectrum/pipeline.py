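"""End-to-end pipeline driver and deterministic test fixtures.

``run_pipeline`` executes simulate -> pool -> decode -> spectrum, and
optionally the mixture fit and the code-flow cross-correlation, from a
single configuration mapping; every run writes a manifest with the seed,
parameters and output digests so it can be reproduced bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import codes, flow, io
from ._rng import substream
from .electrodes import build_layout, pool_spikes
from .fitting import build_component_library, grid_fit, synthesize_target
from .mesh import WeightConfig, build_topology, generate_weights
from .neurons import SimulationConfig, Stimulus, sample_neuron_params, simulate

__all__ = ["run_pipeline", "make_fixtures", "validate_config"]

_SCHEMA = {
    "rows": int, "cols": int, "horizon": int, "a0": int,
    "c": float, "p_a": float, "p_d": float, "seed": int,
    "m_spec": object, "widths": list, "window": int,
    "stimulus": dict, "fit": dict, "xcorr": dict, "tolerance": int,
}

_DEFAULTS = {
    "rows": 33, "cols": 33, "horizon": 2000, "a0": 80,
    "c": 2.5, "p_a": 1 / 12, "p_d": 1 / 12, "seed": 0,
    "m_spec": "uniform", "widths": list(codes.DEFAULT_WIDTHS),
    "window": 2000, "tolerance": 0,
    "stimulus": {"electrode": [1, 1], "bin": 1},
}


def validate_config(config: dict) -> dict:
    """Merge with defaults and reject unknown or ill-typed fields.

    Errors name the offending field path.
    """
    cfg = dict(_DEFAULTS)
    for key, value in (config or {}).items():
        if key not in _SCHEMA:
            raise ValueError(f"config: unknown field '{key}'")
        want = _SCHEMA[key]
        if want in (int, float):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"config.{key}: expected a number, got {value!r}")
            value = want(value)
        elif want is list and not isinstance(value, list):
            raise ValueError(f"config.{key}: expected a list")
        elif want is dict and not isinstance(value, dict):
            raise ValueError(f"config.{key}: expected a mapping")
        cfg[key] = value
    stim = cfg["stimulus"]
    if "electrode" not in stim or "bin" not in stim:
        raise ValueError("config.stimulus: needs 'electrode' [row, col] and 'bin'")
    return cfg


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the configured pipeline; returns {artifact name: path}.

    ``seed`` overrides ``config['seed']``.  Coordinates in the config are
    1-based (file convention).
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    root = cfg["seed"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    topology = build_topology(cfg["rows"], cfg["cols"])
    weights = generate_weights(
        topology,
        WeightConfig(c=cfg["c"], seed=int(substream(root, "weights").integers(2**31))),
    )
    sim_cfg = SimulationConfig(
        horizon=cfg["horizon"], a0=cfg["a0"], p_a=cfg["p_a"], p_d=cfg["p_d"]
    )
    params = sample_neuron_params(sim_cfg, topology.n_neurons, substream(root, "params"))
    layout = build_layout(topology, m_spec=cfg["m_spec"], rng=substream(root, "layout"))

    er, ec = cfg["stimulus"]["electrode"]
    stim_idx = layout.electrode_index(er - 1, ec - 1)
    center = tuple(layout.centers[stim_idx])
    stimulus = Stimulus.triple_at(topology, center, bin=cfg["stimulus"]["bin"] - 1)

    raster = simulate(topology, weights, params, sim_cfg, stimulus, substream(root, "sim"))
    trains = pool_spikes(raster, layout)
    detections = codes.detect_codes(
        trains, widths=cfg["widths"], window=cfg["window"], tolerance=cfg["tolerance"]
    )
    spectrum = codes.compute_spectrum(
        detections[detections["electrode"] != stim_idx],
        window=cfg["window"],
        n_electrodes=layout.n_electrodes - 1,
    )

    paths = {
        "weights": out / "weights.tsv",
        "layout": out / "layout.json",
        "raster": out / "raster.tsv",
        "trains": out / "trains.tsv",
        "detections": out / "detections.tsv",
        "spectrum": out / "spectrum.csv",
    }
    io.write_weights(weights, paths["weights"])
    io.write_layout(layout, paths["layout"])
    io.write_raster(raster, paths["raster"])
    io.write_trains(trains, paths["trains"])
    io.write_detections(detections, paths["detections"])
    io.write_spectrum(spectrum, paths["spectrum"])

    if "xcorr" in cfg:
        xc = cfg["xcorr"]
        table = flow.code_flow_table(
            detections,
            horizon=cfg["window"],
            mode=xc.get("mode", "8N"),
            codes_of_interest=xc.get("codes"),
        )
        table = table.assign(
            electrode_row=table["electrode_row"] + 1,
            electrode_col=table["electrode_col"] + 1,
        )
        paths["xcorr"] = out / "xcorr.csv"
        table.to_csv(paths["xcorr"], index=False)

    if "fit" in cfg:
        fit_cfg = cfg["fit"]
        library = io.read_library(fit_cfg["library"])
        result = grid_fit(spectrum.counts, library)
        paths["fit"] = out / "fit.json"
        io.write_fit_result(result, paths["fit"])

    io.write_manifest(
        out / "manifest.json",
        seed=root,
        parameters={k: v for k, v in cfg.items() if k != "seed"},
        outputs={name: p for name, p in paths.items()},
    )
    paths["manifest"] = out / "manifest.json"
    return {name: str(p) for name, p in paths.items()}


def make_fixtures(kind: str, out_dir, seed: int = 0) -> str:
    """Write one of the small deterministic inputs used by the test suite.

    kinds: 'toy-raster' (3x3 mesh, two spiking neurons), 'toy-train' (the
    3-spike train whose only width-6 match is "1101"), 'synthetic-target'
    (a 21-entry spectrum at a0 = 70 bins, c = 1.0), 'mini-library' (a
    2-cell library over m = {2, 3}).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "toy-train":
        train = np.zeros(40, dtype=bool)
        train[[10, 16, 28]] = True  # "1101" sampled at width 6 from bin 10
        t = np.nonzero(train)[0]
        path = out / "toy_train.tsv"
        with open(path, "w") as fh:
            fh.write("electrode_row\telectrode_col\tbin\n")
            for b in t:
                fh.write(f"1\t1\t{b + 1}\n")
        return str(path)
    if kind == "toy-raster":
        topo = build_topology(3, 3)
        spikes = np.zeros((9, 10), dtype=bool)
        spikes[topo.flat(1, 1), 0] = True
        spikes[topo.flat(1, 2), 3] = True
        from .neurons import SpikeRaster

        path = out / "toy_raster.tsv"
        io.write_raster(SpikeRaster(spikes=spikes, topology=topo), path)
        return str(path)
    if kind == "synthetic-target":
        counts = synthesize_target(
            70, 1.0, {m: 1 / 8 for m in range(2, 10)}, n_trials=1, seed=seed
        )
        path = out / "synthetic_target.csv"
        io.write_spectrum(codes.CodeSpectrum(counts=counts), path)
        return str(path)
    if kind == "mini-library":
        lib = build_component_library(
            a0_grid=(70,), c_grid=(0.3, 1.0), m_values=(2, 3),
            n_trials=1, seed=seed,
        )
        path = out / "mini_library"
        io.write_library(lib, path)
        return str(path)
    raise ValueError(f"unknown fixture kind {kind!r}")
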