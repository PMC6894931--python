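"""Recording container, graph export and the end-to-end pipeline.

Sweep sets are persisted in a documented HDF5 layout::

    /sweeps/<sweep>/<channel>   float64 sample arrays (mV)
    /ground_truth/...           optional known-connectivity block
    attrs["manifest"]           JSON: version, seed, rate, cells, protocol,
                                provenance (tool version, config hash)

Round trips are lossless (bit-exact samples).  Connectivity results export
as an edge-list CSV, a dense adjacency JSON, or GraphML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .detect import ConnectivityResult
from .errors import ConfigError, IntegrityError, InvalidArgumentError, UnsupportedVersionError
from .synthgen import GroundTruthNetwork, StimProtocol, SweepSet

__all__ = [
    "CONTAINER_VERSION",
    "write_container",
    "read_container",
    "export_graph",
    "import_adjacency_json",
    "run_pipeline",
]

CONTAINER_VERSION = 1


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def write_container(path, sweeps: SweepSet, ground_truth: GroundTruthNetwork | None = None) -> None:
    """Write a sweep set (and optional ground truth) to the HDF5 container."""
    proto = asdict(sweeps.protocol)
    manifest = {
        "version": CONTAINER_VERSION,
        "seed": sweeps.seed,
        "rate_hz": sweeps.rate_hz,
        "n_cells": sweeps.n_channels,
        "n_sweeps": sweeps.n_sweeps,
        "protocol": proto,
        "tool_version": __version__,
        "config_hash": _config_hash(proto),
    }
    with h5py.File(path, "w") as fh:
        fh.attrs["manifest"] = json.dumps(manifest, sort_keys=True)
        grp = fh.create_group("sweeps")
        for s in range(sweeps.n_sweeps):
            sg = grp.create_group(f"{s:03d}")
            for c in range(sweeps.n_channels):
                sg.create_dataset(f"ch{c:02d}", data=sweeps.data[s, c])
        if ground_truth is not None:
            gt = fh.create_group("ground_truth")
            gt.create_dataset("adjacency", data=ground_truth.adjacency)
            gt.create_dataset("amplitude_mv", data=ground_truth.amplitude_mv)
            gt.create_dataset("latency_ms", data=ground_truth.latency_ms)
            gt.create_dataset("soma_positions_um", data=ground_truth.soma_positions_um)
            gt.attrs["rise_ms"] = ground_truth.rise_ms
            gt.attrs["decay_ms"] = ground_truth.decay_ms
            gt.attrs["trial_cv"] = ground_truth.trial_cv
            for c, st in enumerate(ground_truth.spike_times_s):
                gt.create_dataset(f"spike_times_{c:02d}", data=np.asarray(st))


def read_container(path):
    """Read a container back; returns ``(SweepSet, GroundTruthNetwork | None)``."""
    with h5py.File(path, "r") as fh:
        if "manifest" not in fh.attrs:
            raise IntegrityError("container has no manifest")
        manifest = json.loads(fh.attrs["manifest"])
        if manifest.get("version") != CONTAINER_VERSION:
            raise UnsupportedVersionError(
                f"container version {manifest.get('version')!r}, supported: {CONTAINER_VERSION}"
            )
        n_sweeps = manifest["n_sweeps"]
        n_cells = manifest["n_cells"]
        data = None
        for s in range(n_sweeps):
            sname = f"sweeps/{s:03d}"
            if sname not in fh:
                raise IntegrityError(f"missing sweep group {sname}")
            for c in range(n_cells):
                cname = f"{sname}/ch{c:02d}"
                if cname not in fh:
                    raise IntegrityError(f"missing channel dataset {cname}")
                arr = fh[cname][()]
                if data is None:
                    data = np.empty((n_sweeps, n_cells, arr.size))
                data[s, c] = arr
        protocol = StimProtocol(**manifest["protocol"])
        sweeps = SweepSet(data=data, rate_hz=manifest["rate_hz"], protocol=protocol,
                          seed=manifest["seed"])
        gt = None
        if "ground_truth" in fh:
            g = fh["ground_truth"]
            gt = GroundTruthNetwork(
                adjacency=g["adjacency"][()].astype(bool),
                amplitude_mv=g["amplitude_mv"][()],
                latency_ms=g["latency_ms"][()],
                rise_ms=float(g.attrs["rise_ms"]),
                decay_ms=float(g.attrs["decay_ms"]),
                trial_cv=float(g.attrs["trial_cv"]),
                soma_positions_um=g["soma_positions_um"][()],
                spike_times_s=[g[f"spike_times_{c:02d}"][()] for c in range(n_cells)],
            )
    return sweeps, gt


# ---------------------------------------------------------------------------
# graph export
# ---------------------------------------------------------------------------

def export_graph(result: ConnectivityResult, path, fmt: str = "edge_csv") -> None:
    """Serialise a connectivity result deterministically (sorted cell ids)."""
    if fmt == "edge_csv":
        df = result.to_edge_dataframe().sort_values(["pre_id", "post_id"])
        df.to_csv(path, index=False)
    elif fmt == "adjacency_json":
        obj = {
            "cells": list(result.cell_ids),
            "tested": result.tested.astype(int).tolist(),
            "connected": result.connected.astype(int).tolist(),
            "amplitude_mV": np.where(np.isnan(result.amplitude_mv), None,
                                     result.amplitude_mv).tolist(),
            "latency_ms": np.where(np.isnan(result.latency_ms), None,
                                   result.latency_ms).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True)
    elif fmt == "graph_ml":
        import networkx as nx

        g = nx.DiGraph()
        for cid in result.cell_ids:
            g.add_node(str(cid))
        n = len(result.cell_ids)
        for i in range(n):
            for j in range(n):
                if result.connected[i, j]:
                    g.add_edge(str(result.cell_ids[i]), str(result.cell_ids[j]),
                               amplitude_mV=float(result.amplitude_mv[i, j]),
                               latency_ms=float(result.latency_ms[i, j]))
        nx.write_graphml(g, path)
    else:
        raise InvalidArgumentError(f"unknown export format {fmt!r}")


def import_adjacency_json(path) -> ConnectivityResult:
    with open(path) as fh:
        obj = json.load(fh)
    amp = np.array([[np.nan if v is None else v for v in row] for row in obj["amplitude_mV"]])
    lat = np.array([[np.nan if v is None else v for v in row] for row in obj["latency_ms"]])
    n = len(obj["cells"])
    return ConnectivityResult(
        cell_ids=list(obj["cells"]),
        tested=np.asarray(obj["tested"], dtype=bool),
        connected=np.asarray(obj["connected"], dtype=bool),
        amplitude_mv=amp,
        latency_ms=lat,
        distance_um=np.full((n, n), np.nan),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_REQUIRED_CONFIG = {
    "seed": int,
    "n_cells": int,
    "p_conn": (int, float),
    "n_sweeps": int,
}


def run_pipeline(config, out_dir) -> dict:
    """Synthesise a cluster, extract features, call connections, write artifacts.

    ``config`` is a dict (or path to a YAML file) with at least seed,
    n_cells, p_conn and n_sweeps; optional keys noise_sd_mv, trial_cv and
    k_sd.  Artifacts (container, cells.csv, edges.csv, adjacency.json,
    stats.json, log.jsonl) land in ``out_dir``; identical configs produce
    identical outputs.
    """
    from pathlib import Path

    import yaml

    from .detect import build_connectivity, screen_connections
    from .ephys import measure_resistances, qc_filter, resting_potential
    from .planner import SessionPlan
    from .stats import connection_probability
    from .synthgen import CellParams, synth_cluster, vc_test_pulse

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    problems = []
    for key, typ in _REQUIRED_CONFIG.items():
        if key not in config:
            problems.append(f"missing field {key!r}")
        elif not isinstance(config[key], typ):
            problems.append(f"field {key!r} must be {typ}")
    if problems:
        raise ConfigError(problems)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k_sd = float(config.get("k_sd", 3.0))
    sweeps, gt = synth_cluster(
        n_cells=config["n_cells"],
        p_conn=config["p_conn"],
        n_sweeps=config["n_sweeps"],
        noise_sd_mv=float(config.get("noise_sd_mv", 0.2)),
        trial_cv=float(config.get("trial_cv", 0.3)),
        seed=config["seed"],
    )
    write_container(out / "cluster.h5", sweeps, gt)

    # per-cell properties from the averaged own channel + a seal test
    from .detect import average_sweeps

    rows = []
    for c in range(sweeps.n_channels):
        avg = average_sweeps(sweeps, c)
        pulse = vc_test_pulse(CellParams())
        props = measure_resistances(pulse)
        rows.append({
            "cell_id": f"{c + 1}.1",
            "rmp_mV": resting_potential(avg),
            "ra_MOhm": props.ra_mohm,
            "rin_MOhm": props.rin_mohm,
        })
    cells = pd.DataFrame(rows)
    qc = qc_filter(cells)
    qc.table.to_csv(out / "cells.csv", index=False)

    calls = screen_connections(sweeps, k_sd=k_sd)
    plan = SessionPlan(sessions=((sweeps.n_channels, 0),), n_pipettes=sweeps.n_channels)
    result = build_connectivity(calls, plan, positions=gt.soma_positions_um)
    export_graph(result, out / "edges.csv", "edge_csv")
    export_graph(result, out / "adjacency.json", "adjacency_json")

    stats_obj = {
        "n_cells": sweeps.n_channels,
        "n_tested": result.n_tested,
        "n_connected": result.n_connected,
        "connection_probability": connection_probability(result.n_connected, result.n_tested),
        "n_true_edges": gt.n_edges,
        "k_sd": k_sd,
        "seed": config["seed"],
        "config_hash": _config_hash({k: config[k] for k in sorted(config)}),
        "tool_version": __version__,
    }
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_obj, fh, sort_keys=True, indent=1)
    with open(out / "log.jsonl", "w") as fh:
        for record in ({"event": "pipeline-start", **stats_obj},
                       {"event": "pipeline-end", "artifacts": sorted(
                           p.name for p in out.iterdir())}):
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    return stats_obj
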