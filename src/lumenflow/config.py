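"""Run configuration, seeding and output plumbing.

A run is fully described by a YAML/JSON mapping with ``network``, ``scenario``
and ``transport`` blocks plus a master seed; every stochastic stream (schedule
sampling, junction volumes, particle noise) derives its sub-seed from the
master seed through labelled ``numpy.random.SeedSequence`` spawns, so a run is
reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .network import (TubularNetwork, build_honeycomb,
                      generate_er_like_network, network_statistics,
                      read_network, write_network)
from .observables import summarise
from .particles import TransportConfig, mixing_experiment, simulate_ensemble
from .scenarios import ConfigError, ScenarioConfig, build_schedule, run_scenario


def subseed(master: int, label: str) -> int:
    """Stable sub-seed (< 2³¹) derived from the master seed and a stream label."""
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _require(cond: bool, msg: str):
    if not cond:
        raise ConfigError(msg)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    _require(isinstance(cfg, dict), "config must be a mapping")
    return cfg


def build_network_from_config(block: dict) -> TubularNetwork:
    kind = block.get("type", "honeycomb")
    if kind == "honeycomb":
        return build_honeycomb(int(block.get("rows", 10)),
                               int(block.get("cols", 10)),
                               float(block.get("edge_length", 1.0)))
    if kind == "generate":
        return generate_er_like_network(
            int(block.get("n_nodes", 200)),
            float(block.get("target_mean_edge_length", 1.0)),
            seed=int(block.get("seed", 0)))
    if kind == "file":
        _require("path" in block, "network block of type 'file' needs 'path'")
        return read_network(block["path"], block.get("format"))
    raise ConfigError(f"unknown network type {kind!r}")


def scenario_from_config(block: dict) -> ScenarioConfig:
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(block) - known
    _require(not unknown, f"unknown scenario keys: {sorted(unknown)}")
    if "sheet_node_ids" in block:
        block = dict(block, sheet_node_ids=tuple(block["sheet_node_ids"]))
    return ScenarioConfig(**block)


def transport_from_config(block: dict, master_seed: int) -> TransportConfig:
    known = {f.name for f in dataclasses.fields(TransportConfig)}
    unknown = set(block) - known
    _require(not unknown, f"unknown transport keys: {sorted(unknown)}")
    tcfg = TransportConfig(**block)
    if "seed" not in block:
        tcfg.seed = subseed(master_seed, "particles")
    return tcfg


def run_from_config(cfg: dict, outdir) -> dict:
    """Execute a configured run and write its outputs.

    Writes network.json, schedule.json, traversals.csv,
    instantaneous_speeds.csv, flow_stats.json (when flows are solved),
    summary.json and manifest.json into ``outdir``; for mixing runs also
    mixing_variance.csv.  Returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("seed", 0))
    net = build_network_from_config(cfg.get("network", {}))
    scfg = scenario_from_config(cfg.get("scenario", {}))
    tcfg = transport_from_config(cfg.get("transport", {}), master_seed)
    if scfg.mechanism == "perinuclear-sheet":
        from .scenarios import configure_perinuclear
        net, base = configure_perinuclear(net, scfg.sheet_node_ids,
                                          scfg.v_sheet, scfg.sheet_two_T)
    write_network(net, outdir / "network.json")
    sched = build_schedule(net, scfg, tcfg.t_end,
                           subseed(master_seed, "schedule"))
    (outdir / "schedule.json").write_text(sched.to_json())

    mixing = cfg.get("mixing", False)
    if mixing:
        times, var, store = mixing_experiment(
            net, sched if scfg.mechanism != "diffusion-only" else None,
            tcfg.n_particles, t_end=tcfg.t_end, config=tcfg)
        import pandas as pd
        pd.DataFrame({"time": times, "variance": var}).to_csv(
            outdir / "mixing_variance.csv", index=False)
    else:
        store = simulate_ensemble(
            net, sched if scfg.mechanism != "diffusion-only" else None, tcfg)
    summary = summarise(store)

    store.traversals().to_csv(outdir / "traversals.csv", index=False)
    import pandas as pd
    pd.DataFrame({"speed": summary.instantaneous_speeds}).to_csv(
        outdir / "instantaneous_speeds.csv", index=False)
    if summary.flow is not None:
        (outdir / "flow_stats.json").write_text(json.dumps(summary.flow,
                                                           indent=1))
    out = {
        "mean_aets": summary.mean_aets,
        "n_traversals": int(len(summary.traversals)),
        "mean_instantaneous_speed": float(np.mean(summary.instantaneous_speeds))
        if len(summary.instantaneous_speeds) else None,
        "flow": summary.flow,
        "fit": summary.fit,
        "network": network_statistics(net),
    }
    (outdir / "summary.json").write_text(json.dumps(out, indent=1))
    manifest = {
        "version": __version__,
        "seed": master_seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
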