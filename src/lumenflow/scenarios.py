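"""Alternative flow-generation mechanisms and experiment orchestration.

Five contraction scenarios can drive the network:

* ``tubule-pinch`` — midpoint pinches on every edge (the baseline mechanism),
  optionally sped up (alpha), made more frequent (beta) or lengthened to the
  full tubule.
* ``junction`` — every tubular junction additionally contracts, expelling a
  volume f·ΔV per event with ΔV drawn from the truncated-normal law of the
  measured junction volumes; alpha/beta scale the junction event laws.
* ``perinuclear-sheet`` — designated sheet nodes connect to one large
  reservoir performing a single contraction + relaxation (2T = 5 s,
  Vsheet = 10 µm³ by default) on top of the tubule pinches.
* ``peripheral-sheet-1`` / ``peripheral-sheet-2`` — sheet volumes
  Vk ~ N(0.12, 0.04) µm³ are expelled through junction-style node sources:
  scenario 1 expels Vk/6 at every node with contractions 2.5× slower than the
  tubule pinches; scenario 2 expels Vk/2 at a random third of the nodes with
  contractions 5× slower.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contractions import (ContractionSchedule, JunctionModel,
                           PerinuclearSheet, PinchParameterDistributions,
                           sample_junction_schedule, sample_pinch_schedule)
from .network import TubularNetwork
from .observables import TransportSummary, summarise
from .particles import TransportConfig, simulate_ensemble

MECHANISMS = ("tubule-pinch", "junction", "perinuclear-sheet",
              "peripheral-sheet-1", "peripheral-sheet-2", "diffusion-only")


class ConfigError(ValueError):
    """Inconsistent scenario configuration."""


@dataclass
class ScenarioConfig:
    """Which mechanism drives the network, and with what parameters."""

    mechanism: str = "tubule-pinch"
    alpha: float = 1.0
    beta: float = 1.0
    f: float = 1.0                      # junction volume fraction
    length_policy: str = "sampled"      # or "full-tubule"
    include_tubule_pinches: bool = True
    v_sheet: float = 10.0               # µm³, perinuclear reservoir
    sheet_two_T: float = 5.0            # s, perinuclear 2T
    sheet_node_ids: tuple = ()
    peripheral_volume_mean: float = 0.12  # µm³
    peripheral_volume_sd: float = 0.04
    active_fraction: float = 1.0 / 3.0  # peripheral scenario 2

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError("alpha and beta must be positive")
        if not (0.0 <= self.f <= 1.0):
            raise ConfigError("f must lie in [0, 1]")
        if self.length_policy not in ("sampled", "full-tubule"):
            raise ConfigError(f"unknown length policy {self.length_policy!r}")


def configure_perinuclear(net: TubularNetwork, sheet_node_ids,
                          v_sheet: float = 10.0,
                          two_T: float = 5.0) -> tuple:
    """Assign sheet roles and return (network copy, ScenarioConfig).

    Sheet nodes join one common-pressure reservoir carrying the prescribed
    total source; they must be disjoint from the exit nodes (at least one
    exit must remain).
    """
    sheet_ids = set(int(n) for n in sheet_node_ids)
    if not sheet_ids:
        raise ConfigError("at least one sheet node is required")
    roles = list(net.roles)
    exits = set(int(n) for n in net.exit_nodes)
    if sheet_ids & exits and len(exits - sheet_ids) == 0:
        raise ConfigError("sheet nodes would leave no exit nodes")
    for nid in sheet_ids:
        if nid in exits and net.roles[net.node_index(nid)] == "exit":
            pass  # converting an exit to a sheet node is allowed
        roles[net.node_index(nid)] = "sheet"
    net2 = net.with_roles(roles)
    if len(net2.exit_nodes) < 1:
        raise ConfigError("no exit nodes remain after sheet assignment")
    cfg = ScenarioConfig(mechanism="perinuclear-sheet", v_sheet=v_sheet,
                         sheet_two_T=two_T,
                         sheet_node_ids=tuple(sorted(sheet_ids)))
    return net2, cfg


def build_schedule(net: TubularNetwork, scfg: ScenarioConfig, t_end: float,
                   seed) -> ContractionSchedule:
    """Sample the full contraction schedule of one scenario run."""
    ss = np.random.SeedSequence(seed)
    s_pinch, s_junc, s_pick = (int(s.generate_state(1)[0]) % (2 ** 31)
                               for s in ss.spawn(3))
    sched = ContractionSchedule(t_end=t_end)
    mech = scfg.mechanism
    if mech == "diffusion-only":
        return sched

    if mech == "tubule-pinch" or scfg.include_tubule_pinches:
        dists = PinchParameterDistributions(
            alpha=scfg.alpha if mech == "tubule-pinch" else 1.0,
            beta=scfg.beta if mech == "tubule-pinch" else 1.0)
        policy = scfg.length_policy if mech == "tubule-pinch" else "sampled"
        sched.pinch_sites = sample_pinch_schedule(
            net, dists, t_end, s_pinch, length_policy=policy)

    if mech == "junction":
        model = JunctionModel(f=scfg.f, alpha=scfg.alpha, beta=scfg.beta)
        exits = set(int(n) for n in net.exit_nodes)
        interior = [int(n) for n in net.node_ids if int(n) not in exits]
        sched.junction_events = sample_junction_schedule(
            net, model, t_end, s_junc, active_nodes=interior)
    elif mech == "perinuclear-sheet":
        if not scfg.sheet_node_ids:
            raise ConfigError("perinuclear scenario needs sheet node ids")
        sheet_set = set(scfg.sheet_node_ids)
        if sheet_set & set(int(n) for n in net.exit_nodes):
            raise ConfigError("sheet nodes overlap exit nodes")
        if not sheet_set <= set(int(n) for n in net.sheet_nodes):
            raise ConfigError("network roles do not mark the sheet nodes; "
                              "use configure_perinuclear first")
        sched.sheet = PerinuclearSheet(list(scfg.sheet_node_ids),
                                       v_sheet=scfg.v_sheet,
                                       T=0.5 * scfg.sheet_two_T)
    elif mech in ("peripheral-sheet-1", "peripheral-sheet-2"):
        rng = np.random.default_rng(s_pick)
        exits = set(int(n) for n in net.exit_nodes)
        interior = [int(n) for n in net.node_ids if int(n) not in exits]
        if mech == "peripheral-sheet-1":
            nodes = interior
            share, alpha = 1.0 / 6.0, 1.0 / 2.5
        else:
            k = max(1, int(round(scfg.active_fraction * len(interior))))
            nodes = sorted(rng.choice(interior, size=k, replace=False))
            share, alpha = 1.0 / 2.0, 1.0 / 5.0
        vk = rng.normal(scfg.peripheral_volume_mean,
                        scfg.peripheral_volume_sd, size=len(nodes))
        vk = np.abs(vk)  # measured volumes are positive
        model = JunctionModel(f=1.0, alpha=alpha, beta=1.0,
                              volume_mean=scfg.peripheral_volume_mean,
                              volume_sd=scfg.peripheral_volume_sd,
                              volume_min=0.0, volume_max=np.inf)
        sched.junction_events = sample_junction_schedule(
            net, model, t_end, s_junc, active_nodes=nodes,
            volumes=share * vk)
    return sched


def run_scenario(net: TubularNetwork, scfg: ScenarioConfig,
                 tcfg: TransportConfig) -> TransportSummary:
    """Orchestrate schedule → hydraulics → transport → observables."""
    if scfg.mechanism == "perinuclear-sheet" and not len(net.sheet_nodes):
        raise ConfigError("perinuclear scenario requires sheet-role nodes")
    sched = build_schedule(net, scfg, tcfg.t_end, tcfg.seed)
    store = simulate_ensemble(net, sched if scfg.mechanism != "diffusion-only"
                              else None, tcfg)
    summary = summarise(store)
    summary.provenance = {
        "mechanism": scfg.mechanism, "alpha": scfg.alpha, "beta": scfg.beta,
        "f": scfg.f, "length_policy": scfg.length_policy,
        "seed": tcfg.seed, "t_end": tcfg.t_end,
        "n_particles": tcfg.n_particles,
    }
    return summary


def junction_sweep(net: TubularNetwork, alphas, betas, f: float,
                   seeds, tcfg: TransportConfig) -> pd.DataFrame:
    """Mean AETS surface over an (alpha, beta) grid of junction scenarios.

    Seeds are shared across grid cells (common random numbers) so that
    monotonicity in the forcing parameters is visible above Monte-Carlo noise.
    Returns a long-format frame (alpha, beta, seed, mean_speed, n_events).
    """
    rows = []
    for a in alphas:
        for b in betas:
            scfg = ScenarioConfig(mechanism="junction", alpha=a, beta=b, f=f)
            for s in np.atleast_1d(seeds):
                summary = run_scenario(net, scfg, replace(tcfg, seed=int(s)))
                rows.append((float(a), float(b), int(s), summary.mean_aets,
                             len(summary.traversals)))
    return pd.DataFrame(rows, columns=["alpha", "beta", "seed", "mean_speed",
                                       "n_events"])
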