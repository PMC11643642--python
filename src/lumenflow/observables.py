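"""Transport statistics: instantaneous speeds, edge traversal speeds,
distribution fits, flow summaries and spatial profiles.

Two speed measures mirror single-particle-tracking practice.  The
*instantaneous speed* is |X(t+Δt) − X(t)|/Δt of the global 2D position at the
recording cadence Δt = 18 ms.  An *edge traversal* happens when a particle
moves from node i to node j of an edge without touching either node in
between; its speed is the edge length divided by the time since the most
recent departure from the origin node.  The *average edge traversal speed*
(AETS) of an edge is the mean over its traversal events, and network-level
distributions pool these per-edge averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import TubularNetwork
from .particles import TrajectoryStore


@dataclass
class TransportSummary:
    """Bundle of the transport statistics of one run."""

    instantaneous_speeds: np.ndarray
    traversals: pd.DataFrame
    edge_mean_speeds: pd.Series       # per-edge average traversal speed
    mean_aets: float                  # mean over edges of per-edge means
    fit: dict | None = None
    flow: dict | None = None
    mixing: pd.DataFrame | None = None
    provenance: dict | None = None


def instantaneous_speeds(store: TrajectoryStore, dt: float = 0.018) -> np.ndarray:
    """Finite-difference speed magnitudes |ΔX|/Δt in the global frame, µm/s."""
    rec = np.diff(store.times)
    if len(rec) == 0:
        return np.empty(0)
    cadence = float(np.median(rec))
    stride = max(1, int(round(dt / cadence)))
    if abs(stride * cadence - dt) > 1e-9:
        raise ValueError("recording cadence does not divide the speed interval")
    x, y = store.positions_xy()
    dx = x[stride::stride] - x[:-stride:stride]
    dy = y[stride::stride] - y[:-stride:stride]
    return (np.hypot(dx, dy) / dt).ravel()


def edge_traversal_events(visits: pd.DataFrame,
                          net: TubularNetwork) -> pd.DataFrame:
    """Extract traversal events from a node-visit log.

    ``visits`` needs columns (particle, time, node), time-ordered per
    particle.  A traversal is a pair of consecutive visits to *different*
    nodes; its duration runs from the most recent departure from the origin
    (i.e. the previous visit) to the arrival.  Consecutive visits to the same
    node reset the departure clock and produce no event.
    """
    lengths = {}
    for (i, j), l in zip(net.edges, net.lengths):
        lengths[(int(i), int(j))] = float(l)
        lengths[(int(j), int(i))] = float(l)
    rows = []
    for particle, grp in visits.groupby("particle", sort=False):
        t = grp["time"].to_numpy()
        nd = grp["node"].to_numpy()
        for k in range(1, len(nd)):
            if nd[k] != nd[k - 1]:
                pair = (int(nd[k - 1]), int(nd[k]))
                if pair not in lengths:
                    raise ValueError(f"visited nodes {pair} are not an edge")
                dur = float(t[k] - t[k - 1])
                rows.append((particle, pair[0], pair[1], t[k], dur,
                             lengths[pair] / dur))
    return pd.DataFrame(rows, columns=["particle", "node_i", "node_j",
                                       "arrival_time", "duration", "speed"])


def average_edge_traversal_speeds(traversals: pd.DataFrame) -> pd.Series:
    """Per-edge mean of traversal speeds (one value per edge with events)."""
    return traversals.groupby("edge")["speed"].mean()


def fit_speed_distribution(samples, family: str = "log-normal") -> dict:
    """Maximum-likelihood fit of the pooled average edge traversal speeds.

    Returns the fitted parameters, the fitted mean and the raw sample mean;
    a near-zero spread is flagged as degenerate rather than fitted.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to fit a distribution")
    out = {"family": family, "sample_mean": float(samples.mean()),
           "n": int(len(samples)), "degenerate": False}
    if np.std(samples) < 1e-12 * max(abs(samples.mean()), 1e-300):
        out["degenerate"] = True
        out["fitted_mean"] = float(samples.mean())
        return out
    if family == "log-normal":
        if np.any(samples <= 0):
            raise ValueError("log-normal fit requires positive samples")
        shape, loc, scale = stats.lognorm.fit(samples, floc=0)
        out.update(sigma=float(shape), mu=float(np.log(scale)),
                   fitted_mean=float(stats.lognorm.mean(shape, loc, scale)))
    elif family == "normal":
        mu, sd = stats.norm.fit(samples)
        out.update(mu=float(mu), sigma=float(sd), fitted_mean=float(mu))
    else:
        raise ValueError(f"unknown family {family!r}")
    return out


def flow_statistics(flow_Q1: np.ndarray, flow_times: np.ndarray,
                    radius: float) -> dict:
    """Mean flow speed and direction-alternation frequency.

    Mean speed is the time-and-edge average of |Q|/(πR²) using the flux
    entering each edge; the alternation frequency counts sign changes of that
    flux per second, averaged over edges.
    """
    Q = np.asarray(flow_Q1, dtype=float)
    if Q.ndim != 2 or len(flow_times) != Q.shape[0]:
        raise ValueError("flow snapshots must be (n_times, n_edges)")
    speed = float(np.mean(np.abs(Q)) / (np.pi * radius ** 2))
    duration = float(flow_times[-1] - flow_times[0]) if len(flow_times) > 1 else 0.0
    if duration <= 0:
        return {"mean_flow_speed": speed, "alternation_frequency": 0.0}
    sign_changes = np.sum(Q[1:] * Q[:-1] < 0, axis=0)
    freq = float(np.mean(sign_changes) / duration)
    return {"mean_flow_speed": speed, "alternation_frequency": freq,
            "n_snapshots": int(Q.shape[0]), "n_edges": int(Q.shape[1])}


def spatial_speed_profile(edge_speeds: pd.Series, net: TubularNetwork,
                          n_bins: int = 10) -> pd.DataFrame:
    """V(x): per-edge speeds averaged along y, binned by edge-midpoint x.

    Empty bins are reported as NaN (missing), not zero.
    """
    ei = net.edge_indices
    mid_x = 0.5 * (net.pos[ei[:, 0], 0] + net.pos[ei[:, 1], 0])
    xmin, xmax = net.pos[:, 0].min(), net.pos[:, 0].max()
    bins = np.linspace(xmin - 1e-9, xmax + 1e-9, n_bins + 1)
    centres = 0.5 * (bins[:-1] + bins[1:])
    V = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    which = np.digitize(mid_x[edge_speeds.index], bins) - 1
    for k in range(n_bins):
        sel = which == k
        if sel.any():
            V[k] = float(edge_speeds.to_numpy()[sel].mean())
            counts[k] = int(sel.sum())
    return pd.DataFrame({"x": centres, "V": V, "n_edges": counts})


def summarise(store: TrajectoryStore, speed_dt: float = 0.018,
              fit_family: str | None = "log-normal") -> TransportSummary:
    """Full transport summary of one simulation run."""
    tr = store.traversals()
    per_edge = average_edge_traversal_speeds(tr) if len(tr) else \
        pd.Series(dtype=float)
    mean_aets = float(per_edge.mean()) if len(per_edge) else float("nan")
    fit = None
    if fit_family and len(per_edge) >= 10:
        fit = fit_speed_distribution(per_edge.to_numpy(), fit_family)
    flow = None
    if store.flow_Q1 is not None:
        flow = flow_statistics(store.flow_Q1, store.flow_times,
                               float(store.net.radii.mean()))
    return TransportSummary(
        instantaneous_speeds=instantaneous_speeds(store, speed_dt),
        traversals=tr, edge_mean_speeds=per_edge, mean_aets=mean_aets,
        fit=fit, flow=flow)
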