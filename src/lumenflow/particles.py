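"""Brownian particle transport through the flowing network.

Particles are rigid spheres (default diameter 5 nm) advected by the
instantaneous lubrication flow and diffusing with constant diffusivity D
(default 0.6 µm²/s, the measured intranode value).  The integration is an
explicit first-order Euler scheme, x_{n+1} = x_n + U Δt + X, with isotropic
Gaussian noise of variance 2DΔt per axis; walls reflect specularly.  At a
node a particle exits into tubule i with probability ∝ max(Pe_i + 1, 0),
Pe_i = U_i R / D with U_i the mean outflow speed — proportional to flow at
high Péclet, uniform at low Péclet.  Particles are independent (low volume
fraction), so the ensemble is advanced in one vectorised pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernel
from .contractions import ContractionSchedule
from .hydraulics import KirchhoffSolver, velocity_field
from .network import TubularNetwork


@dataclass
class TransportConfig:
    """Simulation parameters for particle transport.

    dt is the Brownian step (1e-5 s keeps the diffusive step ≈ R/9); flow_dt
    the quasi-steady flow refresh; record_dt the trajectory sampling cadence
    (18 ms, the tracking resolution the speed statistics assume).
    """

    D: float = 0.6                 # µm²/s
    dt: float = 1e-5               # s
    flow_dt: float = 1e-3          # s
    t_end: float = 10.0            # s
    n_particles: int = 300
    seed: int = 0
    record_dt: float = 0.018       # s
    particle_diameter: float = 0.005  # µm
    slip: float = 0.0              # µm
    store_flow: bool = True

    def validate(self, radius: float):
        if self.dt > self.flow_dt + 1e-15:
            raise ValueError("particle step dt must not exceed flow_dt")
        if math.sqrt(2.0 * self.D * self.dt) > radius / 3.0 + 1e-12:
            raise ValueError(
                "diffusive step exceeds R/3; decrease dt to resolve "
                "the tubule confinement")
        if self.t_end <= 0 or self.n_particles < 1:
            raise ValueError("t_end and n_particles must be positive")


@dataclass
class ParticleState:
    """Single-particle state for step-level tests and diagnostics."""

    edge_index: int
    z: float
    y1: float = 0.0
    y2: float = 0.0
    colour: str = "none"

    @property
    def r(self) -> float:
        return math.hypot(self.y1, self.y2)


@dataclass
class TrajectoryStore:
    """Recorded ensemble trajectories plus traversal events and flow snapshots."""

    net: TubularNetwork
    times: np.ndarray                  # (n_rec,)
    edge: np.ndarray                   # (n_rec, n) int32
    z: np.ndarray                      # (n_rec, n)
    y1: np.ndarray
    y2: np.ndarray
    colours: np.ndarray                # (n,) str
    traversal_edge: np.ndarray         # (n_ev,) int
    traversal_duration: np.ndarray     # (n_ev,) s
    traversal_time: np.ndarray         # (n_ev,) arrival time s
    flow_times: np.ndarray | None = None
    flow_Q1: np.ndarray | None = None  # (n_flow, E), µm³/s
    config: TransportConfig | None = None

    def positions_xy(self):
        """Global (x, y) positions, including the in-plane transverse offset."""
        ei = self.net.edge_indices
        p0 = self.net.pos[ei[:, 0]]
        p1 = self.net.pos[ei[:, 1]]
        vec = p1 - p0
        ln = self.net.lengths
        tang = vec / ln[:, None]
        normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        e = self.edge
        frac = self.z / ln[e]
        x = p0[e][..., 0] + frac * vec[e][..., 0] + self.y1 * normal[e][..., 0]
        y = p0[e][..., 1] + frac * vec[e][..., 1] + self.y1 * normal[e][..., 1]
        return x, y

    def traversals(self) -> pd.DataFrame:
        ln = self.net.lengths[self.traversal_edge] if len(self.traversal_edge) \
            else np.empty(0)
        return pd.DataFrame({
            "edge": self.traversal_edge,
            "arrival_time": self.traversal_time,
            "duration": self.traversal_duration,
            "speed": ln / np.maximum(self.traversal_duration, 1e-300),
        })


def node_transition_weights(U, R: float, D: float) -> np.ndarray:
    """Exit probabilities ∝ max(Pe + 1, 0), Pe = U R / D (uniform if all 0)."""
    U = np.asarray(U, dtype=float)
    w = np.maximum(U * R / D + 1.0, 0.0)
    total = w.sum()
    if total <= 0.0:
        return np.full(len(U), 1.0 / len(U))
    return w / total


def node_transition(U, R: float, D: float, rng) -> int:
    """Sample the outgoing-tubule index for a particle sitting at a node."""
    p = node_transition_weights(U, R, D)
    return int(rng.choice(len(p), p=p))


def step_particle(state: ParticleState, net: TubularNetwork, flow,
                  config: TransportConfig, rng) -> ParticleState:
    """Advance one particle by one Euler step (reference implementation).

    ``flow`` is ``(a, da_dt, da_dz, Q)`` at the particle position; walls
    reflect specularly.  This mirrors the compiled kernel and exists for
    step-level testing and experimentation.
    """
    a, da_dt, da_dz, Q = flow
    r = state.r
    u, v = velocity_field(a, da_dt, da_dz, Q, min(r, a), slip=config.slip)
    sig = math.sqrt(2.0 * config.D * config.dt)
    z = state.z + u * config.dt + sig * rng.standard_normal()
    y1, y2 = state.y1, state.y2
    if r > 1e-12:
        y1 += v * config.dt * y1 / r
        y2 += v * config.dt * y2 / r
    y1 += sig * rng.standard_normal()
    y2 += sig * rng.standard_normal()
    rp = 0.5 * config.particle_diameter
    rmax = a - rp
    rnew = math.hypot(y1, y2)
    if rmax <= 0:
        y1 = y2 = 0.0
    elif rnew > rmax:
        rr = rnew
        for _ in range(10):
            rr = abs(2.0 * rmax - rr)
            if rr <= rmax:
                break
        else:
            rr = 0.0
        y1 *= rr / rnew
        y2 *= rr / rnew
    return replace(state, z=z, y1=y1, y2=y2)


def _adjacency_csr(net: TubularNetwork):
    adj = net.adjacency()
    ei = net.edge_indices
    indptr = np.zeros(net.n_nodes + 1, dtype=np.int64)
    edges = []
    is_i = []
    for n in range(net.n_nodes):
        for e, _ in adj[n]:
            edges.append(e)
            is_i.append(1 if ei[e, 0] == n else 0)
        indptr[n + 1] = len(edges)
    return indptr, np.array(edges, dtype=np.int64), np.array(is_i, dtype=np.int64)


def _initial_positions(net: TubularNetwork, n: int, rng):
    w = net.lengths / net.lengths.sum()
    e = rng.choice(net.n_edges, size=n, p=w).astype(np.int64)
    z = rng.random(n) * net.lengths[e]
    return e, z


def simulate_ensemble(net: TubularNetwork, schedule: ContractionSchedule | None,
                      config: TransportConfig,
                      colours: np.ndarray | None = None) -> TrajectoryStore:
    """Simulate an ensemble of independent Brownian particles.

    ``schedule=None`` (or an empty schedule) gives the diffusion-only
    control: no flow solves, static tubule walls.  Deterministic for a fixed
    ``config.seed``.
    """
    R = float(net.radii.mean())
    config.validate(R)
    E = net.n_edges
    ei = net.edge_indices
    e_i = ei[:, 0].astype(np.int64)
    e_j = ei[:, 1].astype(np.int64)
    e_len = net.lengths.astype(float)
    e_R = net.radii.astype(float)
    indptr, adj_e, adj_isI = _adjacency_csr(net)

    ss = np.random.SeedSequence(config.seed)
    s_place, s_kernel = ss.spawn(2)
    rng = np.random.default_rng(s_place)
    _kernel.seed_rng(int(s_kernel.generate_state(1, np.uint32)[0]) % (2 ** 31))

    n = config.n_particles
    p_edge, p_z = _initial_positions(net, n, rng)
    p_y1 = np.zeros(n)
    p_y2 = np.zeros(n)
    p_origin = np.full(n, -1, dtype=np.int64)
    p_tdep = np.zeros(n)

    if colours is None:
        colours = np.array(["none"] * n)

    has_activity = schedule is not None and (
        len(schedule.pinch_sites) or len(schedule.junction_events)
        or schedule.sheet is not None)
    solver = KirchhoffSolver(net, slip=config.slip) if has_activity else None

    n_chunk_steps = int(round(config.flow_dt / config.dt))
    n_chunks = int(round(config.t_end / config.flow_dt))
    rec_every = max(1, int(round(config.record_dt / config.flow_dt)))
    n_rec = n_chunks // rec_every + 1

    rec_edge = np.empty((n_rec, n), dtype=np.int32)
    rec_z = np.empty((n_rec, n))
    rec_y1 = np.empty((n_rec, n))
    rec_y2 = np.empty((n_rec, n))
    rec_t = np.empty(n_rec)

    def record(k, t):
        rec_edge[k] = p_edge
        rec_z[k] = p_z
        rec_y1[k] = p_y1
        rec_y2[k] = p_y2
        rec_t[k] = t

    record(0, 0.0)
    k_rec = 1

    cap = max(64, 8 * n)
    ev_edge = np.empty(cap, dtype=np.int64)
    ev_dur = np.empty(cap)
    ev_t = np.empty(cap)
    all_ev = []

    store_flow = config.store_flow and has_activity
    flow_Q1 = np.empty((n_chunks, E), dtype=np.float32) if store_flow else None
    flow_t = np.empty(n_chunks) if store_flow else None

    zeros = np.zeros(E)
    b_static = e_R.copy()
    for c in range(n_chunks):
        t0 = c * config.flow_dt
        if has_activity:
            # window-averaged contraction states: each flow interval carries
            # exactly the volume expelled during it
            b, bdot, L, _ = schedule.pinch_state_arrays(t0, net,
                                                        dt=config.flow_dt)
            node_src = schedule.node_source_dict(t0, dt=config.flow_dt)
            sheet_total = schedule.sheet_total(t0, dt=config.flow_dt)
            sol = solver.solve(b=b, bdot=bdot, L=L, node_sources=node_src,
                               sheet_total=sheet_total)
            Q1, Q4 = sol.Q1, sol.Q4
            active = (L > 0.0).astype(np.uint8)
            if store_flow:
                flow_Q1[c] = Q1
                flow_t[c] = t0
        else:
            Q1 = Q4 = zeros
            b, bdot, L = b_static, zeros, zeros
            active = np.zeros(E, dtype=np.uint8)
        n_ev, overflow = _kernel.advance_chunk(
            n_chunk_steps, config.dt, t0, config.D,
            0.5 * config.particle_diameter, config.slip,
            e_i, e_j, e_len, e_R,
            np.ascontiguousarray(Q1, dtype=float),
            np.ascontiguousarray(Q4, dtype=float),
            np.ascontiguousarray(b, dtype=float),
            np.ascontiguousarray(bdot, dtype=float),
            np.ascontiguousarray(L, dtype=float),
            active, indptr, adj_e, adj_isI,
            p_edge, p_z, p_y1, p_y2, p_origin, p_tdep,
            ev_edge, ev_dur, ev_t, 0)
        if overflow:
            raise RuntimeError("traversal-event buffer overflow; the chunk "
                               "event rate exceeded the allocated capacity")
        if n_ev:
            all_ev.append((ev_edge[:n_ev].copy(), ev_dur[:n_ev].copy(),
                           ev_t[:n_ev].copy()))
        if (c + 1) % rec_every == 0 and k_rec < n_rec:
            record(k_rec, (c + 1) * config.flow_dt)
            k_rec += 1

    if all_ev:
        tr_edge = np.concatenate([a for a, _, _ in all_ev])
        tr_dur = np.concatenate([a for _, a, _ in all_ev])
        tr_t = np.concatenate([a for _, _, a in all_ev])
    else:
        tr_edge = np.empty(0, dtype=np.int64)
        tr_dur = np.empty(0)
        tr_t = np.empty(0)

    return TrajectoryStore(
        net=net, times=rec_t[:k_rec], edge=rec_edge[:k_rec],
        z=rec_z[:k_rec], y1=rec_y1[:k_rec], y2=rec_y2[:k_rec],
        colours=colours, traversal_edge=tr_edge, traversal_duration=tr_dur,
        traversal_time=tr_t, flow_times=flow_t, flow_Q1=flow_Q1,
        config=config)


def mixing_experiment(net: TubularNetwork, schedule: ContractionSchedule | None,
                      n_particles: int, n_strips: int = 20,
                      t_end: float = 3.0,
                      config: TransportConfig | None = None):
    """Two-colour homogenisation assay.

    Particles are seeded uniformly; those starting in the left half of the
    network (by x) are blue, the rest red.  At each recorded time the network
    is cut into ``n_strips`` equal-width vertical strips and the variance over
    strips of (n_blue − n_red) is the mixing measure — zero means perfect
    homogeneity.

    Returns (times, variance, store).
    """
    config = config or TransportConfig()
    config = replace(config, n_particles=n_particles, t_end=t_end)
    store = simulate_ensemble(net, schedule, config)
    x0, _ = store.positions_xy()
    median = np.median(x0[0])
    colours = np.where(x0[0] < median, "blue", "red")
    store.colours = colours
    times, var = mixing_variance(store, n_strips)
    return times, var, store


def mixing_variance(store: TrajectoryStore, n_strips: int = 20):
    """Var over strips of (n_blue − n_red) at each recorded time."""
    x, _ = store.positions_xy()
    xmin = store.net.pos[:, 0].min()
    xmax = store.net.pos[:, 0].max()
    edges = np.linspace(xmin - 1e-9, xmax + 1e-9, n_strips + 1)
    blue = store.colours == "blue"
    red = store.colours == "red"
    var = np.empty(len(store.times))
    for k in range(len(store.times)):
        nb, _ = np.histogram(x[k][blue], bins=edges)
        nr, _ = np.histogram(x[k][red], bins=edges)
        var[k] = np.var(nb - nr)
    return store.times, var
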