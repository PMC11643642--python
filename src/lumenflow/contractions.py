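"""Stochastic contraction kinematics: tubule pinches, junctions and sheets.

The kinematics are fully prescribed in time — active forces are assumed to
balance elastic and viscous resistance so that each contraction follows its
prescribed waveform.  A tubule pinch of half-length L centred at z0 narrows
the local radius linearly from R at the pinch edges to a minimum b(t) at the
centre, with b varying sinusoidally between R and b0 over a contraction +
relaxation of total duration 2T.  Junctions and sheet reservoirs are point
sources with sinusoidal flow-rate waveforms whose integral over a contraction
equals the expelled volume.

Units: lengths µm, times s, volumes µm³, flow rates µm³/s.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .network import TubularNetwork

LN10 = math.log(10.0)

#: rate of the exponential law for the pinch duration 2T (mean 0.0725 s)
PINCH_DURATION_RATE = LN10 / 0.167
#: rate of the exponential law for the wait between pinches (mean 0.370 s)
PINCH_WAIT_RATE = LN10 / 0.851
#: mean of the uniform law for the pinch length 2L, µm
PINCH_LENGTH_MEAN = 0.14
#: variance of the uniform law for 2L, µm² (sd ≈ 0.040 µm)
PINCH_LENGTH_VAR = 0.062 ** 2 / LN10
#: minimum pinch radius as a fraction of the tubule radius
B0_FRACTION = 0.01


@dataclass
class PinchParameterDistributions:
    """Stochastic laws for pinch events.

    ``alpha`` > 1 makes events faster (durations scaled by 1/alpha) and
    ``beta`` > 1 makes them more frequent (waits scaled by 1/beta).
    """

    duration_rate: float = PINCH_DURATION_RATE
    wait_rate: float = PINCH_WAIT_RATE
    length_mean: float = PINCH_LENGTH_MEAN
    length_var: float = PINCH_LENGTH_VAR
    alpha: float = 1.0
    beta: float = 1.0
    b0_fraction: float = B0_FRACTION

    def __post_init__(self):
        if self.duration_rate <= 0 or self.wait_rate <= 0:
            raise ValueError("rates must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.length_uniform_bounds()[0] <= 0:
            raise ValueError("uniform pinch-length support must be positive")

    def length_uniform_bounds(self) -> tuple:
        half = math.sqrt(3.0 * self.length_var)
        return (self.length_mean - half, self.length_mean + half)


@dataclass
class PinchSite:
    """One pinch site (edge midpoint) and its sampled event stream.

    ``events`` is an (n, 3) array of (start time, half-duration T, half-length
    L); each event occupies [start, start + 2T] and the pinch region is
    [z0 − L, z0 + L].  Events are non-overlapping and time-ordered.
    """

    edge_index: int
    edge_length: float
    z0: float
    b0: float
    radius: float
    events: np.ndarray

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float).reshape(-1, 3)
        self._starts = self.events[:, 0].tolist()

    def state_at(self, t: float) -> tuple:
        """(active, b, bdot, L) at time t."""
        k = bisect.bisect_right(self._starts, t) - 1
        if k < 0:
            return False, self.radius, 0.0, 0.0
        start, T, L = self.events[k]
        tau = t - start
        if tau >= 2.0 * T:
            return False, self.radius, 0.0, 0.0
        b, bdot = pinch_b(self.b0, self.radius, T, tau)
        return True, b, bdot, L

    def chunk_state(self, t0: float, t1: float) -> tuple:
        """(active, b, bdot, L) averaged over the quasi-steady window [t0, t1].

        Returns the midpoint radius b̄ = (b(t0) + b(t1))/2 and the effective
        rate ḃ = (b(t1) − b(t0))/(t1 − t0); with these the source formula
        reproduces exactly the volume expelled during the window, so events
        shorter than the flow-update interval cannot alias into spurious
        sustained flows (their net expelled volume is what drives the network).
        """
        # candidate event: the one containing t0, else the first starting in
        # (t0, t1)
        k = bisect.bisect_right(self._starts, t0) - 1
        ev = None
        if k >= 0:
            start, T, L = self.events[k]
            if t0 - start < 2.0 * T:
                ev = (start, T, L)
        if ev is None:
            k2 = bisect.bisect_right(self._starts, t0)
            if k2 < len(self.events) and self.events[k2][0] < t1:
                ev = tuple(self.events[k2])
        if ev is None:
            return False, self.radius, 0.0, 0.0
        start, T, L = ev

        def b_of(t):
            tau = t - start
            if tau <= 0.0 or tau >= 2.0 * T:
                return self.radius
            return pinch_b(self.b0, self.radius, T, tau)[0]

        b_a, b_b = b_of(t0), b_of(t1)
        bdot = (b_b - b_a) / (t1 - t0)
        return True, 0.5 * (b_a + b_b), bdot, L

    def radius_at(self, z: float, t: float) -> float:
        active, b, _, L = self.state_at(t)
        if not active:
            return self.radius
        return pinch_radius_profile(z, self.z0, L, b, self.radius)


def pinch_b(b0: float, R: float, T: float, tau: float) -> tuple:
    """Minimum pinch radius b and its rate ḃ at time tau ∈ [0, 2T] into an event.

    b(τ) = (R + b0)/2 + (R − b0) cos(πτ/T)/2 descends from R to b0 over [0, T]
    and returns to R over [T, 2T]; ḃ vanishes at both event boundaries so the
    volume source is continuous in time.
    """
    phase = math.pi * tau / T
    b = 0.5 * (R + b0) + 0.5 * (R - b0) * math.cos(phase)
    bdot = -0.5 * math.pi * (R - b0) * math.sin(phase) / T
    return b, bdot


def pinch_radius_profile(z: float, z0: float, L: float, b: float, R: float) -> float:
    """Piecewise-linear pinch radius a(z) = b + (R − b)|z − z0|/L (R outside)."""
    if L <= 0 or abs(z - z0) >= L:
        return R
    return b + (R - b) * abs(z - z0) / L


def pinch_radius(site: PinchSite, z: float, t: float, R: float | None = None) -> float:
    """Instantaneous radius a(z, t) at a pinch site (R outside events/region)."""
    if R is not None and R != site.radius:
        site = PinchSite(site.edge_index, site.edge_length, site.z0, site.b0,
                         R, site.events)
    return site.radius_at(z, t)


def pinch_source(b: float, bdot: float, L: float, R: float) -> float:
    """Instantaneous volume source q = −(2π/3) ḃ L (R + 2b) of a pinch, µm³/s.

    Positive while contracting (ḃ < 0): fluid is expelled into the network.
    The integral over a full contraction + relaxation vanishes.
    """
    return -(2.0 * math.pi / 3.0) * bdot * L * (R + 2.0 * b)


def pinch_source_at(site: PinchSite, t: float) -> float:
    active, b, bdot, L = site.state_at(t)
    if not active:
        return 0.0
    return pinch_source(b, bdot, L, site.radius)


def junction_source(delta_v: float, T: float, tau: float, f: float = 1.0) -> float:
    """Sinusoidal junction source q = f·ΔV·(π/2T)·sin(πτ/T), µm³/s.

    Over the contraction half [0, T] the integral is f·ΔV; over [T, 2T] the
    sign flips (the junction refills), so the net volume per event is zero.
    Outside [0, 2T] the source is zero.
    """
    if tau < 0.0 or tau > 2.0 * T:
        return 0.0
    return f * delta_v * (math.pi / (2.0 * T)) * math.sin(math.pi * tau / T)


def sheet_source(v_sheet: float, T: float, tau: float) -> float:
    """Total sheet-reservoir source S(t) = Vsheet·π·sin(πτ/T)/(2T), µm³/s."""
    return junction_source(v_sheet, T, tau)


def _window_averaged_sin_source(delta_v: float, T: float, tau0: float,
                                tau1: float, dt: float) -> float:
    """Mean of the sinusoidal source over [tau0, tau1]: the expelled volume
    ΔV·[cos(πτ0/T) − cos(πτ1/T)]/2 divided by the window length."""
    a = min(max(tau0, 0.0), 2.0 * T)
    b = min(max(tau1, 0.0), 2.0 * T)
    if b <= a:
        return 0.0
    vol = 0.5 * delta_v * (math.cos(math.pi * a / T)
                           - math.cos(math.pi * b / T))
    return vol / dt


def sample_junction_volumes(n: int, seed, mean: float = 0.0045,
                            sd: float = 0.0021, lo: float = 0.0020,
                            hi: float = 0.0081) -> np.ndarray:
    """Junction volumes ΔV from a normal law truncated by rejection, µm³."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    k = 0
    while k < n:
        draw = rng.normal(mean, sd, size=2 * (n - k) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - k)
        out[k:k + take] = draw[:take]
        k += take
    return out


def _sample_renewal_events(rng, t_end, duration_rate, wait_rate,
                           sample_extra) -> list:
    """Alternating wait/event renewal stream over [0, t_end].

    Each site starts inside a wait whose remaining duration is a full
    exponential draw (memoryless ⇒ stationary start).  ``sample_extra(rng)``
    supplies per-event payload appended after (start, T_half).
    """
    events = []
    t = rng.exponential(1.0 / wait_rate)
    while t < t_end:
        full = rng.exponential(1.0 / duration_rate)  # total duration 2T
        events.append((t, 0.5 * full, *sample_extra(rng)))
        t += full
        t += rng.exponential(1.0 / wait_rate)
    return events


def sample_pinch_schedule(net: TubularNetwork,
                          dists: PinchParameterDistributions | None = None,
                          t_end: float = 10.0, seed=0,
                          length_policy: str = "sampled") -> list:
    """One pinch site per edge, each an independent renewal stream.

    ``length_policy`` is ``"sampled"`` (uniform law, clamped to the edge
    length) or ``"full-tubule"`` (2L equals the whole edge length).
    Reproducible for a fixed seed.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    dists = dists or PinchParameterDistributions()
    if length_policy not in ("sampled", "full-tubule"):
        raise ValueError(f"unknown length policy {length_policy!r}")
    rng = np.random.default_rng(seed)
    lo, hi = dists.length_uniform_bounds()
    sites = []
    for e in range(net.n_edges):
        l = float(net.lengths[e])
        R = float(net.radii[e])

        if length_policy == "full-tubule":
            def extra(r, _l=l):
                return (0.5 * _l,)
        else:
            def extra(r, _l=l):
                two_l = min(r.uniform(lo, hi), _l)
                return (0.5 * two_l,)

        events = _sample_renewal_events(
            rng, t_end,
            duration_rate=dists.duration_rate * dists.alpha,
            wait_rate=dists.wait_rate * dists.beta,
            sample_extra=extra,
        )
        sites.append(PinchSite(
            edge_index=e, edge_length=l, z0=0.5 * l,
            b0=dists.b0_fraction * R, radius=R,
            events=np.array(events, dtype=float).reshape(-1, 3),
        ))
    return sites


@dataclass
class JunctionModel:
    """Contracting tubular junctions: per-junction expelled volume ΔV drawn
    once from the truncated normal law; each contraction expels f·ΔV and each
    relaxation takes the same volume back in."""

    f: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    volume_mean: float = 0.0045
    volume_sd: float = 0.0021
    volume_min: float = 0.0020
    volume_max: float = 0.0081

    def __post_init__(self):
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("volume fraction f must be in [0, 1]")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


def sample_junction_schedule(net: TubularNetwork, model: JunctionModel,
                             t_end: float, seed,
                             active_nodes=None,
                             volumes: np.ndarray | None = None) -> dict:
    """Per-node renewal streams of junction contractions.

    Returns {node id: (n, 3) array of (start, T_half, ΔV_effective)}.  The
    duration/wait laws are the tubule-pinch exponentials scaled by 1/alpha and
    1/beta.  ``volumes`` overrides the per-junction ΔV (pre-scaling by f).
    """
    rng = np.random.default_rng(seed)
    nodes = list(active_nodes) if active_nodes is not None else \
        [int(n) for n in net.node_ids]
    if volumes is None:
        volumes = sample_junction_volumes(
            len(nodes), rng, model.volume_mean, model.volume_sd,
            model.volume_min, model.volume_max)
    schedule = {}
    for node, dv in zip(nodes, np.asarray(volumes, dtype=float)):
        events = _sample_renewal_events(
            rng, t_end,
            duration_rate=PINCH_DURATION_RATE * model.alpha,
            wait_rate=PINCH_WAIT_RATE * model.beta,
            sample_extra=lambda r, _dv=dv: (model.f * _dv,),
        )
        schedule[int(node)] = np.array(events, dtype=float).reshape(-1, 3)
    return schedule


@dataclass
class PerinuclearSheet:
    """A perinuclear sheet reservoir connected to the network at designated
    sheet nodes, undergoing one contraction + relaxation of duration 2T and
    expelling Vsheet during the contraction half."""

    node_ids: list
    v_sheet: float = 10.0
    T: float = 2.5
    start: float = 0.0

    def total_source(self, t: float) -> float:
        return sheet_source(self.v_sheet, self.T, t - self.start)


@dataclass
class ContractionSchedule:
    """All contraction activity of one run."""

    t_end: float
    pinch_sites: list = field(default_factory=list)
    junction_events: dict = field(default_factory=dict)
    sheet: PerinuclearSheet | None = None

    def pinch_state_arrays(self, t: float, net: TubularNetwork,
                           dt: float | None = None):
        """Per-edge (b, bdot, L_half, q) arrays at time t.

        With ``dt`` set, states are averaged over the quasi-steady window
        [t, t + dt] so that each window injects exactly the volume the pinch
        expels during it (see :meth:`PinchSite.chunk_state`); otherwise the
        instantaneous state is returned.  Edges without an active event carry
        b = R, ḃ = 0, L = 0, q = 0.
        """
        E = net.n_edges
        b = net.radii.astype(float).copy()
        bdot = np.zeros(E)
        L = np.zeros(E)
        q = np.zeros(E)
        for site in self.pinch_sites:
            if dt is None:
                active, bb, bd, ll = site.state_at(t)
            else:
                active, bb, bd, ll = site.chunk_state(t, t + dt)
            if active:
                e = site.edge_index
                b[e], bdot[e], L[e] = bb, bd, ll
                q[e] = pinch_source(bb, bd, ll, site.radius)
        return b, bdot, L, q

    def node_source_dict(self, t: float, dt: float | None = None) -> dict:
        """{node id: q} of junction sources at time t (window-averaged if
        ``dt`` is given, with the same volume-exact convention as pinches)."""
        out = {}
        for node, events in self.junction_events.items():
            k = np.searchsorted(events[:, 0], t, side="right") - 1
            if dt is not None and (k < 0 or t - events[k, 0] >= 2 * events[k, 1]):
                k2 = k + 1  # event starting inside the window, if any
                if k2 < len(events) and events[k2, 0] < t + dt:
                    k = k2
            if k < 0:
                continue
            start, T, dv = events[k]
            if dt is None:
                tau = t - start
                if 0.0 <= tau <= 2.0 * T:
                    s = junction_source(dv, T, tau)
                    if s != 0.0:
                        out[int(node)] = s
            else:
                s = _window_averaged_sin_source(dv, T, t - start,
                                                t + dt - start, dt)
                if s != 0.0:
                    out[int(node)] = s
        return out

    def sheet_total(self, t: float, dt: float | None = None) -> float:
        if self.sheet is None:
            return 0.0
        if dt is None:
            return self.sheet.total_source(t)
        sh = self.sheet
        return _window_averaged_sin_source(sh.v_sheet, sh.T, t - sh.start,
                                           t + dt - sh.start, dt)

    # -- serialisation (exact replay) -------------------------------------
    def to_json(self) -> str:
        d = {
            "t_end": self.t_end,
            "pinch_sites": [
                {"edge_index": s.edge_index, "edge_length": s.edge_length,
                 "z0": s.z0, "b0": s.b0, "radius": s.radius,
                 "events": s.events.tolist()}
                for s in self.pinch_sites
            ],
            "junction_events": {str(k): v.tolist()
                                for k, v in self.junction_events.items()},
            "sheet": None if self.sheet is None else {
                "node_ids": [int(n) for n in self.sheet.node_ids],
                "v_sheet": self.sheet.v_sheet, "T": self.sheet.T,
                "start": self.sheet.start},
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ContractionSchedule":
        d = json.loads(text)
        sites = [PinchSite(s["edge_index"], s["edge_length"], s["z0"],
                           s["b0"], s["radius"], np.array(s["events"]))
                 for s in d["pinch_sites"]]
        junc = {int(k): np.array(v).reshape(-1, 3)
                for k, v in d["junction_events"].items()}
        sheet = None
        if d.get("sheet"):
            sd = d["sheet"]
            sheet = PerinuclearSheet(sd["node_ids"], sd["v_sheet"], sd["T"],
                                     sd["start"])
        return cls(d["t_end"], sites, junc, sheet)
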