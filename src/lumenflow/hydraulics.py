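"""Quasi-steady Kirchhoff hydraulics of a pinching tubular network.

At the nanometre scales of ER tubules the Reynolds number is ~1e-7, so the
flow is Stokesian and at each instant the network fluxes solve a linear
system: mass conservation at every node (K1), zero pressure change around
every independent cycle (K2), and common-pressure conditions tying all exit
nodes (and, separately, all sheet nodes) to their reservoirs.  Each edge
carries a midpoint pinch site represented as a *dummy node* splitting the
tubule into two lubrication-theory resistors r1, r2 with the pinch volume
source attached to the dummy node.

Resistances are viscosity-scaled (pressure/µ per unit flux): the fluid
viscosity cancels from K2 and the pressure boundary conditions, so fluxes are
independent of µ.  Units: µm, s, µm³/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .network import TubularNetwork, _generic_cycle_basis, tree_path

__all__ = [
    "EdgeResistancePair", "FlowSolution", "SolverError",
    "hagen_poiseuille_resistance", "pinch_segment_resistances",
    "flux_profile", "velocity_field", "KirchhoffSolver", "assemble_and_solve",
]


class SolverError(RuntimeError):
    """The hydraulic system cannot be assembled or solved."""


@dataclass
class EdgeResistancePair:
    """Hydraulic resistances of the two tubule segments flanking a pinch."""

    r1: float
    r2: float

    @property
    def total(self) -> float:
        return self.r1 + self.r2


def _slip_integral(b: float, R: float, lam: float) -> float:
    """I = ∫_b^R da / (a³ (a + 4λ)), the lubrication kernel of a linear pinch
    with wall slip length λ.  Exact partial fractions; series for small λ to
    avoid catastrophic cancellation."""
    if lam == 0.0:
        return (1.0 / b ** 3 - 1.0 / R ** 3) / 3.0
    k = 4.0 * lam
    if k < 0.5 * b:
        # sum_{n>=3} (-1)^(n+1) k^(n-3) / n * (b^-n - R^-n), scaled by k^0:
        # I = sum_{n>=3} (-k)^(n-3) * (n-3 terms) ... derived from
        # 1/(a^3 (a+k)) = sum_{m>=0} (-k)^m / a^(4+m)
        total = 0.0
        term_sign = 1.0
        km = 1.0
        for m in range(0, 60):
            n = m + 4
            inc = term_sign * km * (b ** (-(n - 1)) - R ** (-(n - 1))) / (n - 1)
            total += inc
            if abs(inc) < 1e-18 * abs(total):
                break
            term_sign = -term_sign
            km *= k
        return total
    # exact: (1/k³) ln((1+k/b)/(1+k/R)) + (1/k²)(1/R − 1/b) − (1/2k)(1/R² − 1/b²)
    return (math.log1p(k / b) - math.log1p(k / R)) / k ** 3 \
        + (1.0 / R - 1.0 / b) / k ** 2 \
        - (1.0 / R ** 2 - 1.0 / b ** 2) / (2.0 * k)


def _pinch_term(L: float, b: float, R: float, lam: float) -> float:
    """(1/(R−b)) L ∫_b^R da/(a³(a+4λ)) with a stable b→R limit."""
    if L == 0.0:
        return 0.0
    if R - b < 1e-6 * R:
        m = 0.5 * (R + b)
        return L / (m ** 3 * (m + 4.0 * lam))
    return L * _slip_integral(b, R, lam) / (R - b)


def hagen_poiseuille_resistance(l: float, R: float, mu: float = 1.0,
                                slip: float = 0.0) -> float:
    """Resistance 8µl / (πR⁴(1 + 4λ/R)) of a uniform tubule (λ = 0: no slip)."""
    return 8.0 * mu * l / (math.pi * R ** 4 * (1.0 + 4.0 * slip / R))


def pinch_segment_resistances(L1: float, L2: float, L: float, R: float,
                              b: float, slip: float = 0.0,
                              mu: float = 1.0) -> EdgeResistancePair:
    """Resistances of the two segments of a tubule pinched at z0 (L1 + 2L + L2
    long in total): each segment is a straight piece plus half the linear
    pinch profile.  With b = R and λ = 0 the pair sums to the plain
    Hagen–Poiseuille resistance of the whole tubule.
    """
    if b <= 0:
        raise ValueError("minimum pinch radius b must be positive (use b0 > 0)")
    if b > R:
        raise ValueError("pinch radius b cannot exceed the tubule radius R")
    if slip < 0:
        raise ValueError("slip length must be non-negative")
    c = 8.0 * mu / math.pi
    straight = 1.0 / (R ** 4 * (1.0 + 4.0 * slip / R))
    pinch = _pinch_term(L, b, R, slip)
    return EdgeResistancePair(c * (L1 * straight + pinch),
                              c * (L2 * straight + pinch))


def _segment_resistances_noslip(lengths, L, b, R):
    """Vectorised no-slip (r1, r2) over all edges (midpoint pinch sites).

    Uses the algebraically exact pinch term L(R² + Rb + b²)/(3 b³ R³), which
    has no singularity at b → R; inactive edges (L = 0) reduce to half the
    plain Hagen–Poiseuille resistance each.
    """
    L1 = 0.5 * (lengths - 2.0 * L)
    c = 8.0 / math.pi
    pinch = L * (R ** 2 + R * b + b ** 2) / (3.0 * b ** 3 * R ** 3)
    r = c * (L1 / R ** 4 + pinch)
    return r, r.copy()


def flux_profile(z, Q1: float, b: float, bdot: float, L: float, R: float,
                 L1: float):
    """Cross-section flux Q(z, t) along a tubule with one active pinch.

    Mass conservation gives Q(z) = Q1 − 2π ∫₀ᶻ a ∂a/∂t dz̃; with the linear
    pinch profile the integral is polynomial in the scaled coordinate.  Q is
    constant (Q1) before the pinch, varies across it, and is constant
    Q4 = Q1 − 2πḃL(R/3 + 2b/3) after it.
    """
    z = np.asarray(z, dtype=float)
    z0 = L1 + L
    out = np.full(z.shape, Q1, dtype=float)
    if L > 0.0 and bdot != 0.0:
        # scaled distance from the pinch centre, clipped to the pinch region;
        # F covers the approach (w: 1 -> 0), H the exit (w: 0 -> 1), and
        # F(1) = 0, so points before the pinch automatically get zero.
        w = np.clip(np.abs(z - z0) / L, 0.0, 1.0)
        F = b * (1.0 - w) ** 2 / 2.0 + (R - b) * (1.0 / 6.0 - w ** 2 / 2.0
                                                  + w ** 3 / 3.0)
        F0 = b / 2.0 + (R - b) / 6.0
        H = b * (w - w ** 2 / 2.0) + (R - b) * (w ** 2 / 2.0 - w ** 3 / 3.0)
        integral = np.where(z < z0, F, F0 + H)
        out = Q1 - 2.0 * math.pi * bdot * L * integral
    return out if out.shape else float(out)


def velocity_field(a: float, da_dt: float, da_dz: float, Q: float, r,
                   slip: float = 0.0):
    """Axial and radial lubrication velocities (u, v) at radius r in a tubule
    of local radius a, µm/s.

    The axial profile is Poiseuille-like with slip length λ:
    u = 2Q(1 − (r/a)² + 2λ/a) / (πa²(1 + 4λ/a)); the radial component follows
    from incompressibility and satisfies the kinematic wall condition
    v − a_z u = a_t at r = a.  With λ = 0 the classical no-slip forms are
    recovered.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r > a) or np.any(r < 0):
        raise ValueError("radial position must satisfy 0 <= r <= a")
    ell = slip / a
    denom = 1.0 + 4.0 * ell
    s = r / a
    u = 2.0 * Q * (1.0 - s * s + 2.0 * ell) / (math.pi * a * a * denom)
    # radial velocity: wall-motion part + taper part (from 1/r d(rv)/dr = -du/dz)
    v1 = da_dt * s * (2.0 - s * s + 4.0 * ell) / denom
    k = 4.0 * slip
    A = a * a + k * a
    # v2 = -(a_z / r) * 2Q/π * ∫0^r r' ∂u/∂a dr', with the r factored out
    p1 = -(2.0 * a + k) / (A * A) * (r / 2.0 - r ** 3 / (4.0 * a * a)
                                     + slip * r / a)
    p2 = (r ** 3 / (2.0 * a ** 3) - slip * r / (a * a)) / A
    v2 = -da_dz * 2.0 * Q / math.pi * (p1 + p2)
    v = v1 + v2
    if np.ndim(r) == 0:
        return float(u), float(v)
    return u, v


@dataclass
class FlowSolution:
    """Instantaneous network flow: per-edge segment fluxes and node sources.

    ``Q1[e]`` is the flux entering edge e at its i-end (sign: positive i→j);
    ``Q4[e]`` the flux leaving at the j-end; they differ by the pinch source.
    ``node_sources`` covers the original nodes (junction sources, solved exit
    and sheet sources); ``pinch_sources`` the per-edge dummy-node sources.
    """

    Q1: np.ndarray
    Q4: np.ndarray
    node_sources: np.ndarray
    pinch_sources: np.ndarray
    exit_pressure: float = 0.0
    max_residual: float = 0.0

    def mean_speed(self, radii) -> float:
        """Mean over edges of |Q1| / (πR²), µm/s."""
        return float(np.mean(np.abs(self.Q1) / (math.pi * np.asarray(radii) ** 2)))


class KirchhoffSolver:
    """Pre-assembled sparse solver for the instantaneous network fluxes.

    Every edge is split at its midpoint pinch site into two resistor segments
    joined at a dummy node; the sparsity structure is static and only the
    resistance values and sources change between solves.  Unknowns are the 2E
    segment fluxes, the M1 exit-node sources and (when sheet nodes exist) the
    M2 sheet-node sources.
    """

    def __init__(self, net: TubularNetwork, slip: float = 0.0, mu: float = 1.0):
        self.net = net
        self.slip = float(slip)
        self.mu = float(mu)
        N, E = net.n_nodes, net.n_edges
        self.exit_idx = np.array(
            [i for i, r in enumerate(net.roles) if r == "exit"], dtype=int)
        self.sheet_idx = np.array(
            [i for i, r in enumerate(net.roles) if r == "sheet"], dtype=int)
        if len(self.exit_idx) == 0:
            raise SolverError("the network has no exit nodes: the hydraulic "
                              "system needs at least one reservoir connection")
        if len(set(self.exit_idx) & set(self.sheet_idx)):
            raise SolverError("sheet nodes must be disjoint from exit nodes")

        ei = net.edge_indices
        # augmented graph: dummy node N + e on edge e; segments (i, N+e), (N+e, j)
        seg = np.empty((2 * E, 2), dtype=int)
        seg[0::2, 0] = ei[:, 0]
        seg[0::2, 1] = N + np.arange(E)
        seg[1::2, 0] = N + np.arange(E)
        seg[1::2, 1] = ei[:, 1]
        self.segments = seg
        n_aug = N + E
        tree, _, cycle_edges, parent, parent_edge, depth = \
            _generic_cycle_basis(n_aug, seg, start=0)
        self._parent, self._depth = parent, depth
        seg_lookup = {}
        for s, (a, b) in enumerate(seg):
            seg_lookup[(int(a), int(b))] = (s, 1.0)
            seg_lookup[(int(b), int(a))] = (s, -1.0)

        M1, M2 = len(self.exit_idx), len(self.sheet_idx)
        self.n_unknowns = 2 * E + M1 + M2
        col_exit = {int(v): 2 * E + k for k, v in enumerate(self.exit_idx)}
        col_sheet = {int(v): 2 * E + M1 + k for k, v in enumerate(self.sheet_idx)}

        # K1 rows (static coefficients): sum of fluxes out of each node = q
        rows, cols, data = [], [], []
        for s, (a, b) in enumerate(seg):
            rows += [int(a), int(b)]
            cols += [s, s]
            data += [1.0, -1.0]          # Q leaves a, enters b
        for v, c in col_exit.items():
            rows.append(v)
            cols.append(c)
            data.append(-1.0)            # ... - q_exit = rhs
        for v, c in col_sheet.items():
            rows.append(v)
            cols.append(c)
            data.append(-1.0)
        self._static = (np.array(rows), np.array(cols), np.array(data))
        row0 = n_aug

        # resistance-bearing rows: K2 cycles, exit paths, sheet paths
        r_rows, r_cols, r_sign = [], [], []
        rr = row0
        for seq in cycle_edges:
            for s, sgn in seq:
                r_rows.append(rr)
                r_cols.append(s)
                r_sign.append(float(sgn))
            rr += 1
        # equal pressure at exits: path from exit_0 to exit_j through the tree
        ref = int(self.exit_idx[0])
        for v in self.exit_idx[1:]:
            path = tree_path(parent, depth, ref, int(v))
            for x, y in zip(path[:-1], path[1:]):
                s, sgn = seg_lookup[(x, y)]
                r_rows.append(rr)
                r_cols.append(s)
                r_sign.append(sgn)
            rr += 1
        # equal pressure at sheet nodes
        if M2 > 0:
            sref = int(self.sheet_idx[0])
            for v in self.sheet_idx[1:]:
                path = tree_path(parent, depth, sref, int(v))
                for x, y in zip(path[:-1], path[1:]):
                    s, sgn = seg_lookup[(x, y)]
                    r_rows.append(rr)
                    r_cols.append(s)
                    r_sign.append(sgn)
                rr += 1
        self._res_rows = (np.array(r_rows, dtype=int),
                          np.array(r_cols, dtype=int),
                          np.array(r_sign))
        self._sheet_sum_row = rr if M2 > 0 else None
        n_rows = rr + (1 if M2 > 0 else 0)
        if n_rows != self.n_unknowns:
            raise SolverError(
                f"system is not square ({n_rows} equations, "
                f"{self.n_unknowns} unknowns); the network may be degenerate")
        self._n_aug = n_aug

    # ------------------------------------------------------------------
    def _segment_resistance_values(self, b, L):
        net = self.net
        if self.slip == 0.0:
            r1, r2 = _segment_resistances_noslip(net.lengths, L, b, net.radii)
            r1 *= self.mu
            r2 *= self.mu
        else:
            r1 = np.empty(net.n_edges)
            r2 = np.empty(net.n_edges)
            for e in range(net.n_edges):
                L1 = 0.5 * (net.lengths[e] - 2.0 * L[e])
                pair = pinch_segment_resistances(
                    L1, L1, L[e], net.radii[e], b[e], self.slip, self.mu)
                r1[e], r2[e] = pair.r1, pair.r2
        r_seg = np.empty(2 * net.n_edges)
        r_seg[0::2] = r1
        r_seg[1::2] = r2
        return r_seg

    def solve(self, b=None, bdot=None, L=None, node_sources=None,
              sheet_total: float = 0.0) -> FlowSolution:
        """Solve for the instantaneous fluxes.

        b, bdot, L: per-edge pinch state (default: no pinches anywhere).
        node_sources: {node id: q} for junction contractions.
        sheet_total: prescribed total sheet-reservoir source (requires sheet
        nodes).
        """
        net = self.net
        E, N = net.n_edges, net.n_nodes
        b = net.radii.astype(float) if b is None else np.asarray(b, dtype=float)
        bdot = np.zeros(E) if bdot is None else np.asarray(bdot, dtype=float)
        L = np.zeros(E) if L is None else np.asarray(L, dtype=float)
        if sheet_total != 0.0 and len(self.sheet_idx) == 0:
            raise SolverError("sheet source prescribed but no sheet nodes")

        q_pinch = -(2.0 * math.pi / 3.0) * bdot * L * (net.radii + 2.0 * b)
        rhs = np.zeros(self.n_unknowns)
        rhs[N:N + E] = q_pinch  # dummy-node K1 rows carry the pinch sources
        if node_sources:
            for nid, q in node_sources.items():
                rhs[net.node_index(nid)] = q
        if self._sheet_sum_row is not None:
            rhs[self._sheet_sum_row] = sheet_total

        r_seg = self._segment_resistance_values(b, L)
        # normalise the pressure rows by a typical resistance so the matrix
        # mixes O(1) conservation rows with O(1) pressure rows
        r_scale = float(np.median(r_seg))
        rr, rc, rs = self._res_rows
        res_data = rs * (r_seg[rc] / r_scale)
        if self._sheet_sum_row is None:
            rows = np.concatenate([self._static[0], rr])
            cols = np.concatenate([self._static[1], rc])
            data = np.concatenate([self._static[2], res_data])
        else:
            M2 = len(self.sheet_idx)
            sheet_cols = 2 * E + len(self.exit_idx) + np.arange(M2)
            rows = np.concatenate([self._static[0], rr,
                                   np.full(M2, self._sheet_sum_row)])
            cols = np.concatenate([self._static[1], rc, sheet_cols])
            data = np.concatenate([self._static[2], res_data, np.ones(M2)])
        A = sp.csc_matrix((data, (rows.astype(int), cols.astype(int))),
                          shape=(self.n_unknowns, self.n_unknowns))
        try:
            x = splu(A).solve(rhs)
        except RuntimeError as exc:  # singular factorisation
            raise SolverError(f"hydraulic system is singular: {exc}") from exc
        # mass-conservation residual (K1 rows) is the physically meaningful one
        residual = A @ x - rhs
        k1_res = float(np.abs(residual[:self._n_aug]).max())
        scale = max(np.abs(x).max(), 1e-300)
        if not np.isfinite(x).all() or k1_res > 1e-9 * scale:
            # ill-conditioned: fall back to least squares on the dense system
            x, *_ = np.linalg.lstsq(A.toarray(), rhs, rcond=None)
            k1_res = float(np.abs((A @ x - rhs)[:self._n_aug]).max())
        max_res = k1_res

        Q1 = x[0:2 * E:2]
        Q4 = x[1:2 * E:2]
        node_q = np.zeros(N)
        if node_sources:
            for nid, q in node_sources.items():
                node_q[net.node_index(nid)] = q
        M1 = len(self.exit_idx)
        node_q[self.exit_idx] = x[2 * E:2 * E + M1]
        if len(self.sheet_idx):
            node_q[self.sheet_idx] = x[2 * E + M1:]
        return FlowSolution(Q1=Q1, Q4=Q4, node_sources=node_q,
                            pinch_sources=q_pinch, max_residual=max_res)


def assemble_and_solve(net: TubularNetwork, pinch_state=None,
                       node_sources=None, sheet_total: float = 0.0,
                       slip: float = 0.0, mu: float = 1.0) -> FlowSolution:
    """One-shot Kirchhoff solve (see :class:`KirchhoffSolver`).

    ``pinch_state`` is an optional (b, bdot, L) triple of per-edge arrays.
    """
    solver = KirchhoffSolver(net, slip=slip, mu=mu)
    if pinch_state is None:
        return solver.solve(node_sources=node_sources, sheet_total=sheet_total)
    b, bdot, L = pinch_state
    return solver.solve(b=b, bdot=bdot, L=L, node_sources=node_sources,
                        sheet_total=sheet_total)
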