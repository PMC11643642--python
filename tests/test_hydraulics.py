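import math

import numpy as np
import pytest
from scipy.integrate import quad

from lumenflow.contractions import pinch_b
from lumenflow.hydraulics import (KirchhoffSolver, SolverError,
                                  assemble_and_solve, flux_profile,
                                  hagen_poiseuille_resistance,
                                  pinch_segment_resistances, velocity_field)
from lumenflow.network import (TubularNetwork, build_honeycomb,
                               generate_er_like_network)

R = 0.03
B0 = 0.01 * R
MU = 1.0


def quad_resistance(L1, L, R_, b, lam=0.0):
    """Independent oracle: (8µ/π)∫dz/(a⁴(1+4λ/a)) over straight + half pinch."""
    def a_of(z):
        if z <= L1:
            return R_
        return R_ - (R_ - b) * (z - L1) / L
    val, _ = quad(lambda z: 1.0 / (a_of(z) ** 4 * (1 + 4 * lam / a_of(z))),
                  0, L1 + L, points=[L1], limit=400)
    return 8 * MU / math.pi * val


class TestResistances:
    def test_hagen_poiseuille_recovered_at_b_equals_R(self):
        pair = pinch_segment_resistances(0.43, 0.43, 0.07, R, R)
        assert pair.total == pytest.approx(
            hagen_poiseuille_resistance(1.0, R), rel=1e-12)

    def test_slip_zero_limit(self):
        for b in (0.5 * R, 0.01 * R):
            base = pinch_segment_resistances(0.43, 0.43, 0.07, R, b)
            lim = pinch_segment_resistances(0.43, 0.43, 0.07, R, b,
                                            slip=1e-15)
            assert lim.r1 == pytest.approx(base.r1, rel=1e-9)
            assert lim.r2 == pytest.approx(base.r2, rel=1e-9)

    @pytest.mark.parametrize("b,lam", [
        (0.0003, 0.0), (0.015, 0.0), (0.0299999, 0.0),
        (0.0003, 0.003), (0.015, 0.03), (0.0003, 0.3),
        (0.01, 1e-7), (0.01, 1e-4),
    ])
    def test_matches_adaptive_quadrature(self, b, lam):
        pair = pinch_segment_resistances(0.43, 0.21, 0.07, R, b, slip=lam)
        assert pair.r1 == pytest.approx(quad_resistance(0.43, 0.07, R, b, lam),
                                        rel=1e-8)
        assert pair.r2 == pytest.approx(quad_resistance(0.21, 0.07, R, b, lam),
                                        rel=1e-8)

    def test_monotone_in_pinch_depth(self):
        bs = np.linspace(0.999 * R, 0.01 * R, 40)
        r1 = [pinch_segment_resistances(0.43, 0.43, 0.07, R, b).r1 for b in bs]
        assert np.all(np.diff(r1) > 0)  # resistance grows as b shrinks

    def test_viscosity_scaling(self):
        a = pinch_segment_resistances(0.4, 0.4, 0.1, R, 0.01, mu=1.0)
        b = pinch_segment_resistances(0.4, 0.4, 0.1, R, 0.01, mu=10.0)
        assert b.r1 == pytest.approx(10 * a.r1)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pinch_segment_resistances(0.4, 0.4, 0.1, R, 0.0)
        with pytest.raises(ValueError):
            pinch_segment_resistances(0.4, 0.4, 0.1, R, 2 * R)
        with pytest.raises(ValueError):
            pinch_segment_resistances(0.4, 0.4, 0.1, R, 0.01, slip=-1.0)


class TestFluxProfile:
    def test_static_tube_constant_flux(self):
        z = np.linspace(0, 1, 11)
        q = flux_profile(z, Q1=2.0, b=R, bdot=0.0, L=0.07, R=R, L1=0.43)
        assert np.allclose(q, 2.0)

    def test_endpoint_matches_source_relation(self):
        b, bdot = pinch_b(B0, R, 0.03625, 0.01)
        q_end = flux_profile(1.0, Q1=0.5, b=b, bdot=bdot, L=0.07, R=R, L1=0.43)
        expected = 0.5 - 2 * math.pi * bdot * 0.07 * (R / 3 + 2 * b / 3)
        assert q_end == pytest.approx(expected, rel=1e-12)

    def test_matches_direct_quadrature(self):
        """Q(z) = Q1 − 2π∫ a ∂a/∂t dz̃ against adaptive quadrature."""
        L1, L = 0.43, 0.07
        z0 = L1 + L
        b, bdot = pinch_b(B0, R, 0.03625, 0.02)

        def a_of(z):
            if abs(z - z0) >= L:
                return R
            return b + (R - b) * abs(z - z0) / L

        def dadt(z):
            if abs(z - z0) >= L:
                return 0.0
            return bdot * (1 - abs(z - z0) / L)

        for z in [z0 - 0.05, z0, z0 + 0.03, 1.0]:
            integral, _ = quad(lambda s: a_of(s) * dadt(s), 0, z,
                               points=[z0 - L, z0, z0 + L], limit=400)
            expected = 0.5 - 2 * math.pi * integral
            got = flux_profile(z, Q1=0.5, b=b, bdot=bdot, L=L, R=R, L1=L1)
            assert got == pytest.approx(expected, rel=1e-10)


class TestVelocityField:
    def test_no_slip_wall_and_centreline(self):
        u_wall, _ = velocity_field(R, 0.0, 0.0, 1.0, R, slip=0.0)
        assert u_wall == pytest.approx(0.0, abs=1e-15)
        u0, v0 = velocity_field(R, 0.0, 0.0, 1.0, 0.0, slip=0.0)
        assert u0 == pytest.approx(2 * 1.0 / (math.pi * R ** 2))  # 2x mean
        assert v0 == 0.0

    def test_slip_preserves_flux_reduces_centreline(self):
        r = np.linspace(0, R, 2001)
        u_ns, _ = velocity_field(R, 0.0, 0.0, 1.0, r, slip=0.0)
        for lam in (0.003, 0.03, 0.3):
            u_s, _ = velocity_field(R, 0.0, 0.0, 1.0, r, slip=lam)
            assert u_s[0] < u_ns[0]  # centreline speed drops
            flux = np.trapezoid(2 * math.pi * r * u_s, r)
            assert flux == pytest.approx(1.0, rel=1e-5)  # same volume flux

    def test_kinematic_wall_condition(self):
        # v - a_z u = a_t at r = a (moving, tapering wall), with slip
        a, at, az, Q = 0.02, -0.5, 0.1, 0.3
        for lam in (0.0, 0.01):
            u, v = velocity_field(a, at, az, Q, a, slip=lam)
            assert v - az * u == pytest.approx(at, rel=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.01])
    def test_divergence_free(self, lam):
        """(1/r)∂(rv)/∂r + ∂u/∂z = 0 by central differences."""
        L1, L = 0.43, 0.07
        b, bdot = pinch_b(B0, R, 0.03625, 0.02)
        Q1 = 0.4
        rng = np.random.default_rng(0)
        h = 3e-6
        for _ in range(20):
            z = L1 + rng.uniform(0.1 * L, 1.9 * L)  # inside the pinch
            if abs(z - (L1 + L)) < 3 * h:
                continue
            w = abs(z - L1 - L) / L
            a = b + (R - b) * w
            r = rng.uniform(0.1, 0.8) * a

            def uv(zz, rr):
                ww = abs(zz - L1 - L) / L
                aa = b + (R - b) * ww
                da_dz = (R - b) / L * np.sign(zz - L1 - L)
                da_dt = bdot * (1 - ww)
                Q = flux_profile(zz, Q1, b, bdot, L, R, L1)
                return velocity_field(aa, da_dt, da_dz, Q, rr, slip=lam)

            du_dz = (uv(z + h, r)[0] - uv(z - h, r)[0]) / (2 * h)
            hr = 1e-6
            rv_p = (r + hr) * uv(z, r + hr)[1]
            rv_m = (r - hr) * uv(z, r - hr)[1]
            div = du_dz + (rv_p - rv_m) / (2 * hr) / r
            scale = max(abs(du_dz), 1.0)
            assert abs(div) < 1e-6 * scale

    def test_r_outside_tube_rejected(self):
        with pytest.raises(ValueError):
            velocity_field(R, 0.0, 0.0, 1.0, 2 * R)


from tests_oracles import dense_nodal_oracle, random_pinch_state  # noqa: E402


class TestKirchhoffSolver:
    def test_no_sources_no_flow(self, honeycomb33):
        sol = assemble_and_solve(honeycomb33)
        assert np.allclose(sol.Q1, 0.0)
        assert np.allclose(sol.Q4, 0.0)
        assert np.allclose(sol.node_sources, 0.0)

    def test_single_tubule_symmetry(self, single_tubule):
        b, bdot = pinch_b(B0, R, 0.03625, 0.018)
        sol = assemble_and_solve(single_tubule,
                                 ([b], [bdot], [0.07]))
        q = sol.pinch_sources[0]
        assert sol.Q1[0] == pytest.approx(-q / 2, rel=1e-10)
        assert sol.Q4[0] == pytest.approx(q / 2, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dense_nodal_oracle(self, seed):
        net = generate_er_like_network(30, 1.0, seed=seed)
        assert net.n_nodes <= 60
        b, bdot, L = random_pinch_state(net, seed + 10)
        sol = assemble_and_solve(net, (b, bdot, L))
        Q1o, Q4o = dense_nodal_oracle(net, b, bdot, L)
        scale = np.abs(Q1o).max()
        assert np.abs(sol.Q1 - Q1o).max() < 1e-9 * scale
        assert np.abs(sol.Q4 - Q4o).max() < 1e-9 * scale

    def test_oracle_with_junction_sources(self, honeycomb33):
        net = honeycomb33
        b, bdot, L = random_pinch_state(net, 5)
        interior = [int(n) for n in net.node_ids
                    if net.roles[net.node_index(n)] == "normal"]
        srcs = {interior[0]: 0.05, interior[3]: -0.02}
        sol = assemble_and_solve(net, (b, bdot, L), node_sources=srcs)
        Q1o, Q4o = dense_nodal_oracle(net, b, bdot, L, node_sources=srcs)
        scale = np.abs(Q1o).max()
        assert np.abs(sol.Q1 - Q1o).max() < 1e-9 * scale

    def test_flux_conservation_residuals(self):
        net = build_honeycomb(4, 4, 1.0)
        b, bdot, L = random_pinch_state(net, 7)
        sol = assemble_and_solve(net, (b, bdot, L))
        scale = max(np.abs(sol.Q1).max(), np.abs(sol.Q4).max())
        assert sol.max_residual < 1e-10 * scale
        # global conservation: all sources sum to zero
        total = sol.node_sources.sum() + sol.pinch_sources.sum()
        assert abs(total) < 1e-10 * max(np.abs(sol.node_sources).max(), 1e-30)
        # K1 at every real node, recomputed independently
        ei = net.edge_indices
        for n in range(net.n_nodes):
            out = sol.Q1[ei[:, 0] == n].sum() - sol.Q4[ei[:, 1] == n].sum()
            assert abs(out - sol.node_sources[n]) < 1e-10 * scale

    def test_viscosity_independence(self, honeycomb33):
        b, bdot, L = random_pinch_state(honeycomb33, 2)
        s1 = assemble_and_solve(honeycomb33, (b, bdot, L), mu=1.0)
        s2 = assemble_and_solve(honeycomb33, (b, bdot, L), mu=10.0)
        scale = np.abs(s1.Q1).max()
        assert np.allclose(s1.Q1, s2.Q1, rtol=1e-9, atol=1e-12 * scale)

    def test_inactive_edges_have_uniform_flux(self, honeycomb33):
        b, bdot, L = random_pinch_state(honeycomb33, 3, n_active=4)
        sol = assemble_and_solve(honeycomb33, (b, bdot, L))
        passive = L == 0.0
        assert np.allclose(sol.Q1[passive], sol.Q4[passive],
                           rtol=1e-9, atol=1e-18)

    def test_no_exit_nodes_rejected(self):
        net = TubularNetwork(
            np.arange(3), np.array([[0., 0.], [1., 0.], [2., 0.]]),
            ["normal"] * 3, np.array([[0, 1], [1, 2]]), np.ones(2),
            np.full(2, R))
        with pytest.raises(SolverError, match="exit"):
            KirchhoffSolver(net)

    def test_equal_exit_pressures(self):
        """Recomputed pressures at all exit nodes agree."""
        net = build_honeycomb(3, 3, 1.0)
        b, bdot, L = random_pinch_state(net, 8)
        sol = assemble_and_solve(net, (b, bdot, L))
        # integrate pressure drops over a spanning tree from node 0
        from lumenflow.network import bfs_spanning_tree
        N, E = net.n_nodes, net.n_edges
        ei = net.edge_indices
        r = np.empty(2 * E)
        for e in range(E):
            L1 = 0.5 * (net.lengths[e] - 2 * L[e])
            pair = pinch_segment_resistances(L1, L1, L[e], net.radii[e], b[e])
            r[2 * e], r[2 * e + 1] = pair.r1, pair.r2
        p = np.full(N + E, np.nan)
        p[0] = 0.0
        adj = {i: [] for i in range(N + E)}
        for e in range(E):
            adj[ei[e, 0]].append((2 * e, N + e))
            adj[N + e].append((2 * e, ei[e, 0]))
            adj[N + e].append((2 * e + 1, ei[e, 1]))
            adj[ei[e, 1]].append((2 * e + 1, N + e))
        Qseg = np.empty(2 * E)
        Qseg[0::2] = sol.Q1
        Qseg[1::2] = sol.Q4
        seg_nodes = np.empty((2 * E, 2), dtype=int)
        for e in range(E):
            seg_nodes[2 * e] = (ei[e, 0], N + e)
            seg_nodes[2 * e + 1] = (N + e, ei[e, 1])
        stack = [0]
        while stack:
            u = stack.pop()
            for s, vtx in adj[u]:
                if np.isnan(p[vtx]):
                    sgn = 1.0 if seg_nodes[s][0] == u else -1.0
                    p[vtx] = p[u] - sgn * r[s] * Qseg[s]
                    stack.append(vtx)
        exits = [i for i, role in enumerate(net.roles) if role == "exit"]
        pe = p[exits]
        assert np.nanmax(pe) - np.nanmin(pe) < 1e-7 * (np.nanmax(np.abs(p))
                                                       + 1e-30)

    def test_sheet_constraints(self):
        """Sheet nodes share a pressure and carry the prescribed total source."""
        from lumenflow.scenarios import configure_perinuclear
        net = build_honeycomb(3, 3, 1.0)
        exits = net.exit_nodes.tolist()
        sheet_ids = exits[:3]
        net2, _ = configure_perinuclear(net, sheet_ids)
        solver = KirchhoffSolver(net2)
        sol = solver.solve(sheet_total=2.5)
        sheet_idx = [net2.node_index(n) for n in sheet_ids]
        assert sol.node_sources[sheet_idx].sum() == pytest.approx(2.5,
                                                                  rel=1e-9)
        exit_idx = [i for i, r_ in enumerate(net2.roles) if r_ == "exit"]
        assert sol.node_sources[exit_idx].sum() == pytest.approx(-2.5,
                                                                 rel=1e-9)

    def test_symmetric_sheet_nodes_equal_sources(self):
        """Two sheet nodes placed symmetrically get equal sources."""
        # symmetric 4-node diamond: two sheet nodes opposite two exits
        net = TubularNetwork(
            np.arange(4),
            np.array([[0., 0.], [1., 1.], [1., -1.], [2., 0.]]),
            ["sheet", "exit", "exit", "sheet"],
            np.array([[0, 1], [0, 2], [1, 3], [2, 3]]),
            np.full(4, math.sqrt(2)), np.full(4, R))
        sol = KirchhoffSolver(net).solve(sheet_total=1.0)
        sheet_idx = [0, 3]
        assert sol.node_sources[sheet_idx][0] == pytest.approx(
            sol.node_sources[sheet_idx][1], rel=1e-9)
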