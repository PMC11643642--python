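"""Shared independent oracles for hydraulic solver tests.

The dense nodal-analysis oracle solves the same physical problem from first
principles — unknown pressures at every node of the pinch-augmented graph,
exit nodes grounded, conductance Laplacian solved densely — without touching
the cycle-basis flux formulation it is used to check.
"""

import math

import numpy as np

from lumenflow.contractions import pinch_b
from lumenflow.hydraulics import pinch_segment_resistances

R = 0.03
B0 = 0.01 * R


def dense_nodal_oracle(net, b, bdot, L, node_sources=None, slip=0.0):
    N, E = net.n_nodes, net.n_edges
    ei = net.edge_indices
    n_aug = N + E
    segs = []
    for e in range(E):
        L1 = 0.5 * (net.lengths[e] - 2 * L[e])
        pair = pinch_segment_resistances(L1, L1, L[e], net.radii[e], b[e],
                                         slip=slip)
        segs.append((ei[e, 0], N + e, pair.r1))
        segs.append((N + e, ei[e, 1], pair.r2))
    q = np.zeros(n_aug)
    q[N:] = -(2 * math.pi / 3) * bdot * L * (net.radii + 2 * b)
    if node_sources:
        for nid, s in node_sources.items():
            q[net.node_index(nid)] += s
    exits = [i for i, role in enumerate(net.roles) if role == "exit"]
    A = np.zeros((n_aug, n_aug))
    rhs = q.copy()
    for a, c, r in segs:
        g = 1.0 / r
        A[a, a] += g
        A[a, c] -= g
        A[c, c] += g
        A[c, a] -= g
    for x in exits:
        A[x, :] = 0.0
        A[x, x] = 1.0
        rhs[x] = 0.0
    p = np.linalg.solve(A, rhs)
    Q1 = np.empty(E)
    Q4 = np.empty(E)
    for e in range(E):
        a, c, r = segs[2 * e]
        Q1[e] = (p[a] - p[c]) / r
        a, c, r = segs[2 * e + 1]
        Q4[e] = (p[a] - p[c]) / r
    return Q1, Q4


def random_pinch_state(net, seed, n_active=None):
    rng = np.random.default_rng(seed)
    E = net.n_edges
    b = net.radii.astype(float).copy()
    bdot = np.zeros(E)
    L = np.zeros(E)
    n_active = n_active or max(1, E // 3)
    for e in rng.choice(E, n_active, replace=False):
        bb, bd = pinch_b(B0, R, 0.03625, rng.uniform(1e-4, 2 * 0.03625))
        b[e], bdot[e], L[e] = bb, bd, min(0.07, 0.4 * net.lengths[e])
    return b, bdot, L
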