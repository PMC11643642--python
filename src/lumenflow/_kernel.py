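"""Numba inner loop for Brownian particle advection in a pinching network.

The kernel advances all particles through one flow interval (the flow solution
is frozen between quasi-steady updates).  Positions are tubule-local:
axial coordinate z along the edge plus two transverse offsets (y1 in the
network plane, y2 out of plane).  Walls reflect particles specularly; node
arrivals trigger the Péclet-weighted exit rule.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _local_flow(e, z, Q1, Q4, b, bdot, Lp, active, e_len, e_R):
    """(a, da_dt, da_dz, Q) at axial position z of edge e."""
    l = e_len[e]
    R = e_R[e]
    z0 = 0.5 * l
    if active[e] == 1:
        L = Lp[e]
        dz0 = z - z0
        adz = abs(dz0)
        if adz < L and L > 0.0:
            be = b[e]
            w = adz / L
            a = be + (R - be) * w
            da_dt = bdot[e] * (1.0 - w)
            da_dz = (R - be) / L if dz0 > 0.0 else -(R - be) / L
            if dz0 < 0.0:
                integ = be * (1.0 - w) ** 2 / 2.0 + (R - be) * (
                    1.0 / 6.0 - w * w / 2.0 + w ** 3 / 3.0)
            else:
                F0 = be / 2.0 + (R - be) / 6.0
                H = be * (w - w * w / 2.0) + (R - be) * (w * w / 2.0
                                                         - w ** 3 / 3.0)
                integ = F0 + H
            Q = Q1[e] - 2.0 * math.pi * bdot[e] * L * integ
            return a, da_dt, da_dz, Q
        Q = Q1[e] if z < z0 else Q4[e]
        return R, 0.0, 0.0, Q
    return R, 0.0, 0.0, Q1[e]


@njit(cache=True)
def advance_chunk(n_steps, dt, t0, D, rp, slip,
                  e_i, e_j, e_len, e_R,
                  Q1, Q4, b, bdot, Lp, active,
                  indptr, adj_e, adj_isI,
                  p_edge, p_z, p_y1, p_y2, p_origin, p_tdep,
                  ev_edge, ev_dur, ev_t, n_ev0):
    """Advance all particles by n_steps of length dt under the frozen flow.

    Traversal events (edge index, duration, arrival time) are appended to the
    ev_* buffers starting at n_ev0.  Returns (n_ev, overflow_flag).
    """
    n_ev = n_ev0
    cap = ev_edge.shape[0]
    overflow = 0
    sig = math.sqrt(2.0 * D * dt)
    n_p = p_edge.shape[0]
    for p in range(n_p):
        e = p_edge[p]
        z = p_z[p]
        y1 = p_y1[p]
        y2 = p_y2[p]
        origin = p_origin[p]
        tdep = p_tdep[p]
        for s in range(n_steps):
            a, da_dt, da_dz, Q = _local_flow(e, z, Q1, Q4, b, bdot, Lp,
                                             active, e_len, e_R)
            r = math.sqrt(y1 * y1 + y2 * y2)
            sr = r / a
            if sr > 1.0:
                sr = 1.0
            ell = slip / a
            denom = 1.0 + 4.0 * ell
            u = 2.0 * Q * (1.0 - sr * sr + 2.0 * ell) / (math.pi * a * a
                                                         * denom)
            v = da_dt * sr * (2.0 - sr * sr + 4.0 * ell) / denom
            if da_dz != 0.0:
                rr = sr * a
                k4 = 4.0 * slip
                A = a * a + k4 * a
                p1 = -(2.0 * a + k4) / (A * A) * (rr / 2.0
                                                  - rr ** 3 / (4.0 * a * a)
                                                  + slip * rr / a)
                p2 = (rr ** 3 / (2.0 * a ** 3) - slip * rr / (a * a)) / A
                v += -da_dz * 2.0 * Q / math.pi * (p1 + p2)
            # advect + diffuse
            z = z + u * dt + sig * np.random.normal()
            if r > 1e-12:
                vdt = v * dt / r
                y1 = y1 + vdt * y1
                y2 = y2 + vdt * y2
            y1 = y1 + sig * np.random.normal()
            y2 = y2 + sig * np.random.normal()

            l = e_len[e]
            if z <= 0.0 or z >= l:
                # node arrival
                node = e_i[e] if z <= 0.0 else e_j[e]
                tnow = t0 + (s + 1) * dt
                if origin >= 0 and node != origin:
                    if n_ev < cap:
                        ev_edge[n_ev] = e
                        ev_dur[n_ev] = tnow - tdep
                        ev_t[n_ev] = tnow
                        n_ev += 1
                    else:
                        overflow = 1
                # Péclet-weighted exit
                k0 = indptr[node]
                k1 = indptr[node + 1]
                wsum = 0.0
                for k in range(k0, k1):
                    ee = adj_e[k]
                    Re = e_R[ee]
                    if adj_isI[k] == 1:
                        U = Q1[ee] / (math.pi * Re * Re)
                    else:
                        U = -Q4[ee] / (math.pi * Re * Re)
                    pe = U * Re / D
                    w = pe + 1.0
                    if w > 0.0:
                        wsum += w
                uu = np.random.random()
                chosen = adj_e[k1 - 1]
                chosen_isI = adj_isI[k1 - 1]
                if wsum <= 0.0:
                    idx = k0 + int(uu * (k1 - k0))
                    if idx >= k1:
                        idx = k1 - 1
                    chosen = adj_e[idx]
                    chosen_isI = adj_isI[idx]
                else:
                    target = uu * wsum
                    acc = 0.0
                    for k in range(k0, k1):
                        ee = adj_e[k]
                        Re = e_R[ee]
                        if adj_isI[k] == 1:
                            U = Q1[ee] / (math.pi * Re * Re)
                        else:
                            U = -Q4[ee] / (math.pi * Re * Re)
                        pe = U * Re / D
                        w = pe + 1.0
                        if w < 0.0:
                            w = 0.0
                        acc += w
                        if acc >= target:
                            chosen = ee
                            chosen_isI = adj_isI[k]
                            break
                e = chosen
                z = 0.0 if chosen_isI == 1 else e_len[e]
                y1 = 0.0
                y2 = 0.0
                origin = node
                tdep = tnow
                continue

            # wall handling at the new position
            a2, _, _, _ = _local_flow(e, z, Q1, Q4, b, bdot, Lp, active,
                                      e_len, e_R)
            rmax = a2 - rp
            r = math.sqrt(y1 * y1 + y2 * y2)
            if rmax <= 0.0:
                # wall narrower than the particle: squeeze onto the axis
                y1 = 0.0
                y2 = 0.0
            elif r > rmax:
                rnew = r
                ok = 0
                for _ in range(10):
                    rnew = 2.0 * rmax - rnew
                    if rnew < 0.0:
                        rnew = -rnew
                    if rnew <= rmax:
                        ok = 1
                        break
                if ok == 0:
                    rnew = 0.0
                scale = rnew / r
                y1 *= scale
                y2 *= scale
        p_edge[p] = e
        p_z[p] = z
        p_y1[p] = y1
        p_y2[p] = y2
        p_origin[p] = origin
        p_tdep[p] = tdep
    return n_ev, overflow
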