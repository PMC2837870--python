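"""Numba-compiled fast path for the total-energy evaluation.

The pure-numpy term implementations in :mod:`loopcg.forcefield` are the
reference; this kernel fuses them into one pass over the conformation for
the sampler's inner loop.  Term-by-term equivalence with the reference
path is asserted by the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]

INF = np.inf


@njit(cache=True, fastmath=False)
def total_energy(xyz, sc_dist, out_of_plane, cb_distance,
                 eps, r_rep2, r_min2, r_max2, eps_rep, min_contact_sep,
                 hc_ca2, hc_cb2,
                 e13_gen, e14_gen, cls13, cls14,
                 r13_lo, r13_step, r14_lo, r14_step,
                 hb_dmin2, hb_dmax2, hb_colin, hb_e, hb_coop,
                 rst_i, rst_j, rst_d0, rst_tol, rst_w,
                 w_ev, w_sr, w_pc, w_hb, w_rst):
    n = xyz.shape[0]
    # ---- pseudo-atoms (sc, cb) ----
    sc = xyz.copy()
    cb = xyz.copy()
    if n >= 3:
        for i in range(1, n - 1):
            b1x = xyz[i, 0] - xyz[i - 1, 0]
            b1y = xyz[i, 1] - xyz[i - 1, 1]
            b1z = xyz[i, 2] - xyz[i - 1, 2]
            b2x = xyz[i + 1, 0] - xyz[i, 0]
            b2y = xyz[i + 1, 1] - xyz[i, 1]
            b2z = xyz[i + 1, 2] - xyz[i, 2]
            n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            e1x, e1y, e1z = -b1x / n1, -b1y / n1, -b1z / n1
            e2x, e2y, e2z = b2x / n2, b2y / n2, b2z / n2
            dx = -(e1x + e2x)
            dy = -(e1y + e2y)
            dz = -(e1z + e2z)
            cx = e1y * e2z - e1z * e2y
            cy = e1z * e2x - e1x * e2z
            cz = e1x * e2y - e1y * e2x
            cn = np.sqrt(cx * cx + cy * cy + cz * cz)
            if cn > 1e-9:
                dx += out_of_plane * cx / cn
                dy += out_of_plane * cy / cn
                dz += out_of_plane * cz / cn
            dn = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dn < 1e-9:
                # collinear frame: any perpendicular to the chain direction
                if abs(e2x) < 0.9:
                    px, py, pz = 0.0, e2z, -e2y
                else:
                    px, py, pz = -e2z, 0.0, e2x
                pn = np.sqrt(px * px + py * py + pz * pz)
                dx, dy, dz = px / pn, py / pn, pz / pn
                dn = 1.0
            dx, dy, dz = dx / dn, dy / dn, dz / dn
            sc[i, 0] = xyz[i, 0] + dx * sc_dist[i]
            sc[i, 1] = xyz[i, 1] + dy * sc_dist[i]
            sc[i, 2] = xyz[i, 2] + dz * sc_dist[i]
            cb[i, 0] = xyz[i, 0] + dx * cb_distance
            cb[i, 1] = xyz[i, 1] + dy * cb_distance
            cb[i, 2] = xyz[i, 2] + dz * cb_distance
            if i == 1:
                sc[0, 0] = xyz[0, 0] + dx * sc_dist[0]
                sc[0, 1] = xyz[0, 1] + dy * sc_dist[0]
                sc[0, 2] = xyz[0, 2] + dz * sc_dist[0]
                cb[0, 0] = xyz[0, 0] + dx * cb_distance
                cb[0, 1] = xyz[0, 1] + dy * cb_distance
                cb[0, 2] = xyz[0, 2] + dz * cb_distance
            if i == n - 2:
                sc[n - 1, 0] = xyz[n - 1, 0] + dx * sc_dist[n - 1]
                sc[n - 1, 1] = xyz[n - 1, 1] + dy * sc_dist[n - 1]
                sc[n - 1, 2] = xyz[n - 1, 2] + dz * sc_dist[n - 1]
                cb[n - 1, 0] = xyz[n - 1, 0] + dx * cb_distance
                cb[n - 1, 1] = xyz[n - 1, 1] + dy * cb_distance
                cb[n - 1, 2] = xyz[n - 1, 2] + dz * cb_distance

    # ---- excluded volume + pair contacts ----
    e_pc = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            ddx = xyz[i, 0] - xyz[j, 0]
            ddy = xyz[i, 1] - xyz[j, 1]
            ddz = xyz[i, 2] - xyz[j, 2]
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 < hc_ca2:
                return INF
            ddx = cb[i, 0] - cb[j, 0]
            ddy = cb[i, 1] - cb[j, 1]
            ddz = cb[i, 2] - cb[j, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz < hc_cb2:
                return INF
            if j - i >= min_contact_sep:
                ddx = sc[i, 0] - sc[j, 0]
                ddy = sc[i, 1] - sc[j, 1]
                ddz = sc[i, 2] - sc[j, 2]
                s2 = ddx * ddx + ddy * ddy + ddz * ddz
                if s2 < r_rep2[i, j]:
                    e_pc += eps_rep
                elif r_min2[i, j] <= s2 <= r_max2[i, j]:
                    e_pc -= eps[i, j]

    # ---- short range ----
    e_sr = 0.0
    nb13 = e13_gen.shape[0]
    nb14 = e14_gen.shape[0]
    for i in range(n - 2):
        vx = xyz[i + 2, 0] - xyz[i, 0]
        vy = xyz[i + 2, 1] - xyz[i, 1]
        vz = xyz[i + 2, 2] - xyz[i, 2]
        r13 = np.sqrt(vx * vx + vy * vy + vz * vz)
        b = int((r13 - r13_lo) / r13_step)
        if b < 0:
            b = 0
        elif b >= nb13:
            b = nb13 - 1
        e_sr += e13_gen[b] + cls13[i + 1, b]
    for i in range(n - 3):
        b1x = xyz[i + 1, 0] - xyz[i, 0]
        b1y = xyz[i + 1, 1] - xyz[i, 1]
        b1z = xyz[i + 1, 2] - xyz[i, 2]
        b2x = xyz[i + 2, 0] - xyz[i + 1, 0]
        b2y = xyz[i + 2, 1] - xyz[i + 1, 1]
        b2z = xyz[i + 2, 2] - xyz[i + 1, 2]
        b3x = xyz[i + 3, 0] - xyz[i + 2, 0]
        b3y = xyz[i + 3, 1] - xyz[i + 2, 1]
        b3z = xyz[i + 3, 2] - xyz[i + 2, 2]
        cx = b1y * b2z - b1z * b2y
        cy = b1z * b2x - b1x * b2z
        cz = b1x * b2y - b1y * b2x
        chir = cx * b3x + cy * b3y + cz * b3z
        vx = xyz[i + 3, 0] - xyz[i, 0]
        vy = xyz[i + 3, 1] - xyz[i, 1]
        vz = xyz[i + 3, 2] - xyz[i, 2]
        r14 = np.sqrt(vx * vx + vy * vy + vz * vz)
        if chir < -1e-6:  # coplanar counts as right-handed (rotation-stable)
            r14 = -r14
        b = int((r14 - r14_lo) / r14_step)
        if b < 0:
            b = 0
        elif b >= nb14:
            b = nb14 - 1
        e_sr += e14_gen[b] + cls14[i + 1, b]

    # ---- hydrogen bonds ----
    e_hb = 0.0
    if n >= 4:
        tang = np.empty((n, 3))
        for i in range(n):
            if i == 0:
                tx = xyz[1, 0] - xyz[0, 0]
                ty = xyz[1, 1] - xyz[0, 1]
                tz = xyz[1, 2] - xyz[0, 2]
            elif i == n - 1:
                tx = xyz[n - 1, 0] - xyz[n - 2, 0]
                ty = xyz[n - 1, 1] - xyz[n - 2, 1]
                tz = xyz[n - 1, 2] - xyz[n - 2, 2]
            else:
                tx = xyz[i + 1, 0] - xyz[i - 1, 0]
                ty = xyz[i + 1, 1] - xyz[i - 1, 1]
                tz = xyz[i + 1, 2] - xyz[i - 1, 2]
            tn = np.sqrt(tx * tx + ty * ty + tz * tz)
            tang[i, 0] = tx / tn
            tang[i, 1] = ty / tn
            tang[i, 2] = tz / tn
        B = np.zeros((n, n), dtype=np.bool_)
        nb = 0
        for i in range(n):
            for j in range(i + min_contact_sep, n):
                ax = xyz[j, 0] - xyz[i, 0]
                ay = xyz[j, 1] - xyz[i, 1]
                az = xyz[j, 2] - xyz[i, 2]
                d2 = ax * ax + ay * ay + az * az
                if d2 < hb_dmin2 or d2 > hb_dmax2:
                    continue
                dn = np.sqrt(d2)
                ci = abs(ax * tang[i, 0] + ay * tang[i, 1] + az * tang[i, 2]) / dn
                cj = abs(ax * tang[j, 0] + ay * tang[j, 1] + az * tang[j, 2]) / dn
                if ci <= hb_colin and cj <= hb_colin:
                    B[i, j] = True
                    nb += 1
        ncoop = 0
        for i in range(n - 1):
            for j in range(i + 1, n - 1):
                if B[i, j] and B[i + 1, j + 1]:
                    ncoop += 1
            for j in range(i + 2, n):
                if B[i, j] and B[i + 1, j - 1]:
                    ncoop += 1
        e_hb = -hb_e * nb - hb_coop * ncoop

    # ---- restraints ----
    e_rst = 0.0
    for k in range(rst_i.shape[0]):
        i = rst_i[k]
        j = rst_j[k]
        ddx = xyz[i, 0] - xyz[j, 0]
        ddy = xyz[i, 1] - xyz[j, 1]
        ddz = xyz[i, 2] - xyz[j, 2]
        d = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
        v = abs(d - rst_d0[k]) - rst_tol[k]
        if v > 0.0:
            e_rst += rst_w[k] * v * v

    # w_ev scales a term that is 0 or the +inf sentinel, so it appears only
    # through the early returns above
    return w_pc * e_pc + w_sr * e_sr + w_hb * e_hb + w_rst * e_rst
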