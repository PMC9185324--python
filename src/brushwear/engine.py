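"""Explicit discrete-element dynamics engine.

Assembles all forces (Hertz-Mindlin contacts, WLC chain elasticity,
optional torsion and gravity, background viscous damping) and integrates
free particles with a semi-implicit (symplectic) Euler scheme; clamped
particles are advanced kinematically with the brush head.  The inner loop
is a single numba-compiled kernel; candidate bristle-bristle contact pairs
are maintained by a Verlet list rebuilt between kernel chunks.

The engine is strictly deterministic: there is no randomness anywhere, and
identical inputs produce bit-identical trajectories, force logs and wear
grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .contact import effective_pair_properties
from .geometry import BrushAssembly, MotionProfile, ToothModel
from .materials import ENAMEL, Material

_DAMP = 2.0 * math.sqrt(5.0 / 6.0)

# --- parameter-array slots (float params) -----------------------------------
PT_KHZ, PT_SN, PT_KT, PT_BETA, PT_MU = 0, 1, 2, 3, 4
PP_KHZ, PP_SN, PP_KT, PP_BETA, PP_MU, PP_DSUM = 5, 6, 7, 8, 9, 10
G_XGL, G_XGR, G_DEPTH, G_XLO, G_XHI, G_XM0, G_XM1, G_YHALF = 11, 12, 13, 14, 15, 16, 17, 18
W_CELL, W_KOH = 19, 20
M_V, M_L, M_ON = 21, 22, 23
BG_GAMMA, GRAV_Z = 24, 25
T_SNAP1, T_SNAP2, SNAP_WIN = 26, 27, 28
TOOTH_ON, TORSION_ON, TOR_KT, TOR_GAMMA0, TOR_IINV = 29, 30, 31, 32, 33
N_PAR = 34

_ABORT_OK = -1


@njit(cache=True)
def _tooth_query(cx, cy, cz, radius, gl, gr, depth, xlo, xhi, out):
    """Closed-form sphere contact against the plate+groove cross-section.

    ``out`` is a (2, 5) buffer filled with rows (delta_n, nx, nz, px, pz);
    returns the number of contacts (0..2).  Face contacts use the signed
    face distance (so a center on or slightly behind a face still gets the
    outward face normal); a center inside the solid is pushed out through
    its nearest face only.  Face contacts are preferred over edge/corner
    contacts and duplicate corner hits are merged.
    """
    n_face = 0
    s_min = 1.0e30
    n_edge = 0
    e0 = 0.0
    e1 = 0.0
    e2 = 0.0
    e3 = 0.0
    e4 = 0.0  # first edge hit
    f0 = 0.0
    f1 = 0.0
    f2 = 0.0
    f3 = 0.0
    f4 = 0.0  # second edge hit
    for k in range(5):
        if k == 0:
            ax, az, bx, bz, nx, nz = xlo, 0.0, gl, 0.0, 0.0, 1.0
        elif k == 1:
            ax, az, bx, bz, nx, nz = gl, -depth, gl, 0.0, 1.0, 0.0
        elif k == 2:
            ax, az, bx, bz, nx, nz = gl, -depth, gr, -depth, 0.0, 1.0
        elif k == 3:
            ax, az, bx, bz, nx, nz = gr, -depth, gr, 0.0, -1.0, 0.0
        else:
            ax, az, bx, bz, nx, nz = gr, 0.0, xhi, 0.0, 0.0, 1.0
        ex = bx - ax
        ez = bz - az
        seg2 = ex * ex + ez * ez
        t = ((cx - ax) * ex + (cz - az) * ez) / seg2
        tc = t
        if tc < 0.0:
            tc = 0.0
        elif tc > 1.0:
            tc = 1.0
        px = ax + tc * ex
        pz = az + tc * ez
        interior = (tc > 1e-9) and (tc < 1.0 - 1e-9)
        if interior:
            s = (cx - px) * nx + (cz - pz) * nz  # signed face distance
            if s < radius:
                if s < s_min:
                    s_min = s
                if n_face < 2:
                    out[n_face, 0] = radius - s
                    out[n_face, 1] = nx
                    out[n_face, 2] = nz
                    out[n_face, 3] = px
                    out[n_face, 4] = pz
                    n_face += 1
        else:
            dx = cx - px
            dz = cz - pz
            dist = math.sqrt(dx * dx + dz * dz)
            if dist >= radius or dist == 0.0:
                continue
            if n_edge == 0:
                e0, e1, e2, e3, e4 = radius - dist, dx / dist, dz / dist, px, pz
                n_edge = 1
            elif n_edge == 1:
                # merge duplicate corner hits
                if abs(px - e3) > 1e-12 or abs(pz - e4) > 1e-12:
                    f0, f1, f2, f3, f4 = radius - dist, dx / dist, dz / dist, px, pz
                    n_edge = 2
    if n_face > 0:
        if s_min < 0.0:
            # inside the solid: nearest face only.  s_best tracks the most
            # negative s, but "nearest" is the largest s: rescan kept rows.
            if n_face == 2:
                if out[0, 0] <= out[1, 0]:
                    return 1
                out[0, 0] = out[1, 0]
                out[0, 1] = out[1, 1]
                out[0, 2] = out[1, 2]
                out[0, 3] = out[1, 3]
                out[0, 4] = out[1, 4]
                return 1
            return 1
        return n_face
    n = 0
    if n_edge >= 1:
        out[0, 0], out[0, 1], out[0, 2], out[0, 3], out[0, 4] = e0, e1, e2, e3, e4
        n = 1
    if n_edge == 2:
        out[1, 0], out[1, 1], out[1, 2], out[1, 3], out[1, 4] = f0, f1, f2, f3, f4
        n = 2
    return n


@njit(cache=True)
def _facet_and_u(px, pz, par):
    """Facet id (0..6) and unfolded coordinate u of a surface point."""
    gl = par[G_XGL]
    gr = par[G_XGR]
    depth = par[G_DEPTH]
    xm0 = par[G_XM0]
    xm1 = par[G_XM1]
    plate_w = gl - xm0
    if pz >= -1e-12 and px <= gl + 1e-12:
        if px >= xm0:
            return 1, px - xm0
        return 0, 0.0
    if pz >= -1e-12 and px >= gr - 1e-12:
        if px <= xm1:
            return 5, plate_w + 2.0 * depth + (gr - gl) + (px - gr)
        return 6, 0.0
    if pz <= -depth + 1e-12:
        return 3, plate_w + depth + (px - gl)
    if px <= 0.5 * (gl + gr):
        return 2, plate_w + (-pz)
    return 4, plate_w + depth + (gr - gl) + (pz + depth)


@njit(cache=True)
def _run_chunk(
    n_steps,
    start_step,
    t0,
    dt,
    par,
    pos,
    vel,
    frc,
    mass,
    inv_mass,
    fext,
    clamped,
    anchor0,
    bond_ij,
    bond_ks,
    bond_l0,
    bond_twist,
    spin,
    joint_ijk,
    joint_kb,
    pairs,
    pair_hist,
    tan_hist,
    tan_act,
    radius,
    work_grid,
    dropped,
    tip_idx,
    tip_groove_max,
    snap_done,
    snap_mean,
    snap_count,
    snap_groove_max,
    snap_tip_f,
    snap_tip_fn,
    snap_tip_ft,
    snap_tip_x,
    snap_tip_y,
    snap_win_max,
    log_next,
    log_t,
    log_s,
    log_ke,
    log_fn,
    log_ft,
    stride,
    tfv,
    tn,
    tt,
    stats,
):
    n = pos.shape[0]
    nb = bond_ij.shape[0]
    nj = joint_ijk.shape[0]
    npair = pairs.shape[0]
    ntip = tip_idx.shape[0]
    nu = work_grid.shape[0]
    nv = work_grid.shape[1]
    cell = par[W_CELL]
    t = t0
    cbuf = np.empty((2, 5))
    abort = _ABORT_OK

    half_t = 0.5 * par[M_L] / par[M_V] if par[M_V] > 0.0 else 0.0

    for istep in range(n_steps):
        gstep = start_step + istep
        # ---- force assembly -------------------------------------------------
        for i in range(n):
            frc[i, 0] = fext[i, 0]
            frc[i, 1] = fext[i, 1]
            frc[i, 2] = fext[i, 2] + mass[i] * par[GRAV_Z]
            tfv[i, 0] = 0.0
            tfv[i, 1] = 0.0
            tfv[i, 2] = 0.0
            tn[i] = 0.0
            tt[i] = 0.0

        # WLC stretching
        for b in range(nb):
            i = bond_ij[b, 0]
            j = bond_ij[b, 1]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            l = math.sqrt(dx * dx + dy * dy + dz * dz)
            if l <= 0.0:
                stats[4] = float(i)
                return gstep
            coef = bond_ks[b] * (l - bond_l0[b]) / l
            fx = coef * dx
            fy = coef * dy
            fz = coef * dz
            frc[i, 0] += fx
            frc[i, 1] += fy
            frc[i, 2] += fz
            frc[j, 0] -= fx
            frc[j, 1] -= fy
            frc[j, 2] -= fz

        # WLC bending
        for q in range(nj):
            a = joint_ijk[q, 0]
            m = joint_ijk[q, 1]
            c = joint_ijk[q, 2]
            kb = joint_kb[q]
            t1x = pos[m, 0] - pos[a, 0]
            t1y = pos[m, 1] - pos[a, 1]
            t1z = pos[m, 2] - pos[a, 2]
            l1 = math.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
            t2x = pos[c, 0] - pos[m, 0]
            t2y = pos[c, 1] - pos[m, 1]
            t2z = pos[c, 2] - pos[m, 2]
            l2 = math.sqrt(t2x * t2x + t2y * t2y + t2z * t2z)
            if l1 <= 0.0 or l2 <= 0.0:
                stats[4] = float(m)
                return gstep
            t1x /= l1
            t1y /= l1
            t1z /= l1
            t2x /= l2
            t2y /= l2
            t2z /= l2
            cos = t1x * t2x + t1y * t2y + t1z * t2z
            gpx = -(t2x - cos * t1x) / l1
            gpy = -(t2y - cos * t1y) / l1
            gpz = -(t2z - cos * t1z) / l1
            gnx = (t1x - cos * t2x) / l2
            gny = (t1y - cos * t2y) / l2
            gnz = (t1z - cos * t2z) / l2
            frc[a, 0] += kb * gpx
            frc[a, 1] += kb * gpy
            frc[a, 2] += kb * gpz
            frc[c, 0] += kb * gnx
            frc[c, 1] += kb * gny
            frc[c, 2] += kb * gnz
            frc[m, 0] -= kb * (gpx + gnx)
            frc[m, 1] -= kb * (gpy + gny)
            frc[m, 2] -= kb * (gpz + gnz)

        # bristle-tooth contacts
        if par[TOOTH_ON] > 0.5:
            for i in range(n):
                seen0 = -1
                seen1 = -1
                nc = _tooth_query(
                    pos[i, 0],
                    pos[i, 1],
                    pos[i, 2],
                    radius,
                    par[G_XGL],
                    par[G_XGR],
                    par[G_DEPTH],
                    par[G_XLO],
                    par[G_XHI],
                    cbuf,
                )
                for k in range(nc):
                    delta = cbuf[k, 0]
                    nx = cbuf[k, 1]
                    nz = cbuf[k, 2]
                    px = cbuf[k, 3]
                    pz = cbuf[k, 4]
                    fid, ucoord = _facet_and_u(px, pz, par)
                    if k == 0:
                        seen0 = fid
                    else:
                        seen1 = fid
                    vn = vel[i, 0] * nx + vel[i, 2] * nz
                    sqd = math.sqrt(delta)
                    f_el = par[PT_KHZ] * delta * sqd
                    c_n = _DAMP * par[PT_BETA] * math.sqrt(par[PT_SN] * sqd * mass[i])
                    fn = f_el - c_n * vn
                    if fn < 0.0:
                        fn = 0.0
                    # tangential velocity (full 3-D; normal lies in x-z)
                    vtx = vel[i, 0] - vn * nx
                    vty = vel[i, 1]
                    vtz = vel[i, 2] - vn * nz
                    # history: project onto the tangent plane, accumulate slip
                    hx = tan_hist[i, fid, 0]
                    hy = tan_hist[i, fid, 1]
                    hz = tan_hist[i, fid, 2]
                    if tan_act[i, fid] == 0:
                        hx = 0.0
                        hy = 0.0
                        hz = 0.0
                    hn = hx * nx + hz * nz
                    hx -= hn * nx
                    hz -= hn * nz
                    hx += vtx * dt
                    hy += vty * dt
                    hz += vtz * dt
                    kt = par[PT_KT] * sqd
                    c_t = _DAMP * par[PT_BETA] * math.sqrt(kt * mass[i])
                    ftx = -kt * hx - c_t * vtx
                    fty = -kt * hy - c_t * vty
                    ftz = -kt * hz - c_t * vtz
                    ftm = math.sqrt(ftx * ftx + fty * fty + ftz * ftz)
                    cap = par[PT_MU] * fn
                    if ftm > cap:
                        if ftm > 0.0:
                            sc = cap / ftm
                            ftx *= sc
                            fty *= sc
                            ftz *= sc
                        hx = -ftx / kt
                        hy = -fty / kt
                        hz = -ftz / kt
                        ftm = cap
                    tan_hist[i, fid, 0] = hx
                    tan_hist[i, fid, 1] = hy
                    tan_hist[i, fid, 2] = hz
                    frc[i, 0] += fn * nx + ftx
                    frc[i, 1] += fty
                    frc[i, 2] += fn * nz + ftz
                    tfv[i, 0] += fn * nx + ftx
                    tfv[i, 1] += fty
                    tfv[i, 2] += fn * nz + ftz
                    tn[i] += fn
                    tt[i] += ftm
                    # Archard wear on measured facets
                    vtm = math.sqrt(vtx * vtx + vty * vty + vtz * vtz)
                    w = fn * vtm * dt
                    if fid == 0 or fid == 6:
                        dropped[0] += w
                    elif w > 0.0:
                        iu = int(ucoord / cell)
                        if iu < 0:
                            iu = 0
                        elif iu >= nu:
                            iu = nu - 1
                        iv = int((pz * 0.0 + pos[i, 1] + par[G_YHALF]) / cell)
                        if iv < 0:
                            iv = 0
                        elif iv >= nv:
                            iv = nv - 1
                        work_grid[iu, iv] += w
                # contact-break bookkeeping for the 7 facet slots
                for fid in range(7):
                    if fid == seen0 or fid == seen1:
                        tan_act[i, fid] = 1
                    elif tan_act[i, fid] == 1:
                        tan_act[i, fid] = 0
                        tan_hist[i, fid, 0] = 0.0
                        tan_hist[i, fid, 1] = 0.0
                        tan_hist[i, fid, 2] = 0.0

        # bristle-bristle contacts (candidate Verlet pairs)
        dsum = par[PP_DSUM]
        for p in range(npair):
            i = pairs[p, 0]
            j = pairs[p, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 >= dsum * dsum or d2 == 0.0:
                pair_hist[p, 0] = 0.0
                pair_hist[p, 1] = 0.0
                pair_hist[p, 2] = 0.0
                continue
            dist = math.sqrt(d2)
            nx = dx / dist
            ny = dy / dist
            nz = dz / dist
            delta = dsum - dist
            im = inv_mass[i] + inv_mass[j]
            if im == 0.0:
                continue
            mstar = 1.0 / im
            rvx = vel[i, 0] - vel[j, 0]
            rvy = vel[i, 1] - vel[j, 1]
            rvz = vel[i, 2] - vel[j, 2]
            vn = rvx * nx + rvy * ny + rvz * nz
            sqd = math.sqrt(delta)
            f_el = par[PP_KHZ] * delta * sqd
            c_n = _DAMP * par[PP_BETA] * math.sqrt(par[PP_SN] * sqd * mstar)
            fn = f_el - c_n * vn
            if fn < 0.0:
                fn = 0.0
            vtx = rvx - vn * nx
            vty = rvy - vn * ny
            vtz = rvz - vn * nz
            hx = pair_hist[p, 0]
            hy = pair_hist[p, 1]
            hz = pair_hist[p, 2]
            hn = hx * nx + hy * ny + hz * nz
            hx -= hn * nx
            hy -= hn * ny
            hz -= hn * nz
            hx += vtx * dt
            hy += vty * dt
            hz += vtz * dt
            kt = par[PP_KT] * sqd
            c_t = _DAMP * par[PP_BETA] * math.sqrt(kt * mstar)
            ftx = -kt * hx - c_t * vtx
            fty = -kt * hy - c_t * vty
            ftz = -kt * hz - c_t * vtz
            ftm = math.sqrt(ftx * ftx + fty * fty + ftz * ftz)
            cap = par[PP_MU] * fn
            if ftm > cap:
                if ftm > 0.0:
                    sc = cap / ftm
                    ftx *= sc
                    fty *= sc
                    ftz *= sc
                hx = -ftx / kt
                hy = -fty / kt
                hz = -ftz / kt
            pair_hist[p, 0] = hx
            pair_hist[p, 1] = hy
            pair_hist[p, 2] = hz
            frc[i, 0] += fn * nx + ftx
            frc[i, 1] += fn * ny + fty
            frc[i, 2] += fn * nz + ftz
            frc[j, 0] -= fn * nx + ftx
            frc[j, 1] -= fn * ny + fty
            frc[j, 2] -= fn * nz + ftz

        # torsion (optional): scalar twist per bond, spin about the bond axis
        if par[TORSION_ON] > 0.5:
            for b in range(nb):
                i = bond_ij[b, 0]
                j = bond_ij[b, 1]
                bond_twist[b] += (spin[j] - spin[i]) * dt
                tau = -par[TOR_KT] * (bond_twist[b] - par[TOR_GAMMA0])
                if clamped[i] == 0:
                    spin[i] -= tau * par[TOR_IINV] * dt
                if clamped[j] == 0:
                    spin[j] += tau * par[TOR_IINV] * dt
            for i in range(n):
                spin[i] -= par[BG_GAMMA] * spin[i] * dt

        # background damping + integration (semi-implicit Euler)
        gam = par[BG_GAMMA]
        for i in range(n):
            if clamped[i] == 1:
                continue
            frc[i, 0] -= gam * mass[i] * vel[i, 0]
            frc[i, 1] -= gam * mass[i] * vel[i, 1]
            frc[i, 2] -= gam * mass[i] * vel[i, 2]
            vel[i, 0] += frc[i, 0] * inv_mass[i] * dt
            vel[i, 1] += frc[i, 1] * inv_mass[i] * dt
            vel[i, 2] += frc[i, 2] * inv_mass[i] * dt
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt

        t += dt

        # head kinematics (clamped particles)
        if par[M_ON] > 0.5:
            if t <= half_t:
                s = par[M_V] * t
                vx = par[M_V]
            else:
                s = par[M_V] * half_t - par[M_V] * (t - half_t)
                vx = -par[M_V]
            for i in range(n):
                if clamped[i] == 1:
                    pos[i, 0] = anchor0[i, 0] + s
                    pos[i, 1] = anchor0[i, 1]
                    pos[i, 2] = anchor0[i, 2]
                    vel[i, 0] = vx
                    vel[i, 1] = 0.0
                    vel[i, 2] = 0.0
        else:
            s = 0.0

        # ---- tip aggregates, snapshots, logging ----------------------------
        for k in range(ntip):
            ti = tip_idx[k]
            fmag = math.sqrt(
                tfv[ti, 0] * tfv[ti, 0] + tfv[ti, 1] * tfv[ti, 1] + tfv[ti, 2] * tfv[ti, 2]
            )
            in_groove = par[G_XGL] <= pos[ti, 0] <= par[G_XGR]
            if in_groove:
                if fmag > tip_groove_max[k]:
                    tip_groove_max[k] = fmag
            for sidx in range(2):
                ts = par[T_SNAP1] if sidx == 0 else par[T_SNAP2]
                if ts - par[SNAP_WIN] <= t <= ts + par[SNAP_WIN]:
                    if fmag > snap_win_max[sidx, k]:
                        snap_win_max[sidx, k] = fmag
                    if in_groove and fmag > snap_groove_max[sidx]:
                        snap_groove_max[sidx] = fmag
        for sidx in range(2):
            ts = par[T_SNAP1] if sidx == 0 else par[T_SNAP2]
            if snap_done[sidx] == 0 and t >= ts and par[M_ON] > 0.5:
                tot = 0.0
                cnt = 0
                for k in range(ntip):
                    ti = tip_idx[k]
                    fmag = math.sqrt(
                        tfv[ti, 0] * tfv[ti, 0]
                        + tfv[ti, 1] * tfv[ti, 1]
                        + tfv[ti, 2] * tfv[ti, 2]
                    )
                    snap_tip_f[sidx, k] = fmag
                    snap_tip_fn[sidx, k] = tn[ti]
                    snap_tip_ft[sidx, k] = tt[ti]
                    snap_tip_x[sidx, k] = pos[ti, 0]
                    snap_tip_y[sidx, k] = pos[ti, 1]
                    if fmag > 0.0:
                        tot += fmag
                        cnt += 1
                snap_mean[sidx] = tot / cnt if cnt > 0 else 0.0
                snap_count[sidx] = cnt
                snap_done[sidx] = 1

        if gstep % stride == 0:
            row = log_next[0]
            if row < log_t.shape[0]:
                ke = 0.0
                for i in range(n):
                    if clamped[i] == 0:
                        ke += (
                            0.5
                            * mass[i]
                            * (
                                vel[i, 0] * vel[i, 0]
                                + vel[i, 1] * vel[i, 1]
                                + vel[i, 2] * vel[i, 2]
                            )
                        )
                log_t[row] = t
                log_s[row] = s
                log_ke[row] = ke
                for k in range(ntip):
                    ti = tip_idx[k]
                    log_fn[row, k] = tn[ti]
                    log_ft[row, k] = tt[ti]
                log_next[0] = row + 1
                if not math.isfinite(ke):
                    stats[4] = -2.0
                    return gstep

    # ---- chunk-exit statistics ---------------------------------------------
    vmax = 0.0
    fmax = 0.0
    ke = 0.0
    for i in range(n):
        if clamped[i] == 1:
            continue
        v2 = vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1] + vel[i, 2] * vel[i, 2]
        ke += 0.5 * mass[i] * v2
        if v2 > vmax:
            vmax = v2
        f2 = frc[i, 0] * frc[i, 0] + frc[i, 1] * frc[i, 1] + frc[i, 2] * frc[i, 2]
        if f2 > fmax:
            fmax = f2
    stats[0] = math.sqrt(vmax)
    stats[1] = math.sqrt(fmax)
    stats[2] = ke
    stats[3] = t
    return _ABORT_OK


def critical_timestep(
    assembly: BrushAssembly,
    tooth_material: Material = ENAMEL,
    depth: float = 0.9e-3,
    safety: float = 0.1,
) -> float:
    """Recommended stable timestep.

    dt_crit = 2 sqrt(m_min / k_max) where k_max bounds the stiffest
    interaction: the chain stretching spring and the Hertz tangent stiffness
    2 E* sqrt(R* delta) evaluated at the prescribed brushing depth (the
    largest overlap the kinematics enforce).  Returns safety * dt_crit.
    """
    r = assembly.particle_radius
    m = assembly.particle_mass
    pt = effective_pair_properties(assembly.material, tooth_material, r)
    pp = effective_pair_properties(assembly.material, assembly.material, r, r)
    delta = max(depth, 0.1 * r)
    k_hertz_t = 2.0 * pt.eq_elastic_modulus * math.sqrt(pt.eq_radius * delta)
    k_hertz_p = 2.0 * pp.eq_elastic_modulus * math.sqrt(pp.eq_radius * delta)
    k_max = max(assembly.chain.k_s, k_hertz_t, k_hertz_p)
    return safety * 2.0 * math.sqrt(m / k_max)


@dataclass
class EngineParams:
    """Tunable engine settings (see docs/methods.md for rationale)."""

    restitution: float = 0.3
    friction: float = 0.18
    gamma_bg: float = 10.0  # background viscous damping, 1/s
    gravity: bool = False
    torsion: bool = False
    pair_contacts: bool = True
    dt_safety: float = 0.1
    wear_cell: float = 0.5e-3
    archard_k: float = 1.0
    log_stride: int = 200
    snap_window: float = 5.0e-3  # rolling-max window around snapshots, s
    verlet_skin: float = 0.9e-3


class Engine:
    """Stateful simulation driver around the compiled kernel."""

    def __init__(
        self,
        positions: np.ndarray,
        masses: np.ndarray,
        radius: float,
        clamped: np.ndarray,
        bonds: np.ndarray,
        bond_ks: np.ndarray,
        bond_l0: np.ndarray,
        joints: np.ndarray,
        joint_kb: np.ndarray,
        material: Material,
        teeth: Optional[ToothModel] = None,
        motion: Optional[MotionProfile] = None,
        tooth_material: Material = ENAMEL,
        params: EngineParams = None,
        dt: Optional[float] = None,
        tip_indices: Optional[np.ndarray] = None,
        torsion_kt: float = 1.0,
        n_wear_u: int = 1,
        n_wear_v: int = 1,
        max_log_rows: int = 20_000,
    ):
        self.params = params or EngineParams()
        p = self.params
        n = positions.shape[0]
        self.n = n
        self.pos = np.array(positions, dtype=np.float64)
        self.vel = np.zeros((n, 3))
        self.frc = np.zeros((n, 3))
        self.mass = np.array(masses, dtype=np.float64)
        self.clamped = np.array(clamped, dtype=np.int8)
        self.inv_mass = np.where(self.clamped == 1, 0.0, 1.0 / self.mass)
        self.fext = np.zeros((n, 3))
        self.anchor0 = np.array(self.pos)
        self.radius = float(radius)
        self.bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_ks = np.array(bond_ks, dtype=np.float64)
        self.bond_l0 = np.array(bond_l0, dtype=np.float64)
        self.bond_twist = np.zeros(len(self.bonds))
        self.spin = np.zeros(n)
        self.joints = np.array(joints, dtype=np.int64).reshape(-1, 3)
        self.joint_kb = np.array(joint_kb, dtype=np.float64)
        self.material = material
        self.teeth = teeth
        self.motion = motion
        self.step_count = 0
        self.t = 0.0

        # contact parameter block
        par = np.zeros(N_PAR)
        pt = effective_pair_properties(
            material, tooth_material, self.radius, restitution=p.restitution
        )
        pp = effective_pair_properties(
            material, material, self.radius, self.radius, restitution=p.restitution
        )
        par[PT_KHZ] = (4.0 / 3.0) * pt.eq_elastic_modulus * math.sqrt(pt.eq_radius)
        par[PT_SN] = 2.0 * pt.eq_elastic_modulus * math.sqrt(pt.eq_radius)
        par[PT_KT] = 8.0 * pt.eq_shear_modulus * math.sqrt(pt.eq_radius)
        par[PT_BETA] = abs(pt.damping_ratio)
        par[PT_MU] = p.friction
        par[PP_KHZ] = (4.0 / 3.0) * pp.eq_elastic_modulus * math.sqrt(pp.eq_radius)
        par[PP_SN] = 2.0 * pp.eq_elastic_modulus * math.sqrt(pp.eq_radius)
        par[PP_KT] = 8.0 * pp.eq_shear_modulus * math.sqrt(pp.eq_radius)
        par[PP_BETA] = abs(pp.damping_ratio)
        par[PP_MU] = p.friction
        par[PP_DSUM] = 2.0 * self.radius
        if teeth is not None:
            par[G_XGL] = teeth.groove_left
            par[G_XGR] = teeth.groove_right
            par[G_DEPTH] = teeth.groove_depth
            par[G_XLO], par[G_XHI] = teeth.surface_x
            par[G_XM0], par[G_XM1] = teeth.measured_x
            par[TOOTH_ON] = 1.0
            n_wear_u = int(np.ceil(teeth.unfolded_length / p.wear_cell))
            n_wear_v = int(np.ceil(teeth.plate_height / p.wear_cell))
            if n_wear_v % 2 == 0:  # keep one cell centred on y = 0 (symmetry)
                n_wear_v += 1
            par[G_YHALF] = 0.5 * n_wear_v * p.wear_cell
        par[W_CELL] = p.wear_cell
        par[W_KOH] = p.archard_k / tooth_material.hardness
        if motion is not None:
            par[M_V] = motion.speed
            par[M_L] = motion.stroke
            par[M_ON] = 1.0
            ts1, ts2 = motion.crossing_times()
            par[T_SNAP1], par[T_SNAP2] = ts1, ts2
        else:
            par[T_SNAP1] = par[T_SNAP2] = -1.0
        par[BG_GAMMA] = p.gamma_bg
        par[GRAV_Z] = -9.81 if p.gravity else 0.0
        par[SNAP_WIN] = p.snap_window
        par[TORSION_ON] = 1.0 if p.torsion else 0.0
        par[TOR_KT] = torsion_kt
        par[TOR_GAMMA0] = 0.0
        par[TOR_IINV] = 1.0 / (0.4 * float(np.min(self.mass)) * self.radius**2)
        self.par = par

        self.dt = dt if dt is not None else self._default_dt()

        # tangential histories
        self.tan_hist = np.zeros((n, 7, 3))
        self.tan_act = np.zeros((n, 7), dtype=np.int8)
        self.pairs = np.zeros((0, 2), dtype=np.int64)
        self.pair_hist = np.zeros((0, 3))
        self._pair_steps_left = 0
        self._bonded = {(int(i), int(j)) for i, j in self.bonds}

        # wear + diagnostics
        self.work_grid = np.zeros((n_wear_u, n_wear_v))
        self.dropped = np.zeros(1)
        self.tip_idx = (
            np.array(tip_indices, dtype=np.int64)
            if tip_indices is not None
            else np.arange(n, dtype=np.int64)
        )
        ntip = len(self.tip_idx)
        self.tip_groove_max = np.zeros(ntip)
        self.snap_done = np.zeros(2, dtype=np.int8)
        self.snap_mean = np.zeros(2)
        self.snap_count = np.zeros(2, dtype=np.int64)
        self.snap_groove_max = np.zeros(2)
        self.snap_tip_f = np.zeros((2, ntip))
        self.snap_tip_fn = np.zeros((2, ntip))
        self.snap_tip_ft = np.zeros((2, ntip))
        self.snap_tip_x = np.zeros((2, ntip))
        self.snap_tip_y = np.zeros((2, ntip))
        self.snap_win_max = np.zeros((2, ntip))
        self.log_next = np.zeros(1, dtype=np.int64)
        self.log_t = np.zeros(max_log_rows)
        self.log_s = np.zeros(max_log_rows)
        self.log_ke = np.zeros(max_log_rows)
        self.log_fn = np.zeros((max_log_rows, ntip))
        self.log_ft = np.zeros((max_log_rows, ntip))
        self._tfv = np.zeros((n, 3))
        self._tn = np.zeros(n)
        self._tt = np.zeros(n)
        self.stats = np.zeros(5)

    # -- construction ---------------------------------------------------------
    @classmethod
    def from_assembly(
        cls,
        assembly: BrushAssembly,
        teeth: Optional[ToothModel],
        motion: Optional[MotionProfile],
        params: EngineParams = None,
        dt: Optional[float] = None,
        tooth_material: Material = ENAMEL,
        max_log_rows: int = 20_000,
    ) -> "Engine":
        """Build an engine for the full brush over the tooth model; the head
        is placed so the undeformed tip overlap equals the brushing depth
        and the head center starts one L/5 before the groove midline."""
        params = params or EngineParams()
        pos = np.array(assembly.positions)
        if motion is not None and teeth is not None:
            z_head = motion.head_height(assembly.particle_radius, assembly.beam_length)
            pos[:, 2] += z_head
            pos[:, 0] += motion.start_center(teeth.groove_center)
        chain = assembly.chain
        bonds = assembly.bonds()
        joints = assembly.joints()
        eng = cls(
            positions=pos,
            masses=np.full(assembly.n_particles, assembly.particle_mass),
            radius=assembly.particle_radius,
            clamped=assembly.clamped,
            bonds=bonds,
            bond_ks=np.full(len(bonds), chain.k_s),
            bond_l0=np.full(len(bonds), chain.l0),
            joints=joints,
            joint_kb=np.full(len(joints), chain.k_bend),
            material=assembly.material,
            teeth=teeth,
            motion=motion,
            tooth_material=tooth_material,
            params=params,
            dt=dt,
            tip_indices=assembly.tip_indices,
            torsion_kt=chain.k_t,
            max_log_rows=max_log_rows,
        )
        eng.assembly = assembly
        return eng

    def _default_dt(self) -> float:
        k_max = float(np.max(self.bond_ks)) if len(self.bond_ks) else 0.0
        delta = self.motion.depth if self.motion is not None else 0.1 * self.radius
        k_hz = self.par[PT_SN] * math.sqrt(max(delta, 0.1 * self.radius))
        k_max = max(k_max, k_hz, 1e-30)
        m_min = float(np.min(self.mass))
        return self.params.dt_safety * 2.0 * math.sqrt(m_min / k_max)

    # -- pair list -------------------------------------------------------------
    def _rebuild_pairs(self) -> None:
        if not self.params.pair_contacts or self.n < 2:
            self.pairs = np.zeros((0, 2), dtype=np.int64)
            self.pair_hist = np.zeros((0, 3))
            self._pair_steps_left = 10**9
            return
        cutoff = 2.0 * self.radius + self.params.verlet_skin
        tree = cKDTree(self.pos)
        cand = tree.query_pairs(cutoff, output_type="ndarray")
        keep = []
        for i, j in cand:
            i, j = int(i), int(j)
            if (i, j) in self._bonded or (j, i) in self._bonded:
                continue
            if self.clamped[i] == 1 and self.clamped[j] == 1:
                continue
            keep.append((i, j))
        new_pairs = np.array(keep, dtype=np.int64).reshape(-1, 2)
        new_hist = np.zeros((len(new_pairs), 3))
        if len(self.pairs) and len(new_pairs):
            old_keys = self.pairs[:, 0] * self.n + self.pairs[:, 1]
            new_keys = new_pairs[:, 0] * self.n + new_pairs[:, 1]
            order = np.argsort(old_keys)
            idx = np.searchsorted(old_keys[order], new_keys)
            idx = np.clip(idx, 0, len(old_keys) - 1)
            match = old_keys[order][idx] == new_keys
            new_hist[match] = self.pair_hist[order[idx[match]]]
        self.pairs = new_pairs
        self.pair_hist = new_hist
        v_now = float(np.max(np.abs(self.vel))) if self.n else 0.0
        vmax = max(self.stats[0], abs(self.par[M_V]), v_now)
        if vmax > 0:
            horizon = self.params.verlet_skin / (4.0 * vmax * self.dt)
            self._pair_steps_left = int(min(max(horizon, 50.0), 5000.0))
        else:
            self._pair_steps_left = 5000

    # -- stepping ---------------------------------------------------------------
    def step(self, n_steps: int = 1) -> None:
        """Advance ``n_steps`` explicit steps (deterministic)."""
        remaining = int(n_steps)
        while remaining > 0:
            if self._pair_steps_left <= 0:
                self._rebuild_pairs()
            chunk = max(min(remaining, self._pair_steps_left), 1)
            abort = _run_chunk(
                chunk,
                self.step_count,
                self.t,
                self.dt,
                self.par,
                self.pos,
                self.vel,
                self.frc,
                self.mass,
                self.inv_mass,
                self.fext,
                self.clamped,
                self.anchor0,
                self.bonds,
                self.bond_ks,
                self.bond_l0,
                self.bond_twist,
                self.spin,
                self.joints,
                self.joint_kb,
                self.pairs,
                self.pair_hist,
                self.tan_hist,
                self.tan_act,
                self.radius,
                self.work_grid,
                self.dropped,
                self.tip_idx,
                self.tip_groove_max,
                self.snap_done,
                self.snap_mean,
                self.snap_count,
                self.snap_groove_max,
                self.snap_tip_f,
                self.snap_tip_fn,
                self.snap_tip_ft,
                self.snap_tip_x,
                self.snap_tip_y,
                self.snap_win_max,
                self.log_next,
                self.log_t,
                self.log_s,
                self.log_ke,
                self.log_fn,
                self.log_ft,
                self.params.log_stride,
                self._tfv,
                self._tn,
                self._tt,
                self.stats,
            )
            if abort != _ABORT_OK:
                who = int(self.stats[4])
                raise RuntimeError(
                    f"simulation aborted at step {abort}: "
                    + (
                        "non-finite kinetic energy"
                        if who == -2
                        else f"degenerate bond at particle {who}"
                    )
                )
            self.t = self.stats[3]
            self.step_count += chunk
            self._pair_steps_left -= chunk
            remaining -= chunk

    def run_until(self, t_end: float) -> None:
        n = int(math.ceil((t_end - self.t) / self.dt - 1e-9))
        if n > 0:
            self.step(n)

    def relax_static(
        self,
        tol_speed: float = 1.0e-5,
        tol_force: float = 1.0e-4,
        max_steps: int = 2_000_000,
        gamma: float = 2.0e4,
        ramp_steps: int = 5000,
        check_every: int = 2000,
    ) -> int:
        """Damped quasi-static relaxation under the current external loads.

        Integrates with strong mass-proportional viscous damping ``gamma``
        until the maximum free-particle speed and net-force residual fall
        below the tolerances; the external load is ramped linearly over
        ``ramp_steps`` to avoid a violent transient.  Returns the number of
        steps taken; raises if the residuals do not converge.
        """
        gamma_save = self.par[BG_GAMMA]
        motion_save = self.par[M_ON]
        self.par[BG_GAMMA] = gamma
        self.par[M_ON] = 0.0
        target = np.array(self.fext)
        done = 0
        try:
            while done < ramp_steps:
                frac = min(1.0, (done + check_every) / max(ramp_steps, 1))
                self.fext[:] = target * frac
                self.step(check_every)
                done += check_every
            self.fext[:] = target
            while done < max_steps:
                self.step(check_every)
                done += check_every
                if self.stats[0] < tol_speed and self.stats[1] < tol_force:
                    return done
            raise RuntimeError(
                f"relax_static did not converge in {max_steps} steps: "
                f"max speed {self.stats[0]:.3e} m/s, residual {self.stats[1]:.3e} N"
            )
        finally:
            self.par[BG_GAMMA] = gamma_save
            self.par[M_ON] = motion_save
            self.fext[:] = target

    # -- outputs ---------------------------------------------------------------
    @property
    def kinetic_energy(self) -> float:
        free = self.clamped == 0
        v2 = np.sum(self.vel[free] ** 2, axis=1)
        return float(0.5 * np.sum(self.mass[free] * v2))

    def log_frames(self) -> dict:
        nrow = int(self.log_next[0])
        return {
            "t": self.log_t[:nrow].copy(),
            "s": self.log_s[:nrow].copy(),
            "ke": self.log_ke[:nrow].copy(),
            "tip_fn": self.log_fn[:nrow].copy(),
            "tip_ft": self.log_ft[:nrow].copy(),
        }
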