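"""Compiled simulation core.

One call to :func:`simulate_cell` runs a single cell from bud emergence to
nuclear migration (or the cutoff) with Euler integration of the overdamped
equations of motion at a fixed step.  The kernel works exclusively in a
(um, pN, s) unit system; :func:`mitosim.runner.run_cell` converts the user
parameter set (Table-unit speeds and frequencies) into the flat vector
consumed here and interprets the outputs.

The physics mirrors the module-level operations (`microtubule`, `cortex`,
`spindle`, `integrator`); the flat-array form exists purely so numba can
compile the inner loop.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .microtubule import load_modulation

# -- parameter-vector layout (all seconds / um / pN) -----------------------
P_R = 0          # mother radius
P_RNUC = 1
P_RSPB = 2
P_RKT = 3
P_KCOR = 4
P_ETACYT = 5
P_ETANU = 6
P_ETANE = 7
P_VG = 8         # um/s
P_VS = 9         # um/s
P_FC = 10        # 1/s (cell-resolved catastrophe frequency)
P_FR = 11        # 1/s
P_FCSTALL = 12   # 1/s
P_FSTALL = 13    # pN
P_FDYN = 14
P_LAMDYN = 15
P_LAMIP = 16
P_FK5 = 17
P_KCOH = 18
P_KC = 19
P_KFIB = 20
P_CREP = 21
P_FWALL = 22
P_WCOR = 23
P_DT = 24        # s
P_HKMT = 25      # 1/(s um)
P_LAMBIM = 26
P_FBI = 27       # final budding index
P_TGROW = 28     # s, bud growth duration
P_BLC = 29       # um, bias length constant
P_LREF = 30      # um, wild-type reference mean cMT length
P_PATCH = 31     # daughter patch multiplier
P_REST = 32      # daughter background multiplier
P_PATCHCOS = 33  # cos of the apex-cap polar angle
P_NECKFRAC = 34
P_SINSLIDE = 35  # sin of the sliding-incidence threshold
P_KAPPA = 36     # pN um^2
P_MOTHERMULT = 37
P_BCELL = 38     # per-cell bias scale B in [0, 1]
P_CUTOFF = 39    # s
P_MIGTH = 40     # um past the septin plane
P_SAMPINT = 41   # s
P_NCMT = 42      # cMTs per MTOC body
P_BSCALED = 43   # 1.0 -> B also scales mother dynein
P_RENUC = 44     # um, renucleation length
P_NKT = 45
P_NCMTSPB = 46   # cMTs per SPB after duplication
P_TENG = 47      # s, Bim1/dynein plus-end recruitment time at the cortex
P_ASEP = 48      # um, maximum septin-ring (neck constriction) radius
P_KSEP = 49      # pN/um, stiffness of the septum constriction
NPARAMS = 50

#: status codes
OK = 0
UNSTABLE = 1

_L_GAP_CAP = 0.2      # um, kMT-KT connector spring cap
BIAS_TRANSMISSION = 0.1   # fraction of the tip bias force reaching the anchor
_TETHER_CAP = 0.3     # um, pre-duplication KT tether stretch cap
_K_TETHER = 1.0       # pN/um, soft pre-duplication KT-MTOC tether


@njit(cache=True, inline="always")
def _norm3(x, y, z):
    return math.sqrt(x * x + y * y + z * z)


@njit(cache=True)
def _rand_unit():
    while True:
        x = np.random.normal()
        y = np.random.normal()
        z = np.random.normal()
        n = _norm3(x, y, z)
        if n > 1e-12:
            return x / n, y / n, z / n


@njit(cache=True)
def simulate_cell(p, e_bud, nuc0, mtoc0, contain_dirs, seed):  # noqa: C901
    """Run one cell; returns times, diagnostics and sampled trajectories."""
    np.random.seed(seed)

    R = p[P_R]
    r_nuc = p[P_RNUC]
    r_kt = p[P_RKT]
    k_cor = p[P_KCOR]
    v_g = p[P_VG]
    v_s = p[P_VS]
    f_c0 = p[P_FC]
    f_r = p[P_FR]
    f_c_stall = p[P_FCSTALL]
    f_stall = p[P_FSTALL]
    f_dyn = p[P_FDYN]
    lam_dyn = p[P_LAMDYN]
    w_cor = p[P_WCOR]
    dt = p[P_DT]
    lam_bim = p[P_LAMBIM]
    neck_frac = p[P_NECKFRAC]
    sin_slide = p[P_SINSLIDE]
    kappa = p[P_KAPPA]
    cutoff = p[P_CUTOFF]
    renuc_len = p[P_RENUC]

    n = int(p[P_NKT])
    m = int(p[P_NCMT])
    m_spb = int(p[P_NCMTSPB])
    n_mt = n * m
    n_mt_max = max(n_mt, 2 * m_spb)
    ndirs = contain_dirs.shape[0]

    xi_nuc = 6.0 * math.pi * p[P_ETACYT] * r_nuc
    xi_kt = 6.0 * math.pi * p[P_ETANU] * r_kt

    # -- state ---------------------------------------------------------
    nuc = nuc0.copy()
    body_pos = mtoc0.copy()
    body_rad = np.full(n, p[P_RSPB])
    body_act = np.ones(n, np.uint8)
    body_nf = np.ones(n, np.int64)
    n_active = n

    mt_anchor = np.zeros(n_mt_max, np.int64)
    mt_dir = np.empty((n_mt_max, 3))
    mt_len = np.full(n_mt_max, renuc_len)
    mt_grow = np.ones(n_mt_max, np.uint8)
    mt_slide = np.zeros(n_mt_max, np.uint8)
    mt_dwell = np.zeros(n_mt_max)
    mt_on = np.zeros(n_mt_max, np.uint8)
    mt_on[:n_mt] = 1
    for k in range(n_mt):
        b = k // m
        mt_anchor[k] = b
        ux, uy, uz = _rand_unit()
        nx = (body_pos[b, 0] - nuc[0]) / r_nuc
        ny = (body_pos[b, 1] - nuc[1]) / r_nuc
        nz = (body_pos[b, 2] - nuc[2]) / r_nuc
        d = ux * nx + uy * ny + uz * nz
        if d < 0.0:
            ux -= 2.0 * d * nx
            uy -= 2.0 * d * ny
            uz -= 2.0 * d * nz
        mt_dir[k, 0] = ux
        mt_dir[k, 1] = uy
        mt_dir[k, 2] = uz

    kt_pos = np.empty((n, 3))
    kt_body = np.arange(n)
    for i in range(n):
        for c in range(3):
            kt_pos[i, c] = nuc[c] + (body_pos[i, c] - nuc[c]) * (
                (r_nuc - 2.0 * r_kt) / r_nuc
            )

    duplicated = False
    kmt_len = np.zeros(n)
    kmt_grow = np.ones(n, np.uint8)
    kmt_att = np.zeros(n, np.uint8)
    kmt_spb = np.zeros(n, np.int64)
    ip_len = np.full(4, 0.1)
    ip_grow = np.ones(4, np.uint8)

    # -- outputs -------------------------------------------------------
    clustering_t = -1.0
    migration_t = -1.0
    fusion_t = np.full(max(n - 1, 1), -1.0)
    fusion_nrem = np.zeros(max(n - 1, 1), np.int64)
    n_fus = 0
    n_samp_max = int(cutoff / p[P_SAMPINT]) + 2
    samp_t = np.full(n_samp_max, np.nan)
    samp_neck = np.full(n_samp_max, np.nan)
    samp_nbod = np.zeros(n_samp_max, np.int64)
    samp_mlen = np.full(n_samp_max, np.nan)
    samp_spb = np.full(n_samp_max, np.nan)
    samp_ndau = np.zeros(n_samp_max, np.int64)
    samp_fax = np.full(n_samp_max, np.nan)
    n_samp = 0
    max_ne_res = 0.0
    status = OK

    cum_len = 0.0
    cum_cnt = 0.0

    if n_active == 1 and clustering_t < 0.0:
        clustering_t = 0.0

    F_body = np.zeros((n, 3))
    F_kt = np.zeros((n, 3))
    F_nuc = np.zeros(3)

    # abort only on true divergence; collective dynein pulls on the
    # low-drag SPBs legitimately exceed the strict 0.1*r_spb bound
    disp_bound = p[P_RSPB]
    max_steps = int(cutoff / dt) + 1
    next_samp = 0.0

    for it in range(max_steps):
        t = it * dt

        # geometry of the moment
        frac = t / p[P_TGROW]
        if frac > 1.0:
            frac = 1.0
        r_bud = R * p[P_FBI] * frac
        if r_bud > 1e-9:
            a_neck = neck_frac * r_bud
            x_pl = math.sqrt(R * R - a_neck * a_neck)
            d_bud = x_pl + math.sqrt(r_bud * r_bud - a_neck * a_neck)
        else:
            a_neck = 0.0
            x_pl = R
            d_bud = R
        cbx = d_bud * e_bud[0]
        cby = d_bud * e_bud[1]
        cbz = d_bud * e_bud[2]

        B = p[P_BCELL]
        t_eng = p[P_TENG]
        # cortical motor copy number builds up as the bud grows
        acc = frac * math.sqrt(frac)
        # the sliding direction of a cortex-tracking tip is set by the
        # competition between ring-directed Bim1 and isotropically anchored
        # dynein at the plus end
        lam_mother = lam_dyn * p[P_MOTHERMULT]
        beta = 0.0
        if lam_bim + lam_mother > 0.0:
            beta = lam_bim / (lam_bim + lam_mother)
        beta *= B

        for c in range(3):
            F_nuc[c] = 0.0
        for i in range(n):
            for c in range(3):
                F_body[i, c] = 0.0
                F_kt[i, c] = 0.0

        # ---------------- cytoplasmic MTs -----------------------------
        n_dau_engaged = 0
        dbg_dau_lseg = 0.0
        dbg_dau_mat = 0.0
        for k in range(n_mt_max):
            if mt_on[k] == 0:
                continue
            b = mt_anchor[k]
            ax = body_pos[b, 0]
            ay = body_pos[b, 1]
            az = body_pos[b, 2]
            ux = mt_dir[k, 0]
            uy = mt_dir[k, 1]
            uz = mt_dir[k, 2]
            L = mt_len[k]
            tx = ax + L * ux
            ty = ay + L * uy
            tz = az + L * uz

            rm = _norm3(tx, ty, tz)
            depth_m = R - rm
            if r_bud > 1e-9:
                rb = _norm3(tx - cbx, ty - cby, tz - cbz)
                depth_b = r_bud - rb
            else:
                rb = 1.0
                depth_b = -1e30

            pinned = False
            if depth_m < 0.0 and depth_b < 0.0:
                # clamp length to the exit of the connected in-cell interval
                qb = ax * ux + ay * uy + az * uz
                qc = ax * ax + ay * ay + az * az - R * R
                disc = qb * qb - qc
                m0 = 1e30
                m1 = -1e30
                if disc > 0.0:
                    sq = math.sqrt(disc)
                    m0 = -qb - sq
                    m1 = -qb + sq
                b0 = 1e30
                b1 = -1e30
                if r_bud > 1e-9:
                    wx = ax - cbx
                    wy = ay - cby
                    wz = az - cbz
                    qb2 = wx * ux + wy * uy + wz * uz
                    qc2 = wx * wx + wy * wy + wz * wz - r_bud * r_bud
                    disc2 = qb2 * qb2 - qc2
                    if disc2 > 0.0:
                        sq2 = math.sqrt(disc2)
                        b0 = -qb2 - sq2
                        b1 = -qb2 + sq2
                # the anchor (s=0) lies in at least one interval
                if m0 <= 0.0 <= m1:
                    s_exit = m1
                    if b0 <= s_exit + 1e-9 and b1 > s_exit:
                        s_exit = b1
                elif b0 <= 0.0 <= b1:
                    s_exit = b1
                    if m0 <= s_exit + 1e-9 and m1 > s_exit:
                        s_exit = m1
                else:
                    s_exit = 1e-6
                if s_exit < 1e-6:
                    s_exit = 1e-6
                if L > s_exit:
                    L = s_exit
                    pinned = True
                tx = ax + L * ux
                ty = ay + L * uy
                tz = az + L * uz
                rm = _norm3(tx, ty, tz)
                depth_m = R - rm
                if r_bud > 1e-9:
                    rb = _norm3(tx - cbx, ty - cby, tz - cbz)
                    depth_b = r_bud - rb

            use_bud = depth_b > depth_m
            depth = depth_b if use_bud else depth_m
            if use_bud:
                nox = (tx - cbx) / rb
                noy = (ty - cby) / rb
                noz = (tz - cbz) / rb
            else:
                nox = tx / rm
                noy = ty / rm
                noz = tz / rm

            l_cor = 0.0
            l_seg = 0.0
            if 0.0 <= depth < w_cor:
                # tip penetration depth (bounded by the shell width) ...
                l_cor = w_cor - depth
                if l_cor > L:
                    l_cor = L
                # ... and the rod segment lying inside the shell, which the
                # cortex-anchored dynein motors decorate
                ri = (r_bud if use_bud else R) - w_cor
                if use_bud:
                    qx = ax - cbx
                    qy = ay - cby
                    qz = az - cbz
                else:
                    qx = ax
                    qy = ay
                    qz = az
                qb3 = qx * ux + qy * uy + qz * uz
                qc3 = qx * qx + qy * qy + qz * qz - ri * ri
                disc3 = qb3 * qb3 - qc3
                if disc3 > 0.0:
                    l_seg = L - (-qb3 + math.sqrt(disc3))
                    if l_seg < l_cor:
                        l_seg = l_cor
                    if l_seg > L:
                        l_seg = L
                else:
                    l_seg = L
                if l_seg > 1.5:
                    l_seg = 1.5
            # Bim1 and dynein accumulate at a plus end while it dwells in
            # the cortex; motor forces ramp in over the recruitment time
            if l_cor > 0.0:
                mt_dwell[k] += dt
            else:
                mt_dwell[k] = 0.0
            mat = acc * mt_dwell[k] / t_eng
            if mat > acc:
                mat = acc
            axial = tx * e_bud[0] + ty * e_bud[1] + tz * e_bud[2]
            in_daughter = axial > x_pl
            if in_daughter and l_cor > 0.0:
                n_dau_engaged += 1

            # local dynein density at the tip (daughter-cortex pull only
            # after SPB duplication, with the condensed apex patch)
            lam_eff = 0.0
            pull_mag = 0.0
            if l_cor > 0.0:
                if in_daughter:
                    if duplicated:
                        ubx = (tx - cbx) / rb
                        uby = (ty - cby) / rb
                        ubz = (tz - cbz) / rb
                        capdot = (
                            ubx * e_bud[0] + uby * e_bud[1] + ubz * e_bud[2]
                        )
                        mult = p[P_PATCH] if capdot > p[P_PATCHCOS] else p[P_REST]
                    else:
                        mult = 0.0
                    lam_eff = lam_dyn * mult
                else:
                    lam_eff = lam_dyn * p[P_MOTHERMULT]
                    if p[P_BSCALED] > 0.5:
                        lam_eff *= B
                pull_mag = mat * l_seg * lam_eff * f_dyn

            f_load = k_cor * l_cor
            f_buck = 0.0
            wall_hit = False

            if mt_grow[k] == 1:
                if pinned:
                    cosn = abs(ux * nox + uy * noy + uz * noz)
                    if cosn < sin_slide or mt_slide[k] == 1:
                        # sliding: the tip tracks the cortex surface (through
                        # the neck into the daughter when it reaches the
                        # ring), Bim1-biased while in the mother
                        mt_slide[k] = 1
                        dgx = ux - (ux * nox + uy * noy + uz * noz) * nox
                        dgy = uy - (ux * nox + uy * noy + uz * noz) * noy
                        dgz = uz - (ux * nox + uy * noy + uz * noz) * noz
                        gn = _norm3(dgx, dgy, dgz)
                        if gn > 1e-9:
                            dgx /= gn
                            dgy /= gn
                            dgz /= gn
                        if (not in_daughter) and lam_bim > 0.0 and beta * mat > 0.0:
                            trx, try_, trz, ringd = _ring_tangent(
                                tx, ty, tz, nox, noy, noz, e_bud, x_pl, a_neck
                            )
                            if ringd < 0.15:
                                # at the ring: carry on across the neck
                                trx = dgx
                                try_ = dgy
                                trz = dgz
                            bm = beta * mat
                            dgx = (1.0 - bm) * dgx + bm * trx
                            dgy = (1.0 - bm) * dgy + bm * try_
                            dgz = (1.0 - bm) * dgz + bm * trz
                            gn = _norm3(dgx, dgy, dgz)
                            if gn > 1e-9:
                                dgx /= gn
                                dgy /= gn
                                dgz /= gn
                        f_net = f_load - pull_mag
                        if f_net < -f_stall:
                            f_net = -f_stall
                        vg_eff, fce = load_modulation(
                            v_g, f_c0, f_c_stall, f_stall, f_net
                        )
                        if vg_eff > v_g:
                            vg_eff = v_g
                        ntx = tx + vg_eff * dt * dgx
                        nty = ty + vg_eff * dt * dgy
                        ntz = tz + vg_eff * dt * dgz
                        # keep the tip just inside the containing sphere
                        if use_bud:
                            qx = ntx - cbx
                            qy = nty - cby
                            qz = ntz - cbz
                            qn = _norm3(qx, qy, qz)
                            sc = (r_bud - 1e-4) / qn
                            ntx = cbx + qx * sc
                            nty = cby + qy * sc
                            ntz = cbz + qz * sc
                        else:
                            qn = _norm3(ntx, nty, ntz)
                            sc = (R - 1e-4) / qn
                            ntx *= sc
                            nty *= sc
                            ntz *= sc
                        ux = ntx - ax
                        uy = nty - ay
                        uz = ntz - az
                        L = _norm3(ux, uy, uz)
                        ux /= L
                        uy /= L
                        uz /= L
                        if np.random.random() < 1.0 - math.exp(-fce * dt):
                            mt_grow[k] = 0
                            mt_slide[k] = 0
                            wall_hit = True
                    else:
                        # stalled against the wall: the transmitted
                        # compression saturates at the weaker of the combined
                        # elastic + first-order buckling (pi^2 kappa / L^2)
                        # response and the polymerisation stall force -- a
                        # tip cannot push harder than it can grow.
                        f_comp = k_cor * l_cor + math.pi * math.pi * kappa / (L * L)
                        if f_comp > f_stall:
                            f_comp = f_stall
                        # force assembly subtracts k_cor*l_cor + f_buck
                        f_buck = f_comp - k_cor * l_cor
                        f_load = f_comp
                        f_net = f_load - pull_mag
                        if f_net < -f_stall:
                            f_net = -f_stall
                        vg_eff, fce = load_modulation(
                            v_g, f_c0, f_c_stall, f_stall, f_net
                        )
                        if np.random.random() < 1.0 - math.exp(-fce * dt):
                            mt_grow[k] = 0
                            mt_slide[k] = 0
                            wall_hit = True
                else:
                    f_net = f_load - pull_mag
                    if f_net < -f_stall:
                        f_net = -f_stall
                    vg_eff, fce = load_modulation(
                        v_g, f_c0, f_c_stall, f_stall, f_net
                    )
                    if vg_eff > v_g:
                        vg_eff = v_g
                    L += vg_eff * dt
                    if np.random.random() < 1.0 - math.exp(-fce * dt):
                        mt_grow[k] = 0
                        mt_slide[k] = 0
                    elif l_cor > 0.0 and (not in_daughter) and lam_bim > 0.0 and B > 0.0:
                        # Bim1 drags the cortex-dwelling tip toward the ring;
                        # tip mobility of a slender rod pivoting about its
                        # anchor: xi_tip = c_perp * L / 3 with
                        # c_perp = 4 pi eta / ln(L/d) (log factor ~5)
                        fb = mat * B * l_cor * lam_bim * f_dyn
                        xi_rod = (4.0 * math.pi * p[P_ETACYT] / 5.0) * max(L, 0.5) / 3.0
                        trx, try_, trz, _rd = _ring_tangent(
                            tx, ty, tz, nox, noy, noz, e_bud, x_pl, a_neck
                        )
                        step = fb / xi_rod * dt
                        ntx = tx + step * trx
                        nty = ty + step * try_
                        ntz = tz + step * trz
                        ux = ntx - ax
                        uy = nty - ay
                        uz = ntz - az
                        un = _norm3(ux, uy, uz)
                        ux /= un
                        uy /= un
                        uz /= un
            else:
                L -= v_s * dt
                if L <= renuc_len:
                    nx = (ax - nuc[0]) / r_nuc
                    ny = (ay - nuc[1]) / r_nuc
                    nz = (az - nuc[2]) / r_nuc
                    ux, uy, uz = _rand_unit()
                    dd = ux * nx + uy * ny + uz * nz
                    if dd < 0.0:
                        ux -= 2.0 * dd * nx
                        uy -= 2.0 * dd * ny
                        uz -= 2.0 * dd * nz
                    L = renuc_len
                    mt_grow[k] = 1
                    mt_slide[k] = 0
                    mt_dwell[k] = 0.0
                    l_cor = 0.0
                    f_load = 0.0
                elif np.random.random() < 1.0 - math.exp(-f_r * dt):
                    mt_grow[k] = 1

            mt_dir[k, 0] = ux
            mt_dir[k, 1] = uy
            mt_dir[k, 2] = uz
            mt_len[k] = L
            cum_len += L
            cum_cnt += 1.0

            # cortical forces: axial resultant on the anchor and nucleus
            if l_cor > 0.0 or wall_hit or f_buck > 0.0:
                f_ax = pull_mag - l_cor * k_cor - f_buck
                if wall_hit:
                    f_ax -= p[P_FWALL]
                F_nuc[0] += f_ax * ux
                F_nuc[1] += f_ax * uy
                F_nuc[2] += f_ax * uz
                F_body[b, 0] += f_ax * ux
                F_body[b, 1] += f_ax * uy
                F_body[b, 2] += f_ax * uz
                # Bim1 bias at the plus end: mostly steers the rod (handled
                # in the growth update); the fraction transmitted down the
                # pivoting rod to the anchor and nucleus is small
                if (
                    mt_grow[k] == 1
                    and l_cor > 0.0
                    and (not in_daughter)
                    and lam_bim > 0.0
                    and B > 0.0
                ):
                    fb = BIAS_TRANSMISSION * mat * B * l_cor * lam_bim * f_dyn
                    trx, try_, trz, _rd = _ring_tangent(
                        tx, ty, tz, nox, noy, noz, e_bud, x_pl, a_neck
                    )
                    F_nuc[0] += fb * trx
                    F_nuc[1] += fb * try_
                    F_nuc[2] += fb * trz
                    F_body[b, 0] += fb * trx
                    F_body[b, 1] += fb * try_
                    F_body[b, 2] += fb * trz

        # ---------------- nucleus containment -------------------------
        for j in range(ndirs):
            dx = contain_dirs[j, 0]
            dy = contain_dirs[j, 1]
            dz = contain_dirs[j, 2]
            px = nuc[0] + r_nuc * dx
            py = nuc[1] + r_nuc * dy
            pz = nuc[2] + r_nuc * dz
            vm = _norm3(px, py, pz) - R
            if r_bud > 1e-9:
                vb = _norm3(px - cbx, py - cby, pz - cbz) - r_bud
            else:
                vb = 1e30
            viol = vm if vm < vb else vb
            if viol > 0.0:
                # the factor compensates the sparse surface sampling; the
                # wall is only numerically soft, so squeezing through the
                # neck needs a genuine sustained pull from the far side
                F_nuc[0] -= 10.0 * k_cor * viol * dx
                F_nuc[1] -= 10.0 * k_cor * viol * dy
                F_nuc[2] -= 10.0 * k_cor * viol * dz

        # septum constriction: the nucleus crosses the neck only through
        # the septin ring; its cross-section in the septin plane must fit
        # inside the ring of radius a_sep
        a_sep = a_neck if a_neck < p[P_ASEP] else p[P_ASEP]
        ca = (
            nuc[0] * e_bud[0] + nuc[1] * e_bud[1] + nuc[2] * e_bud[2]
        ) - x_pl
        if p[P_KSEP] > 1e-9 and abs(ca) < r_nuc and a_sep > 1e-9:
            rc = math.sqrt(r_nuc * r_nuc - ca * ca)
            rhx = nuc[0] - (ca + x_pl) * e_bud[0]
            rhy = nuc[1] - (ca + x_pl) * e_bud[1]
            rhz = nuc[2] - (ca + x_pl) * e_bud[2]
            rho_c = _norm3(rhx, rhy, rhz)
            v_sep = rho_c + rc - a_sep
            # the penalty cannot exceed how deeply the nucleus actually
            # pokes through the septin plane
            poke = r_nuc - abs(ca)
            if v_sep > poke:
                v_sep = poke
            if v_sep > 0.0:
                k_sep = p[P_KSEP]
                if rho_c > 1e-9:
                    F_nuc[0] -= k_sep * v_sep * rhx / rho_c
                    F_nuc[1] -= k_sep * v_sep * rhy / rho_c
                    F_nuc[2] -= k_sep * v_sep * rhz / rho_c
                ax_push = k_sep * v_sep * (ca / rc)
                F_nuc[0] += ax_push * e_bud[0]
                F_nuc[1] += ax_push * e_bud[1]
                F_nuc[2] += ax_push * e_bud[2]

        # ---------------- kinetochores & spindle -----------------------
        if not duplicated:
            scale = (r_nuc - 2.0 * r_kt) / r_nuc
            for i in range(n):
                bidx = kt_body[i]
                tgx = nuc[0] + (body_pos[bidx, 0] - nuc[0]) * scale
                tgy = nuc[1] + (body_pos[bidx, 1] - nuc[1]) * scale
                tgz = nuc[2] + (body_pos[bidx, 2] - nuc[2]) * scale
                ddx = tgx - kt_pos[i, 0]
                ddy = tgy - kt_pos[i, 1]
                ddz = tgz - kt_pos[i, 2]
                dn = _norm3(ddx, ddy, ddz)
                if dn > 1e-12:
                    stretch = dn if dn < _TETHER_CAP else _TETHER_CAP
                    f = _K_TETHER * stretch / dn
                    F_kt[i, 0] += f * ddx
                    F_kt[i, 1] += f * ddy
                    F_kt[i, 2] += f * ddz
                    F_body[bidx, 0] -= f * ddx
                    F_body[bidx, 1] -= f * ddy
                    F_body[bidx, 2] -= f * ddz
        else:
            # SPBs live in body slots 0 and 1
            axx = body_pos[1, 0] - body_pos[0, 0]
            axy = body_pos[1, 1] - body_pos[0, 1]
            axz = body_pos[1, 2] - body_pos[0, 2]
            d_spb = max(_norm3(axx, axy, axz), 1e-9)
            adx = axx / d_spb
            ady = axy / d_spb
            adz = axz / d_spb
            # interpolar MTs: slots 0,1 from pole 0; 2,3 from pole 1
            ov_tot = 0.0
            for q in range(4):
                lcl = ip_len[q]
                if ip_grow[q] == 1:
                    lcl += v_g * dt
                    if lcl > d_spb:
                        lcl = d_spb
                        if np.random.random() < 1.0 - math.exp(-f_c_stall * dt):
                            ip_grow[q] = 0
                    cat = p[P_HKMT] * lcl
                    if np.random.random() < 1.0 - math.exp(-cat * dt):
                        ip_grow[q] = 0
                else:
                    lcl -= v_s * dt
                    if lcl <= 0.05:
                        lcl = 0.05
                        ip_grow[q] = 1
                ip_len[q] = lcl
            for q in range(2):
                ov = ip_len[q] + ip_len[q + 2] - d_spb
                if ov > 0.0:
                    ov_tot += ov
            f_ip = ov_tot * p[P_LAMIP] * p[P_FK5]
            F_body[0, 0] -= f_ip * adx
            F_body[0, 1] -= f_ip * ady
            F_body[0, 2] -= f_ip * adz
            F_body[1, 0] += f_ip * adx
            F_body[1, 1] += f_ip * ady
            F_body[1, 2] += f_ip * adz

            for i in range(n):
                s = kmt_spb[i]
                dvx = kt_pos[i, 0] - body_pos[s, 0]
                dvy = kt_pos[i, 1] - body_pos[s, 1]
                dvz = kt_pos[i, 2] - body_pos[s, 2]
                dist = max(_norm3(dvx, dvy, dvz), 1e-9)
                kx = dvx / dist
                ky = dvy / dist
                kz = dvz / dist
                target = dist - r_kt
                if target < 0.0:
                    target = 0.0
                lk = kmt_len[i]
                if kmt_att[i] == 0:
                    lk += v_g * dt
                    if lk >= target:
                        lk = target
                        kmt_att[i] = 1
                else:
                    if kmt_grow[i] == 1:
                        lk += v_g * dt
                        if lk > dist + r_kt:
                            lk = dist + r_kt
                        cat = p[P_HKMT] * lk
                        if np.random.random() < 1.0 - math.exp(-cat * dt):
                            kmt_grow[i] = 0
                    else:
                        lk -= v_s * dt
                        if lk <= 0.05:
                            lk = 0.05
                            kmt_grow[i] = 1
                        elif np.random.random() < 1.0 - math.exp(-f_r * dt):
                            kmt_grow[i] = 1
                    pen = lk - target
                    if pen > 0.0:
                        if pen > 2.0 * r_kt:
                            pen = 2.0 * r_kt
                        f = p[P_KFIB] * pen
                        F_kt[i, 0] += f * kx
                        F_kt[i, 1] += f * ky
                        F_kt[i, 2] += f * kz
                        F_body[s, 0] -= f * kx
                        F_body[s, 1] -= f * ky
                        F_body[s, 2] -= f * kz
                    else:
                        gap = -pen
                        if gap > _L_GAP_CAP:
                            gap = _L_GAP_CAP
                        f = p[P_KC] * gap
                        F_kt[i, 0] -= f * kx
                        F_kt[i, 1] -= f * ky
                        F_kt[i, 2] -= f * kz
                        F_body[s, 0] += f * kx
                        F_body[s, 1] += f * ky
                        F_body[s, 2] += f * kz
                kmt_len[i] = lk
            # cohesin springs between consecutive sisters
            for a in range(0, n - 1, 2):
                bb = a + 1
                dvx = kt_pos[bb, 0] - kt_pos[a, 0]
                dvy = kt_pos[bb, 1] - kt_pos[a, 1]
                dvz = kt_pos[bb, 2] - kt_pos[a, 2]
                f = p[P_KCOH]
                F_kt[a, 0] += f * dvx
                F_kt[a, 1] += f * dvy
                F_kt[a, 2] += f * dvz
                F_kt[bb, 0] -= f * dvx
                F_kt[bb, 1] -= f * dvy
                F_kt[bb, 2] -= f * dvz

        # KT-KT hard-core repulsion (always)
        for i in range(n):
            for j in range(i + 1, n):
                dvx = kt_pos[i, 0] - kt_pos[j, 0]
                dvy = kt_pos[i, 1] - kt_pos[j, 1]
                dvz = kt_pos[i, 2] - kt_pos[j, 2]
                dist = _norm3(dvx, dvy, dvz)
                ov = 2.0 * r_kt - dist
                if ov > 0.0 and dist > 1e-9:
                    f = p[P_CREP] * ov / dist
                    F_kt[i, 0] += f * dvx
                    F_kt[i, 1] += f * dvy
                    F_kt[i, 2] += f * dvz
                    F_kt[j, 0] -= f * dvx
                    F_kt[j, 1] -= f * dvy
                    F_kt[j, 2] -= f * dvz

        # ---------------- integrate ------------------------------------
        vnx = F_nuc[0] / xi_nuc
        vny = F_nuc[1] / xi_nuc
        vnz = F_nuc[2] / xi_nuc
        dnx = vnx * dt
        dny = vny * dt
        dnz = vnz * dt
        if _norm3(dnx, dny, dnz) > disp_bound:
            print("UNSTABLE nucleus step", it, F_nuc[0], F_nuc[1], F_nuc[2])
            status = UNSTABLE
            break
        nnx = nuc[0] + dnx
        nny = nuc[1] + dny
        nnz = nuc[2] + dnz

        ok = True
        for i in range(n):
            if body_act[i] == 0:
                continue
            xi_b = 6.0 * math.pi * p[P_ETANE] * body_rad[i]
            bdx = F_body[i, 0] / xi_b * dt
            bdy = F_body[i, 1] / xi_b * dt
            bdz = F_body[i, 2] / xi_b * dt
            if _norm3(bdx, bdy, bdz) > disp_bound:
                print("UNSTABLE body", i, "step", it, F_body[i, 0], F_body[i, 1], F_body[i, 2])
                ok = False
                break
            # advect with the nucleus (bodies ride on the NE), then re-project
            rx = body_pos[i, 0] + bdx + dnx - nnx
            ry = body_pos[i, 1] + bdy + dny - nny
            rz = body_pos[i, 2] + bdz + dnz - nnz
            rn = _norm3(rx, ry, rz)
            body_pos[i, 0] = nnx + rx * (r_nuc / rn)
            body_pos[i, 1] = nny + ry * (r_nuc / rn)
            body_pos[i, 2] = nnz + rz * (r_nuc / rn)
            # NE-constraint residual after re-projection
            res = abs(
                _norm3(
                    body_pos[i, 0] - nnx,
                    body_pos[i, 1] - nny,
                    body_pos[i, 2] - nnz,
                )
                - r_nuc
            )
            if res > max_ne_res:
                max_ne_res = res
        if not ok:
            status = UNSTABLE
            break

        for i in range(n):
            kdx = F_kt[i, 0] / xi_kt * dt
            kdy = F_kt[i, 1] / xi_kt * dt
            kdz = F_kt[i, 2] / xi_kt * dt
            rx = kt_pos[i, 0] + kdx + dnx - nnx
            ry = kt_pos[i, 1] + kdy + dny - nny
            rz = kt_pos[i, 2] + kdz + dnz - nnz
            rn = _norm3(rx, ry, rz)
            lim = r_nuc - r_kt
            if rn > lim:
                sc = lim / rn
                rx *= sc
                ry *= sc
                rz *= sc
            kt_pos[i, 0] = nnx + rx
            kt_pos[i, 1] = nny + ry
            kt_pos[i, 2] = nnz + rz

        nuc[0] = nnx
        nuc[1] = nny
        nuc[2] = nnz

        # ---------------- fusion & duplication -------------------------
        if (not duplicated) and n_active > 1:
            merged = True
            while merged and n_active > 1:
                merged = False
                for i in range(n):
                    if body_act[i] == 0:
                        continue
                    for j in range(i + 1, n):
                        if body_act[j] == 0:
                            continue
                        dvx = body_pos[i, 0] - body_pos[j, 0]
                        dvy = body_pos[i, 1] - body_pos[j, 1]
                        dvz = body_pos[i, 2] - body_pos[j, 2]
                        if (
                            _norm3(dvx, dvy, dvz)
                            <= body_rad[i] + body_rad[j] + 1e-3
                        ):
                            vi = body_rad[i] ** 3
                            vj = body_rad[j] ** 3
                            for c in range(3):
                                body_pos[i, c] = (
                                    vi * body_pos[i, c] + vj * body_pos[j, c]
                                ) / (vi + vj)
                            rx = body_pos[i, 0] - nuc[0]
                            ry = body_pos[i, 1] - nuc[1]
                            rz = body_pos[i, 2] - nuc[2]
                            rn = _norm3(rx, ry, rz)
                            body_pos[i, 0] = nuc[0] + rx * (r_nuc / rn)
                            body_pos[i, 1] = nuc[1] + ry * (r_nuc / rn)
                            body_pos[i, 2] = nuc[2] + rz * (r_nuc / rn)
                            body_rad[i] = (vi + vj) ** (1.0 / 3.0)
                            body_nf[i] += body_nf[j]
                            body_act[j] = 0
                            n_active -= 1
                            for k in range(n_mt):
                                if mt_anchor[k] == j:
                                    mt_anchor[k] = i
                            for k in range(n):
                                if kt_body[k] == j:
                                    kt_body[k] = i
                            fusion_t[n_fus] = t
                            fusion_nrem[n_fus] = n_active
                            n_fus += 1
                            merged = True
                            break
                    if merged:
                        break
            if n_active == 1 and clustering_t < 0.0:
                clustering_t = t + dt

        if (not duplicated) and n_active == 1:
            # SPB duplication: split the fused body into two on the NE
            ci = 0
            for i in range(n):
                if body_act[i] == 1:
                    ci = i
                    break
            rx = (body_pos[ci, 0] - nuc[0]) / r_nuc
            ry = (body_pos[ci, 1] - nuc[1]) / r_nuc
            rz = (body_pos[ci, 2] - nuc[2]) / r_nuc
            tx_, ty_, tz_ = _rand_unit()
            dd = tx_ * rx + ty_ * ry + tz_ * rz
            tx_ -= dd * rx
            ty_ -= dd * ry
            tz_ -= dd * rz
            tn = _norm3(tx_, ty_, tz_)
            tx_ /= tn
            ty_ /= tn
            tz_ /= tn
            half_r = body_rad[ci] * 2.0 ** (-1.0 / 3.0)
            nf_tot = body_nf[ci]
            cpos0 = body_pos[ci, 0]
            cpos1 = body_pos[ci, 1]
            cpos2 = body_pos[ci, 2]
            for i in range(n):
                body_act[i] = 0
            for s in range(2):
                sgn = 1.0 if s == 0 else -1.0
                px = cpos0 + sgn * p[P_RSPB] * tx_
                py = cpos1 + sgn * p[P_RSPB] * ty_
                pz = cpos2 + sgn * p[P_RSPB] * tz_
                rx = px - nuc[0]
                ry = py - nuc[1]
                rz = pz - nuc[2]
                rn = _norm3(rx, ry, rz)
                body_pos[s, 0] = nuc[0] + rx * (r_nuc / rn)
                body_pos[s, 1] = nuc[1] + ry * (r_nuc / rn)
                body_pos[s, 2] = nuc[2] + rz * (r_nuc / rn)
                body_rad[s] = half_r
                body_act[s] = 1
                body_nf[s] = nf_tot // 2
            n_active = 2
            for k in range(2 * m_spb):
                was_on = mt_on[k] == 1
                mt_on[k] = 1
                mt_anchor[k] = k % 2
                if not was_on:
                    bsl = k % 2
                    nx = (body_pos[bsl, 0] - nuc[0]) / r_nuc
                    ny = (body_pos[bsl, 1] - nuc[1]) / r_nuc
                    nz = (body_pos[bsl, 2] - nuc[2]) / r_nuc
                    ux, uy, uz = _rand_unit()
                    dd = ux * nx + uy * ny + uz * nz
                    if dd < 0.0:
                        ux -= 2.0 * dd * nx
                        uy -= 2.0 * dd * ny
                        uz -= 2.0 * dd * nz
                    mt_dir[k, 0] = ux
                    mt_dir[k, 1] = uy
                    mt_dir[k, 2] = uz
                    mt_len[k] = renuc_len
                    mt_grow[k] = 1
                    mt_slide[k] = 0
            for k in range(2 * m_spb, n_mt_max):
                mt_on[k] = 0
            for i in range(n):
                d0 = _norm3(
                    kt_pos[i, 0] - body_pos[0, 0],
                    kt_pos[i, 1] - body_pos[0, 1],
                    kt_pos[i, 2] - body_pos[0, 2],
                )
                d1 = _norm3(
                    kt_pos[i, 0] - body_pos[1, 0],
                    kt_pos[i, 1] - body_pos[1, 1],
                    kt_pos[i, 2] - body_pos[1, 2],
                )
                kmt_spb[i] = 0 if d0 <= d1 else 1
            duplicated = True

        # ---------------- observables ----------------------------------
        neck = (
            nuc[0] * e_bud[0] + nuc[1] * e_bud[1] + nuc[2] * e_bud[2]
        ) - x_pl
        if migration_t < 0.0 and neck >= p[P_MIGTH]:
            migration_t = t + dt

        if t >= next_samp:
            mlen = 0.0
            n_on = 0
            for k in range(n_mt_max):
                if mt_on[k] == 1:
                    mlen += mt_len[k]
                    n_on += 1
            mlen /= max(n_on, 1)
            samp_t[n_samp] = t
            samp_neck[n_samp] = neck
            samp_ndau[n_samp] = n_dau_engaged
            samp_fax[n_samp] = (
                F_nuc[0] * e_bud[0] + F_nuc[1] * e_bud[1] + F_nuc[2] * e_bud[2]
            )
            samp_nbod[n_samp] = n_active
            samp_mlen[n_samp] = mlen
            if duplicated:
                samp_spb[n_samp] = _norm3(
                    body_pos[1, 0] - body_pos[0, 0],
                    body_pos[1, 1] - body_pos[0, 1],
                    body_pos[1, 2] - body_pos[0, 2],
                )
            n_samp += 1
            next_samp += p[P_SAMPINT]

        if migration_t >= 0.0 and clustering_t >= 0.0:
            break

    mean_len = cum_len / max(cum_cnt, 1.0)
    final_neck = (
        nuc[0] * e_bud[0] + nuc[1] * e_bud[1] + nuc[2] * e_bud[2]
    ) - x_pl
    return (
        status,
        clustering_t,
        migration_t,
        mean_len,
        fusion_t,
        fusion_nrem,
        n_fus,
        samp_t,
        samp_neck,
        samp_nbod,
        samp_mlen,
        samp_spb,
        samp_ndau,
        samp_fax,
        n_samp,
        max_ne_res,
        nuc,
    )


@njit(cache=True, inline="always")
def _ring_tangent(tx, ty, tz, nox, noy, noz, e_bud, x_pl, a_neck):
    """Unit cortex-tangent toward the septin ring, plus distance to the ring."""
    axial = tx * e_bud[0] + ty * e_bud[1] + tz * e_bud[2]
    rxx = tx - axial * e_bud[0]
    rxy = ty - axial * e_bud[1]
    rxz = tz - axial * e_bud[2]
    rn = _norm3(rxx, rxy, rxz)
    if rn < 1e-9:
        # tip on the axis: any ring point will do
        hx, hy, hz = 1.0, 0.0, 0.0
        if abs(e_bud[0]) > 0.9:
            hx, hy, hz = 0.0, 1.0, 0.0
        rxx = hy * e_bud[2] - hz * e_bud[1]
        rxy = hz * e_bud[0] - hx * e_bud[2]
        rxz = hx * e_bud[1] - hy * e_bud[0]
        rn = _norm3(rxx, rxy, rxz)
    rxx /= rn
    rxy /= rn
    rxz /= rn
    gx = x_pl * e_bud[0] + a_neck * rxx - tx
    gy = x_pl * e_bud[1] + a_neck * rxy - ty
    gz = x_pl * e_bud[2] + a_neck * rxz - tz
    dist = _norm3(gx, gy, gz)
    dd = gx * nox + gy * noy + gz * noz
    gx -= dd * nox
    gy -= dd * noy
    gz -= dd * noz
    gn = _norm3(gx, gy, gz)
    if gn < 1e-9:
        return 0.0, 0.0, 0.0, dist
    return gx / gn, gy / gn, gz / gn, dist
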