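"""Numba kernels for the Monte Carlo engine.

All proposals move a bead subset *rigidly*, so interaction terms fully
inside or fully outside the moved set are unchanged; a move evaluates only
excluded-volume cross terms plus the precomputed boundary bonded/restraint
terms.  Proposal distributions are symmetric, giving plain Metropolis
acceptance min(1, exp(-dE/RT)).
"""

import math

import numpy as np
from numba import njit

# move classes
K_BEAD, K_CRANK, K_SUBTREE, K_PINNED, K_TAPER = 0, 1, 2, 3, 4
N_CLASSES = 5


@njit(cache=True, fastmath=True)
def _dist(coords, i, j):
    dx = coords[i, 0] - coords[j, 0]
    dy = coords[i, 1] - coords[j, 1]
    dz = coords[i, 2] - coords[j, 2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True, fastmath=True)
def _bond_e(coords, bi, bj, r0, k):
    d = _dist(coords, bi, bj) - r0
    return k * d * d


@njit(cache=True, fastmath=True)
def _angle_e(coords, a, b, c, th0, k):
    ux = coords[a, 0] - coords[b, 0]
    uy = coords[a, 1] - coords[b, 1]
    uz = coords[a, 2] - coords[b, 2]
    vx = coords[c, 0] - coords[b, 0]
    vy = coords[c, 1] - coords[b, 1]
    vz = coords[c, 2] - coords[b, 2]
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-12 or nv < 1e-12:
        return 0.0
    cosv = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if cosv > 1.0:
        cosv = 1.0
    elif cosv < -1.0:
        cosv = -1.0
    d = math.acos(cosv) - th0
    return k * d * d


@njit(cache=True, fastmath=True)
def _dihedral_angle(coords, a, b, c, d):
    b0x = coords[b, 0] - coords[a, 0]
    b0y = coords[b, 1] - coords[a, 1]
    b0z = coords[b, 2] - coords[a, 2]
    b1x = coords[c, 0] - coords[b, 0]
    b1y = coords[c, 1] - coords[b, 1]
    b1z = coords[c, 2] - coords[b, 2]
    b2x = coords[d, 0] - coords[c, 0]
    b2y = coords[d, 1] - coords[c, 1]
    b2z = coords[d, 2] - coords[c, 2]
    n1x = b0y * b1z - b0z * b1y
    n1y = b0z * b1x - b0x * b1z
    n1z = b0x * b1y - b0y * b1x
    n2x = b1y * b2z - b1z * b2y
    n2y = b1z * b2x - b1x * b2z
    n2z = b1x * b2y - b1y * b2x
    nb1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    if nb1 < 1e-12:
        return 0.0
    m1x = n1y * b1z - n1z * b1y
    m1y = n1z * b1x - n1x * b1z
    m1z = n1x * b1y - n1y * b1x
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = (m1x * n2x + m1y * n2y + m1z * n2z) / nb1
    return math.atan2(y, x)


@njit(cache=True, fastmath=True)
def _dihedral_e(coords, a, b, c, d, phi0, k):
    return k * (1.0 - math.cos(_dihedral_angle(coords, a, b, c, d) - phi0))


@njit(cache=True, fastmath=True)
def _noe_e(coords, i, j, rmin, rmax, kmin, kmax, fmax):
    r = _dist(coords, i, j)
    if r < rmin:
        s = rmin - r
        k = kmin
    elif r > rmax:
        s = r - rmax
        k = kmax
    else:
        return 0.0
    if k <= 0.0:
        return 0.0
    s_cap = fmax / (2.0 * k)
    if s <= s_cap:
        return k * s * s
    return k * s_cap * s_cap + fmax * (s - s_cap)


@njit(cache=True, fastmath=True)
def _att_e(coords, i, j, eps, r_on, r_off):
    r = _dist(coords, i, j)
    if r <= r_on:
        return -eps
    if r < r_off:
        return -eps * (r_off - r) / (r_off - r_on)
    return 0.0


@njit(cache=True, fastmath=True)
def _ev_pair(coords, radii, i, j, k_ev):
    sig = radii[i] + radii[j]
    dx = coords[i, 0] - coords[j, 0]
    if dx > sig or dx < -sig:
        return 0.0
    dy = coords[i, 1] - coords[j, 1]
    if dy > sig or dy < -sig:
        return 0.0
    dz = coords[i, 2] - coords[j, 2]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= sig * sig:
        return 0.0
    d = sig - math.sqrt(r2)
    return k_ev * d * d


@njit(cache=True, fastmath=True)
def _excluded(excl, i, j):
    for m in range(excl.shape[1]):
        e = excl[i, m]
        if e == -1:
            break
        if e == j:
            return True
    return False


@njit(cache=True, fastmath=True)
def _ev_cross(coords, radii, group_id, excl, mask, mv, k_ev):
    """Excluded volume between the moved set and everything else."""
    n = coords.shape[0]
    e = 0.0
    for a in range(mv.shape[0]):
        i = mv[a]
        gi = group_id[i]
        xi = coords[i, 0]
        yi = coords[i, 1]
        zi = coords[i, 2]
        ri = radii[i]
        for j in range(n):
            if mask[j] == 1:
                continue
            sig = ri + radii[j]
            dx = xi - coords[j, 0]
            if dx > sig or dx < -sig:
                continue
            dy = yi - coords[j, 1]
            if dy > sig or dy < -sig:
                continue
            dz = zi - coords[j, 2]
            if dz > sig or dz < -sig:
                continue
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= sig * sig:
                continue
            if gi >= 0 and group_id[j] == gi:
                continue
            if _excluded(excl, i, j):
                continue
            d = sig - math.sqrt(r2)
            e += k_ev * d * d
    return e


@njit(cache=True, fastmath=True)
def _ev_within(coords, radii, group_id, excl, mv, k_ev):
    """Excluded volume among the moved set (needed for non-rigid moves)."""
    e = 0.0
    for a in range(mv.shape[0]):
        i = mv[a]
        gi = group_id[i]
        for b in range(a + 1, mv.shape[0]):
            j = mv[b]
            if gi >= 0 and group_id[j] == gi:
                continue
            if _excluded(excl, i, j):
                continue
            e += _ev_pair(coords, radii, i, j, k_ev)
    return e


@njit(cache=True, fastmath=True)
def _entry_terms_energy(
    coords, te_b, te_a, te_d, te_n, te_t,
    bond_i, bond_j, bond_r0, bond_k,
    ang_a, ang_b, ang_c, ang_th0, ang_k,
    dih, dih_phi0, dih_k,
    noe_i, noe_j, noe_rmin, noe_rmax, noe_kmin, noe_kmax, noe_fmax,
    att_i, att_j, att_eps, att_ron, att_roff,
):
    e = 0.0
    for m in range(te_b.shape[0]):
        t = te_b[m]
        e += _bond_e(coords, bond_i[t], bond_j[t], bond_r0[t], bond_k[t])
    for m in range(te_a.shape[0]):
        t = te_a[m]
        e += _angle_e(coords, ang_a[t], ang_b[t], ang_c[t], ang_th0[t], ang_k[t])
    for m in range(te_d.shape[0]):
        t = te_d[m]
        e += _dihedral_e(coords, dih[t, 0], dih[t, 1], dih[t, 2], dih[t, 3],
                         dih_phi0[t], dih_k[t])
    for m in range(te_n.shape[0]):
        t = te_n[m]
        e += _noe_e(coords, noe_i[t], noe_j[t], noe_rmin[t], noe_rmax[t],
                    noe_kmin[t], noe_kmax[t], noe_fmax[t])
    for m in range(te_t.shape[0]):
        t = te_t[m]
        e += _att_e(coords, att_i[t], att_j[t], att_eps[t], att_ron, att_roff)
    return e


@njit(cache=True, fastmath=True)
def _rg_energy(s1x, s1y, s1z, s2, n, target, k):
    mx = s1x / n
    my = s1y / n
    mz = s1z / n
    rg2 = s2 / n - (mx * mx + my * my + mz * mz)
    if rg2 < 0.0:
        rg2 = 0.0
    d = math.sqrt(rg2) - target
    return k * d * d


@njit(cache=True, fastmath=True)
def _rand_unit():
    while True:
        x = 2.0 * np.random.random() - 1.0
        y = 2.0 * np.random.random() - 1.0
        z = 2.0 * np.random.random() - 1.0
        r2 = x * x + y * y + z * z
        if 1e-8 < r2 <= 1.0:
            r = math.sqrt(r2)
            return x / r, y / r, z / r


@njit(cache=True, fastmath=True)
def _rotate_set(coords, mv, cx, cy, cz, ax, ay, az, angle):
    """Rotate beads in mv about axis (ax,ay,az) through point (cx,cy,cz)."""
    s = math.sin(angle)
    c = math.cos(angle)
    omc = 1.0 - c
    for a in range(mv.shape[0]):
        i = mv[a]
        px = coords[i, 0] - cx
        py = coords[i, 1] - cy
        pz = coords[i, 2] - cz
        dot = ax * px + ay * py + az * pz
        crx = ay * pz - az * py
        cry = az * px - ax * pz
        crz = ax * py - ay * px
        coords[i, 0] = cx + px * c + crx * s + ax * dot * omc
        coords[i, 1] = cy + py * c + cry * s + ay * dot * omc
        coords[i, 2] = cz + pz * c + crz * s + az * dot * omc


@njit(cache=True)
def run_block(
    coords, radii, group_id, excl, mask,
    bond_i, bond_j, bond_r0, bond_k,
    ang_a, ang_b, ang_c, ang_th0, ang_k,
    dih, dih_phi0, dih_k,
    noe_i, noe_j, noe_rmin, noe_rmax, noe_kmin, noe_kmax, noe_fmax,
    att_i, att_j, att_eps, att_ron, att_roff,
    k_ev,
    rg_on, rg_target, rg_k, rg_sums,
    ent_kind, ent_a1, ent_a2, ent_scale,
    mv_idx, mv_w, mv_off,
    eb_idx, eb_off, ea_idx, ea_off, ed_idx, ed_off, en_idx, en_off,
    et_idx, et_off,
    class_start, class_count, class_cum,
    amp_bead, amp_crank, amp_subtree, amp_pinned_rot, amp_pinned_trans,
    amp_taper,
    n_steps, rt, seed, old_buf, acc,
):
    np.random.seed(seed)
    n = coords.shape[0]
    for _step in range(n_steps):
        # --- select a move entry -------------------------------------
        u = np.random.random()
        cls = 0
        while cls < N_CLASSES - 1 and u > class_cum[cls]:
            cls += 1
        cnt = class_count[cls]
        if cnt == 0:
            continue
        e = class_start[cls] + np.random.randint(0, cnt)
        kind = ent_kind[e]
        scale = ent_scale[e]
        mv = mv_idx[mv_off[e]:mv_off[e + 1]]
        wts = mv_w[mv_off[e]:mv_off[e + 1]]
        nm = mv.shape[0]

        te_b = eb_idx[eb_off[e]:eb_off[e + 1]]
        te_a = ea_idx[ea_off[e]:ea_off[e + 1]]
        te_d = ed_idx[ed_off[e]:ed_off[e + 1]]
        te_n = en_idx[en_off[e]:en_off[e + 1]]
        te_t = et_idx[et_off[e]:et_off[e + 1]]

        for a in range(nm):
            mask[mv[a]] = 1

        e0 = _ev_cross(coords, radii, group_id, excl, mask, mv, k_ev)
        if kind == K_TAPER:
            e0 += _ev_within(coords, radii, group_id, excl, mv, k_ev)
        e0 += _entry_terms_energy(
            coords, te_b, te_a, te_d, te_n, te_t,
            bond_i, bond_j, bond_r0, bond_k,
            ang_a, ang_b, ang_c, ang_th0, ang_k,
            dih, dih_phi0, dih_k,
            noe_i, noe_j, noe_rmin, noe_rmax, noe_kmin, noe_kmax, noe_fmax,
            att_i, att_j, att_eps, att_ron, att_roff,
        )
        d1x = 0.0
        d1y = 0.0
        d1z = 0.0
        d2 = 0.0
        if rg_on == 1:
            e0 += _rg_energy(rg_sums[0], rg_sums[1], rg_sums[2], rg_sums[3],
                             n, rg_target, rg_k)
            for a in range(nm):
                i = mv[a]
                d1x -= coords[i, 0]
                d1y -= coords[i, 1]
                d1z -= coords[i, 2]
                d2 -= (coords[i, 0] * coords[i, 0] + coords[i, 1] * coords[i, 1]
                       + coords[i, 2] * coords[i, 2])

        for a in range(nm):
            i = mv[a]
            old_buf[a, 0] = coords[i, 0]
            old_buf[a, 1] = coords[i, 1]
            old_buf[a, 2] = coords[i, 2]

        # --- propose -------------------------------------------------
        if kind == K_BEAD:
            i = mv[0]
            coords[i, 0] += (2.0 * np.random.random() - 1.0) * amp_bead * scale
            coords[i, 1] += (2.0 * np.random.random() - 1.0) * amp_bead * scale
            coords[i, 2] += (2.0 * np.random.random() - 1.0) * amp_bead * scale
        elif kind == K_CRANK:
            a1 = ent_a1[e]
            a2 = ent_a2[e]
            ax = coords[a2, 0] - coords[a1, 0]
            ay = coords[a2, 1] - coords[a1, 1]
            az = coords[a2, 2] - coords[a1, 2]
            nrm = math.sqrt(ax * ax + ay * ay + az * az)
            if nrm < 1e-9:
                ax, ay, az = _rand_unit()
            else:
                ax /= nrm
                ay /= nrm
                az /= nrm
            ang = (2.0 * np.random.random() - 1.0) * amp_crank * scale
            _rotate_set(coords, mv, coords[a1, 0], coords[a1, 1], coords[a1, 2],
                        ax, ay, az, ang)
        elif kind == K_SUBTREE:
            a1 = ent_a1[e]
            ax, ay, az = _rand_unit()
            ang = (2.0 * np.random.random() - 1.0) * amp_subtree * scale
            _rotate_set(coords, mv, coords[a1, 0], coords[a1, 1], coords[a1, 2],
                        ax, ay, az, ang)
        elif kind == K_PINNED:
            # small rotation about centroid + small translation
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for a in range(nm):
                i = mv[a]
                cx += coords[i, 0]
                cy += coords[i, 1]
                cz += coords[i, 2]
            cx /= nm
            cy /= nm
            cz /= nm
            ax, ay, az = _rand_unit()
            ang = (2.0 * np.random.random() - 1.0) * amp_pinned_rot * scale
            _rotate_set(coords, mv, cx, cy, cz, ax, ay, az, ang)
            tx = (2.0 * np.random.random() - 1.0) * amp_pinned_trans
            ty = (2.0 * np.random.random() - 1.0) * amp_pinned_trans
            tz = (2.0 * np.random.random() - 1.0) * amp_pinned_trans
            for a in range(nm):
                i = mv[a]
                coords[i, 0] += tx
                coords[i, 1] += ty
                coords[i, 2] += tz
        else:  # K_TAPER: full rotation of the core, tapered on the flanks
            cx = 0.0
            cy = 0.0
            cz = 0.0
            nc = 0
            for a in range(nm):
                if wts[a] >= 0.999:
                    i = mv[a]
                    cx += coords[i, 0]
                    cy += coords[i, 1]
                    cz += coords[i, 2]
                    nc += 1
            if nc == 0:
                nc = nm
                for a in range(nm):
                    i = mv[a]
                    cx += coords[i, 0]
                    cy += coords[i, 1]
                    cz += coords[i, 2]
            cx /= nc
            cy /= nc
            cz /= nc
            ax, ay, az = _rand_unit()
            ang = (2.0 * np.random.random() - 1.0) * amp_taper * scale
            one = np.empty(1, dtype=mv.dtype)
            for a in range(nm):
                one[0] = mv[a]
                _rotate_set(coords, one, cx, cy, cz, ax, ay, az, ang * wts[a])

        # --- evaluate ------------------------------------------------
        e1 = _ev_cross(coords, radii, group_id, excl, mask, mv, k_ev)
        if kind == K_TAPER:
            e1 += _ev_within(coords, radii, group_id, excl, mv, k_ev)
        e1 += _entry_terms_energy(
            coords, te_b, te_a, te_d, te_n, te_t,
            bond_i, bond_j, bond_r0, bond_k,
            ang_a, ang_b, ang_c, ang_th0, ang_k,
            dih, dih_phi0, dih_k,
            noe_i, noe_j, noe_rmin, noe_rmax, noe_kmin, noe_kmax, noe_fmax,
            att_i, att_j, att_eps, att_ron, att_roff,
        )
        if rg_on == 1:
            for a in range(nm):
                i = mv[a]
                d1x += coords[i, 0]
                d1y += coords[i, 1]
                d1z += coords[i, 2]
                d2 += (coords[i, 0] * coords[i, 0] + coords[i, 1] * coords[i, 1]
                       + coords[i, 2] * coords[i, 2])
            e1 += _rg_energy(rg_sums[0] + d1x, rg_sums[1] + d1y,
                             rg_sums[2] + d1z, rg_sums[3] + d2,
                             n, rg_target, rg_k)

        de = e1 - e0
        accept = False
        if de <= 0.0:
            accept = True
        else:
            arg = de / rt
            if arg < 50.0 and np.random.random() < math.exp(-arg):
                accept = True

        if accept:
            acc[kind] += 1
            if rg_on == 1:
                rg_sums[0] += d1x
                rg_sums[1] += d1y
                rg_sums[2] += d1z
                rg_sums[3] += d2
        else:
            for a in range(nm):
                i = mv[a]
                coords[i, 0] = old_buf[a, 0]
                coords[i, 1] = old_buf[a, 1]
                coords[i, 2] = old_buf[a, 2]
        for a in range(nm):
            mask[mv[a]] = 0


@njit(cache=True, fastmath=True)
def total_energy(
    coords, radii, group_id, excl,
    bond_i, bond_j, bond_r0, bond_k,
    ang_a, ang_b, ang_c, ang_th0, ang_k,
    dih, dih_phi0, dih_k,
    noe_i, noe_j, noe_rmin, noe_rmax, noe_kmin, noe_kmax, noe_fmax,
    att_i, att_j, att_eps, att_ron, att_roff,
    k_ev, rg_on, rg_target, rg_k,
):
    """Full energy with per-term breakdown.

    Returns (total, bond, angle, dihedral, excluded_volume, attraction,
    noe, rg)."""
    n = coords.shape[0]
    eb = 0.0
    for t in range(bond_i.shape[0]):
        eb += _bond_e(coords, bond_i[t], bond_j[t], bond_r0[t], bond_k[t])
    ea = 0.0
    for t in range(ang_a.shape[0]):
        ea += _angle_e(coords, ang_a[t], ang_b[t], ang_c[t], ang_th0[t], ang_k[t])
    ed = 0.0
    for t in range(dih.shape[0]):
        ed += _dihedral_e(coords, dih[t, 0], dih[t, 1], dih[t, 2], dih[t, 3],
                          dih_phi0[t], dih_k[t])
    ee = 0.0
    for i in range(n):
        gi = group_id[i]
        for j in range(i + 1, n):
            if gi >= 0 and group_id[j] == gi:
                continue
            if _excluded(excl, i, j):
                continue
            ee += _ev_pair(coords, radii, i, j, k_ev)
    et = 0.0
    for t in range(att_i.shape[0]):
        et += _att_e(coords, att_i[t], att_j[t], att_eps[t], att_ron, att_roff)
    en = 0.0
    for t in range(noe_i.shape[0]):
        en += _noe_e(coords, noe_i[t], noe_j[t], noe_rmin[t], noe_rmax[t],
                     noe_kmin[t], noe_kmax[t], noe_fmax[t])
    er = 0.0
    if rg_on == 1:
        s1x = 0.0
        s1y = 0.0
        s1z = 0.0
        s2 = 0.0
        for i in range(n):
            s1x += coords[i, 0]
            s1y += coords[i, 1]
            s1z += coords[i, 2]
            s2 += (coords[i, 0] * coords[i, 0] + coords[i, 1] * coords[i, 1]
                   + coords[i, 2] * coords[i, 2])
        er = _rg_energy(s1x, s1y, s1z, s2, n, rg_target, rg_k)
    return eb + ea + ed + ee + et + en + er, eb, ea, ed, ee, et, en, er
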