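"""Numba-compiled numerical kernels.

Everything here is plain-array code: the object layer (model, samplers,
topology) owns validation and bookkeeping, these kernels own the inner loops.
Energy conventions match :func:`knotswap.model.total_energy` exactly — WCA
between all bead pairs including bonded neighbors, FENE on bonds, harmonic
bending on the angle between consecutive bond vectors. A FENE bond at or
beyond R0 contributes the finite sentinel 1e30 inside Monte Carlo move
evaluation (certain rejection) and +inf in total-energy evaluation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
_BIG = 1e30


# --------------------------------------------------------------------------
# scalar pieces
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _wca_r2(r2, sigma, eps):
    rc2 = WCA_CUT * WCA_CUT * sigma * sigma
    if r2 >= rc2:
        return 0.0
    sr2 = sigma * sigma / r2
    sr6 = sr2 * sr2 * sr2
    return 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)


@njit(cache=True, inline="always")
def _fene_r(r, k, R0):
    if r >= R0:
        return _BIG
    x = r / R0
    return -0.5 * k * R0 * R0 * math.log(1.0 - x * x)


@njit(cache=True, inline="always")
def _bend_phi(ax, ay, az, bx, by, bz):
    """Angle between consecutive bond vectors a, b (0 = straight)."""
    na = math.sqrt(ax * ax + ay * ay + az * az)
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    c = (ax * bx + ay * by + az * bz) / (na * nb)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return math.acos(c)


@njit(cache=True, inline="always")
def _angle_energy_at(pos, i, kappa):
    """Bending energy of the interior angle at bead i (uses i-1, i, i+1)."""
    ax = pos[i, 0] - pos[i - 1, 0]
    ay = pos[i, 1] - pos[i - 1, 1]
    az = pos[i, 2] - pos[i - 1, 2]
    bx = pos[i + 1, 0] - pos[i, 0]
    by = pos[i + 1, 1] - pos[i, 1]
    bz = pos[i + 1, 2] - pos[i, 2]
    phi = _bend_phi(ax, ay, az, bx, by, bz)
    return 0.5 * kappa * phi * phi


@njit(cache=True)
def total_energy_kernel(pos, sigma, eps, k, R0, kappa, ev, wall_l, grafted):
    """Brute-force total potential energy; +inf on an overstretched bond."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= R0:
            return np.inf
        e += _fene_r(r, k, R0)
    for i in range(1, n - 1):
        e += _angle_energy_at(pos, i, kappa)
    if ev:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                e += _wca_r2(dx * dx + dy * dy + dz * dz, sigma, eps)
    if wall_l > 0.0:
        lo = 1 if grafted else 0
        hi = n - 1 if grafted else n
        for i in range(lo, hi):
            z = pos[i, 2]
            if z <= 0.0 or z >= wall_l:
                return np.inf
            e += _wca_r2(z * z, sigma, eps)
            d2 = wall_l - z
            e += _wca_r2(d2 * d2, sigma, eps)
    return e


# --------------------------------------------------------------------------
# cell-hash neighbor search over a static bead set
# --------------------------------------------------------------------------

@njit(cache=True)
def _build_cell_hash(S, wc):
    """Sorted cell-id hash over points S with cell width wc.

    Returns (ids_sorted, S_sorted, origin, ncell) where ids are flattened
    integer cell coordinates. Lookup is by binary search — no dense grid is
    allocated, so arbitrarily extended chains are fine.
    """
    m = S.shape[0]
    origin = np.empty(3)
    ncell = np.empty(3, np.int64)
    for d in range(3):
        lo = S[0, d]
        hi = S[0, d]
        for i in range(1, m):
            v = S[i, d]
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        origin[d] = lo
        ncell[d] = int((hi - lo) / wc) + 1
    ids = np.empty(m, np.int64)
    for i in range(m):
        cx = int((S[i, 0] - origin[0]) / wc)
        cy = int((S[i, 1] - origin[1]) / wc)
        cz = int((S[i, 2] - origin[2]) / wc)
        ids[i] = cx + ncell[0] * (cy + ncell[1] * cz)
    order = np.argsort(ids)
    return ids[order], S[order], origin, ncell


@njit(cache=True)
def _point_static_wca(px, py, pz, ids_sorted, S_sorted, origin, ncell, wc,
                      sigma, eps):
    """WCA energy of one point against the hashed static set."""
    cx = int(math.floor((px - origin[0]) / wc))
    cy = int(math.floor((py - origin[1]) / wc))
    cz = int(math.floor((pz - origin[2]) / wc))
    e = 0.0
    for ax in range(max(0, cx - 1), min(ncell[0] - 1, cx + 1) + 1):
        for ay in range(max(0, cy - 1), min(ncell[1] - 1, cy + 1) + 1):
            for az in range(max(0, cz - 1), min(ncell[2] - 1, cz + 1) + 1):
                cid = ax + ncell[0] * (ay + ncell[1] * az)
                lo = np.searchsorted(ids_sorted, cid)
                hi = np.searchsorted(ids_sorted, cid + 1)
                for s in range(lo, hi):
                    dx = S_sorted[s, 0] - px
                    dy = S_sorted[s, 1] - py
                    dz = S_sorted[s, 2] - pz
                    e += _wca_r2(dx * dx + dy * dy + dz * dz, sigma, eps)
    return e


@njit(cache=True)
def segment_static_wca(pos, seg, lo, hi, sigma, eps):
    """WCA energy between beads seg[0:hi-lo] (candidate coords of chain slice
    [lo,hi)) and all beads outside [lo,hi), via the cell hash."""
    n = pos.shape[0]
    m = n - (hi - lo)
    if m == 0:
        return 0.0
    S = np.empty((m, 3), np.float64)
    w = 0
    for i in range(n):
        if lo <= i < hi:
            continue
        S[w, 0] = pos[i, 0]
        S[w, 1] = pos[i, 1]
        S[w, 2] = pos[i, 2]
        w += 1
    wc = WCA_CUT * sigma
    ids_sorted, S_sorted, origin, ncell = _build_cell_hash(S, wc)
    e = 0.0
    for i in range(hi - lo):
        e += _point_static_wca(seg[i, 0], seg[i, 1], seg[i, 2],
                               ids_sorted, S_sorted, origin, ncell, wc,
                               sigma, eps)
    return e


# --------------------------------------------------------------------------
# Monte Carlo driver (free chains)
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rot_matrix(ux, uy, uz, phi):
    c = math.cos(phi)
    s = math.sin(phi)
    C = 1.0 - c
    return (c + ux * ux * C, ux * uy * C - uz * s, ux * uz * C + uy * s,
            uy * ux * C + uz * s, c + uy * uy * C, uy * uz * C - ux * s,
            uz * ux * C - uy * s, uz * uy * C + ux * s, c + uz * uz * C)


@njit(cache=True)
def _local_delta(pos, i, nx, ny, nz, sigma, eps, k, R0, kappa, ev):
    n = pos.shape[0]
    de = 0.0
    ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
    for j in (i - 1, i + 1):
        if 0 <= j < n:
            dx = nx - pos[j, 0]
            dy = ny - pos[j, 1]
            dz = nz - pos[j, 2]
            rn = math.sqrt(dx * dx + dy * dy + dz * dz)
            if rn >= R0:
                return _BIG
            dx = ox - pos[j, 0]
            dy = oy - pos[j, 1]
            dz = oz - pos[j, 2]
            ro = math.sqrt(dx * dx + dy * dy + dz * dz)
            de += _fene_r(rn, k, R0) - _fene_r(ro, k, R0)
    if kappa > 0.0:
        for a in (i - 1, i, i + 1):
            if 1 <= a <= n - 2:
                de -= _angle_energy_at(pos, a, kappa)
        pos[i, 0], pos[i, 1], pos[i, 2] = nx, ny, nz
        for a in (i - 1, i, i + 1):
            if 1 <= a <= n - 2:
                de += _angle_energy_at(pos, a, kappa)
        pos[i, 0], pos[i, 1], pos[i, 2] = ox, oy, oz
    if ev:
        for j in range(n):
            if j == i:
                continue
            dx = nx - pos[j, 0]
            dy = ny - pos[j, 1]
            dz = nz - pos[j, 2]
            de += _wca_r2(dx * dx + dy * dy + dz * dz, sigma, eps)
            dx = ox - pos[j, 0]
            dy = oy - pos[j, 1]
            dz = oz - pos[j, 2]
            de -= _wca_r2(dx * dx + dy * dy + dz * dz, sigma, eps)
    return de


@njit(cache=True)
def rotate_segment(pos, lo, hi, cx, cy, cz, ux, uy, uz, phi):
    """Rigid rotation of chain slice [lo,hi) about axis u through point c."""
    r00, r01, r02, r10, r11, r12, r20, r21, r22 = _rot_matrix(ux, uy, uz, phi)
    out = np.empty((hi - lo, 3), np.float64)
    for w in range(hi - lo):
        i = lo + w
        x = pos[i, 0] - cx
        y = pos[i, 1] - cy
        z = pos[i, 2] - cz
        out[w, 0] = cx + r00 * x + r01 * y + r02 * z
        out[w, 1] = cy + r10 * x + r11 * y + r12 * z
        out[w, 2] = cz + r20 * x + r21 * y + r22 * z
    return out


@njit(cache=True)
def _global_move_delta(pos, lo, hi, seg, changed_angles, sigma, eps, k, R0,
                       kappa, ev):
    """Energy change for replacing slice [lo,hi) by rigid-rotated coords seg.

    ``changed_angles`` lists the interior-angle indices whose value is not
    preserved by the rigid rotation (the pivot bead / crankshaft axis beads).
    Bonded distances across the slice boundary are preserved by construction.
    """
    n = pos.shape[0]
    de = 0.0
    if kappa > 0.0:
        for a in changed_angles:
            if 1 <= a <= n - 2:
                de -= _angle_energy_at(pos, a, kappa)
    if ev:
        de -= segment_static_wca(pos, pos[lo:hi], lo, hi, sigma, eps)
        de += segment_static_wca(pos, seg, lo, hi, sigma, eps)
    if kappa > 0.0:
        old = pos[lo:hi].copy()
        pos[lo:hi] = seg
        for a in changed_angles:
            if 1 <= a <= n - 2:
                de += _angle_energy_at(pos, a, kappa)
        pos[lo:hi] = old
    return de


@njit(cache=True)
def _rand_unit():
    while True:
        x = np.random.normal()
        y = np.random.normal()
        z = np.random.normal()
        r = math.sqrt(x * x + y * y + z * z)
        if r > 1e-12:
            return x / r, y / r, z / r


@njit(cache=True)
def mc_drive(pos, n_moves, p_local, p_pivot, max_disp, max_crank,
             sigma, eps, k, R0, kappa, temp, ev, seed, snap_every):
    """Metropolis Monte Carlo on a free chain.

    Move mix: capped single-bead displacement, pivot (rotate one tail about a
    random interior bead by a random axis/angle), and crankshaft-type segment
    rotation about the axis through two beads (the segment-reflection move at
    angle pi). Returns snapshots, their move indices, their total energies,
    and per-move-type attempt/accept counters.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_snaps = n_moves // snap_every
    snaps = np.empty((n_snaps, n, 3), np.float64)
    snap_steps = np.empty(n_snaps, np.int64)
    energies = np.empty(n_snaps, np.float64)
    att = np.zeros(3, np.int64)
    acc = np.zeros(3, np.int64)
    beta = 1.0 / temp
    w = 0
    for m in range(n_moves):
        u = np.random.random()
        if u < p_local:
            att[0] += 1
            i = np.random.randint(0, n)
            nx = pos[i, 0] + max_disp * (2.0 * np.random.random() - 1.0)
            ny = pos[i, 1] + max_disp * (2.0 * np.random.random() - 1.0)
            nz = pos[i, 2] + max_disp * (2.0 * np.random.random() - 1.0)
            de = _local_delta(pos, i, nx, ny, nz, sigma, eps, k, R0, kappa, ev)
            if de <= 0.0 or (de < 700.0 and np.random.random() < math.exp(-beta * de)):
                pos[i, 0], pos[i, 1], pos[i, 2] = nx, ny, nz
                acc[0] += 1
        elif u < p_local + p_pivot:
            att[1] += 1
            p = 1 + np.random.randint(0, n - 2)
            tail = np.random.random() < 0.5
            lo, hi = (p + 1, n) if tail else (0, p)
            ux, uy, uz = _rand_unit()
            phi = math.pi * (2.0 * np.random.random() - 1.0)
            seg = rotate_segment(pos, lo, hi, pos[p, 0], pos[p, 1], pos[p, 2],
                                 ux, uy, uz, phi)
            changed = np.empty(1, np.int64)
            changed[0] = p
            de = _global_move_delta(pos, lo, hi, seg, changed,
                                    sigma, eps, k, R0, kappa, ev)
            if de <= 0.0 or (de < 700.0 and np.random.random() < math.exp(-beta * de)):
                pos[lo:hi] = seg
                acc[1] += 1
        else:
            att[2] += 1
            i = np.random.randint(0, n - 2)
            span = 2 + np.random.randint(0, max_crank - 1)
            j = i + span
            if j > n - 1:
                j = n - 1
            ax = pos[j, 0] - pos[i, 0]
            ay = pos[j, 1] - pos[i, 1]
            az = pos[j, 2] - pos[i, 2]
            anorm = math.sqrt(ax * ax + ay * ay + az * az)
            if anorm > 1e-12 and j - i >= 2:
                ax /= anorm
                ay /= anorm
                az /= anorm
                phi = math.pi * (2.0 * np.random.random() - 1.0)
                seg = rotate_segment(pos, i + 1, j, pos[i, 0], pos[i, 1],
                                     pos[i, 2], ax, ay, az, phi)
                changed = np.empty(2, np.int64)
                changed[0] = i
                changed[1] = j
                de = _global_move_delta(pos, i + 1, j, seg, changed,
                                        sigma, eps, k, R0, kappa, ev)
                if de <= 0.0 or (de < 700.0 and np.random.random() < math.exp(-beta * de)):
                    pos[i + 1:j] = seg
                    acc[2] += 1
        if (m + 1) % snap_every == 0:
            snaps[w] = pos
            snap_steps[w] = m + 1
            energies[w] = total_energy_kernel(pos, sigma, eps, k, R0, kappa,
                                              ev, -1.0, False)
            w += 1
    return snaps, snap_steps, energies, att, acc


# --------------------------------------------------------------------------
# Langevin MD driver (wall-confined grafted chains, or free chains)
# --------------------------------------------------------------------------

@njit(cache=True)
def _build_pairs(pos, rlist, pairs):
    """All pairs within rlist, including bonded neighbors. Returns count or -1
    on capacity overflow."""
    n = pos.shape[0]
    r2 = rlist * rlist
    m = 0
    cap = pairs.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < r2:
                if m >= cap:
                    return -1
                pairs[m, 0] = i
                pairs[m, 1] = j
                m += 1
    return m


@njit(cache=True)
def _forces(pos, f, pairs, n_pairs, sigma, eps, k, R0, kappa, ev, wall_l,
            wall_feel):
    """Fill force array; returns 0 ok, 1 bond blowup, 2 escaped slab."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    rc2 = WCA_CUT * WCA_CUT * sigma * sigma
    if ev:
        for p in range(n_pairs):
            i = pairs[p, 0]
            j = pairs[p, 1]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                sr2 = sigma * sigma / r2
                sr6 = sr2 * sr2 * sr2
                fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                f[i, 0] -= fmag * dx
                f[i, 1] -= fmag * dy
                f[i, 2] -= fmag * dz
                f[j, 0] += fmag * dx
                f[j, 1] += fmag * dy
                f[j, 2] += fmag * dz
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R0 * R0:
            return 1
        g = k / (1.0 - r2 / (R0 * R0))
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[i + 1, 0] -= g * dx
        f[i + 1, 1] -= g * dy
        f[i + 1, 2] -= g * dz
    if kappa > 0.0:
        for i in range(1, n - 1):
            ax = pos[i, 0] - pos[i - 1, 0]
            ay = pos[i, 1] - pos[i - 1, 1]
            az = pos[i, 2] - pos[i - 1, 2]
            bx = pos[i + 1, 0] - pos[i, 0]
            by = pos[i + 1, 1] - pos[i, 1]
            bz = pos[i + 1, 2] - pos[i, 2]
            na = math.sqrt(ax * ax + ay * ay + az * az)
            nb = math.sqrt(bx * bx + by * by + bz * bz)
            cphi = (ax * bx + ay * by + az * bz) / (na * nb)
            if cphi > 1.0:
                cphi = 1.0
            elif cphi < -1.0:
                cphi = -1.0
            phi = math.acos(cphi)
            s = math.sqrt(1.0 - cphi * cphi)
            # dU/dphi / sin(phi); finite limit kappa as phi -> 0
            g = kappa if s < 1e-8 else kappa * phi / s
            # gradient of cos(phi) wrt the three beads
            inv_ab = 1.0 / (na * nb)
            da_x = bx * inv_ab - cphi * ax / (na * na)
            da_y = by * inv_ab - cphi * ay / (na * na)
            da_z = bz * inv_ab - cphi * az / (na * na)
            db_x = ax * inv_ab - cphi * bx / (nb * nb)
            db_y = ay * inv_ab - cphi * by / (nb * nb)
            db_z = az * inv_ab - cphi * bz / (nb * nb)
            # U = kappa/2 phi^2; F = -dU/dx = g * dcos/dx with chain rule sign
            # dcos/d r_{i-1} = -da, dcos/d r_{i+1} = db
            f[i - 1, 0] += -g * da_x
            f[i - 1, 1] += -g * da_y
            f[i - 1, 2] += -g * da_z
            f[i + 1, 0] += g * db_x
            f[i + 1, 1] += g * db_y
            f[i + 1, 2] += g * db_z
            f[i, 0] += g * (da_x - db_x)
            f[i, 1] += g * (da_y - db_y)
            f[i, 2] += g * (da_z - db_z)
    if wall_l > 0.0:
        for i in range(n):
            if not wall_feel[i]:
                continue
            z = pos[i, 2]
            if z <= 0.0 or z >= wall_l:
                return 2
            if z * z < rc2:
                sz2 = sigma * sigma / (z * z)
                sz6 = sz2 * sz2 * sz2
                f[i, 2] += 24.0 * eps * (2.0 * sz6 * sz6 - sz6) / z
            d = wall_l - z
            if d * d < rc2:
                sd2 = sigma * sigma / (d * d)
                sd6 = sd2 * sd2 * sd2
                f[i, 2] -= 24.0 * eps * (2.0 * sd6 * sd6 - sd6) / d
    return 0


@njit(cache=True)
def md_drive(pos, mobile, wall_feel, dt, gamma, temp, n_steps,
             sigma, eps, k, R0, kappa, ev, wall_l, seed, snap_every,
             skin):
    """Langevin dynamics, Gronbech-Jensen/Farago discretization, m = 1.

    Temperature is measured from half-step velocities (2GJ estimator), which
    for this scheme carries no leading-order time-step bias. Immobile
    (grafted) beads keep zero velocity and fixed coordinates.

    Returns (snaps, snap_steps, energies, temps, status, fail_step); status
    0 = ok, 1 = bond blowup, 2 = escaped slab.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_snaps = n_steps // snap_every
    snaps = np.empty((n_snaps, n, 3), np.float64)
    snap_steps = np.empty(n_snaps, np.int64)
    energies = np.empty(n_snaps, np.float64)
    temps = np.empty(n_snaps, np.float64)
    a = (1.0 - gamma * dt / 2.0) / (1.0 + gamma * dt / 2.0)
    b = 1.0 / (1.0 + gamma * dt / 2.0)
    sig_beta = math.sqrt(2.0 * gamma * temp * dt)
    sqb = math.sqrt(b)
    n_mob = 0
    for i in range(n):
        if mobile[i]:
            n_mob += 1
    vel = np.zeros((n, 3), np.float64)
    for i in range(n):
        if mobile[i]:
            for d in range(3):
                vel[i, d] = math.sqrt(temp) * np.random.normal()
    rlist = WCA_CUT * sigma + skin
    pairs = np.empty((n * 128, 2), np.int64)
    n_pairs = _build_pairs(pos, rlist, pairs)
    if n_pairs < 0:
        return snaps, snap_steps, energies, temps, 3, 0
    ref = pos.copy()
    f = np.zeros((n, 3), np.float64)
    st = _forces(pos, f, pairs, n_pairs, sigma, eps, k, R0, kappa, ev,
                 wall_l, wall_feel)
    if st != 0:
        return snaps, snap_steps, energies, temps, st, 0
    w = 0
    tsum = 0.0
    tcount = 0
    for step in range(n_steps):
        for i in range(n):
            if not mobile[i]:
                continue
            for d in range(3):
                beta_n = sig_beta * np.random.normal()
                xold = pos[i, d]
                pos[i, d] = (xold + b * dt * vel[i, d]
                             + 0.5 * b * dt * dt * f[i, d]
                             + 0.5 * b * dt * beta_n)
                # half-step velocity for the temperature estimator
                u_half = (pos[i, d] - xold) / (sqb * dt)
                tsum += u_half * u_half
                # stash a*v + (dt/2)*a*f + b*beta; add dt/2 f_new after forces
                vel[i, d] = a * vel[i, d] + 0.5 * dt * a * f[i, d] + b * beta_n
        tcount += 3 * n_mob
        # neighbor list refresh on displacement
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > 0.25 * skin * skin:
            n_pairs = _build_pairs(pos, rlist, pairs)
            if n_pairs < 0:
                return snaps, snap_steps, energies, temps, 3, step
            ref[:] = pos
        st = _forces(pos, f, pairs, n_pairs, sigma, eps, k, R0, kappa, ev,
                     wall_l, wall_feel)
        if st != 0:
            return snaps, snap_steps, energies, temps, st, step
        for i in range(n):
            if not mobile[i]:
                continue
            for d in range(3):
                vel[i, d] += 0.5 * dt * f[i, d]
        if (step + 1) % snap_every == 0:
            snaps[w] = pos
            snap_steps[w] = step + 1
            energies[w] = total_energy_kernel(pos, sigma, eps, k, R0, kappa,
                                              ev, wall_l, not mobile[0])
            temps[w] = tsum / tcount if tcount > 0 else 0.0
            tsum = 0.0
            tcount = 0
            w += 1
    return snaps, snap_steps, energies, temps, 0, n_steps


# --------------------------------------------------------------------------
# topology kernels: KMT reduction and planar crossing detection
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _orient(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Signed volume of tetrahedron (p; a, b, c)."""
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    nx = aby * acz - abz * acy
    ny = abz * acx - abx * acz
    nz = abx * acy - aby * acx
    return apx * nx + apy * ny + apz * nz


@njit(cache=True)
def _triangle_blocked(P, nxt, active, a, v, c, eps_area):
    """True if any active segment (other than those touching a, v, c) crosses
    the triangle (P[a], P[v], P[c]). Degenerate contacts count as blocked."""
    ax, ay, az = P[a, 0], P[a, 1], P[a, 2]
    bx, by, bz = P[v, 0], P[v, 1], P[v, 2]
    cx, cy, cz = P[c, 0], P[c, 1], P[c, 2]
    # triangle bounding box
    tlx = min(ax, bx, cx)
    thx = max(ax, bx, cx)
    tly = min(ay, by, cy)
    thy = max(ay, by, cy)
    tlz = min(az, bz, cz)
    thz = max(az, bz, cz)
    n = P.shape[0]
    for s in range(n):
        if not active[s]:
            continue
        e = nxt[s]
        if s == a or s == v or s == c or e == a or e == v or e == c:
            continue
        px, py, pz = P[s, 0], P[s, 1], P[s, 2]
        qx, qy, qz = P[e, 0], P[e, 1], P[e, 2]
        if max(px, qx) < tlx or min(px, qx) > thx:
            continue
        if max(py, qy) < tly or min(py, qy) > thy:
            continue
        if max(pz, qz) < tlz or min(pz, qz) > thz:
            continue
        d1 = _orient(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz)
        d2 = _orient(qx, qy, qz, ax, ay, az, bx, by, bz, cx, cy, cz)
        if d1 * d2 > 0.0:
            continue
        if d1 == 0.0 and d2 == 0.0:
            return True  # coplanar: conservatively blocked
        d3 = _orient(ax, ay, az, px, py, pz, qx, qy, qz, bx, by, bz)
        d4 = _orient(bx, by, bz, px, py, pz, qx, qy, qz, cx, cy, cz)
        d5 = _orient(cx, cy, cz, px, py, pz, qx, qy, qz, ax, ay, az)
        if (d3 >= 0.0 and d4 >= 0.0 and d5 >= 0.0) or \
           (d3 <= 0.0 and d4 <= 0.0 and d5 <= 0.0):
            return True
    return False


@njit(cache=True)
def kmt_reduce(P):
    """Topology-preserving reduction of a closed polygon.

    Repeatedly deletes a vertex whose spanning triangle is crossed by no other
    segment of the polygon (Koniaris–Muthukumar-style elision). Returns the
    surviving vertices in order. Conservative on degeneracies: a vertex is
    kept unless removal is provably safe.
    """
    n = P.shape[0]
    if n <= 3:
        return P.copy()
    active = np.ones(n, np.bool_)
    nxt = np.empty(n, np.int64)
    prv = np.empty(n, np.int64)
    for i in range(n):
        nxt[i] = (i + 1) % n
        prv[i] = (i - 1) % n
    count = n
    # scale for degenerate-triangle detection
    ext = 0.0
    for d in range(3):
        lo = P[0, d]
        hi = P[0, d]
        for i in range(1, n):
            if P[i, d] < lo:
                lo = P[i, d]
            if P[i, d] > hi:
                hi = P[i, d]
        if hi - lo > ext:
            ext = hi - lo
    eps_area = 1e-12 * ext * ext
    changed = True
    while changed and count > 3:
        changed = False
        v = 0
        while not active[v]:
            v += 1
        start = v
        while True:
            a = prv[v]
            c = nxt[v]
            # degenerate triangle (collinear) => always safe to elide
            ux = P[v, 0] - P[a, 0]
            uy = P[v, 1] - P[a, 1]
            uz = P[v, 2] - P[a, 2]
            wx = P[c, 0] - P[a, 0]
            wy = P[c, 1] - P[a, 1]
            wz = P[c, 2] - P[a, 2]
            nxx = uy * wz - uz * wy
            nyy = uz * wx - ux * wz
            nzz = ux * wy - uy * wx
            area2 = nxx * nxx + nyy * nyy + nzz * nzz
            removable = area2 < eps_area * eps_area or \
                not _triangle_blocked(P, nxt, active, a, v, c, eps_area)
            nv = nxt[v]
            if removable:
                active[v] = False
                nxt[a] = c
                prv[c] = a
                count -= 1
                changed = True
                if count <= 3:
                    break
                if v == start:
                    start = a
            if nv == start:
                break
            v = nv
    out = np.empty((count, 3), np.float64)
    v = 0
    while not active[v]:
        v += 1
    for w in range(count):
        out[w, 0] = P[v, 0]
        out[w, 1] = P[v, 1]
        out[w, 2] = P[v, 2]
        v = nxt[v]
    return out


@njit(cache=True)
def find_crossings(xy, depth):
    """All transversal crossings of a closed planar polygon projection.

    xy: (n, 2) projected vertices; depth: (n,) coordinate along the projection
    direction. Returns (data, m, degenerate) where data[w] =
    (under_pos, over_pos, sign) with positions measured as segment index plus
    fractional parameter along the chain, and sign the right-handed crossing
    sign (over tangent cross under tangent). ``degenerate`` flags tangential
    or depth-ambiguous crossings — the caller should retry with a new
    projection direction.
    """
    n = xy.shape[0]
    cap = 8 * n + 64
    data = np.empty((cap, 3), np.float64)
    m = 0
    degen = False
    eps = 1e-9
    for i in range(n):
        i2 = (i + 1) % n
        px, py = xy[i, 0], xy[i, 1]
        rx = xy[i2, 0] - px
        ry = xy[i2, 1] - py
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue
            j2 = (j + 1) % n
            qx, qy = xy[j, 0], xy[j, 1]
            sx = xy[j2, 0] - qx
            sy = xy[j2, 1] - qy
            denom = rx * sy - ry * sx
            if abs(denom) < 1e-14:
                continue
            t = ((qx - px) * sy - (qy - py) * sx) / denom
            u = ((qx - px) * ry - (qy - py) * rx) / denom
            inside_t = eps < t < 1.0 - eps
            inside_u = eps < u < 1.0 - eps
            near_t = -eps <= t <= 1.0 + eps
            near_u = -eps <= u <= 1.0 + eps
            if inside_t and inside_u:
                zi = depth[i] + t * (depth[i2] - depth[i])
                zj = depth[j] + u * (depth[j2] - depth[j])
                if abs(zi - zj) < 1e-10:
                    degen = True
                if m >= cap:
                    degen = True
                    break
                if zi > zj:
                    over_pos = i + t
                    under_pos = j + u
                    sgn = 1.0 if denom > 0.0 else -1.0
                else:
                    over_pos = j + u
                    under_pos = i + t
                    sgn = 1.0 if -denom > 0.0 else -1.0
                data[m, 0] = under_pos
                data[m, 1] = over_pos
                data[m, 2] = sgn
                m += 1
            elif near_t and near_u:
                # grazing contact: ambiguous diagram
                degen = True
    return data, m, degen


# --------------------------------------------------------------------------
# segment-distance helpers for closure safety checks
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _seg_seg_dist2(p0x, p0y, p0z, p1x, p1y, p1z,
                   q0x, q0y, q0z, q1x, q1y, q1z):
    """Squared minimum distance between segments p0-p1 and q0-q1."""
    ux, uy, uz = p1x - p0x, p1y - p0y, p1z - p0z
    vx, vy, vz = q1x - q0x, q1y - q0y, q1z - q0z
    wx, wy, wz = p0x - q0x, p0y - q0y, p0z - q0z
    a = ux * ux + uy * uy + uz * uz
    b = ux * vx + uy * vy + uz * vz
    c = vx * vx + vy * vy + vz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    den = a * c - b * b
    if den > 1e-14 * max(a * c, 1e-300):
        s = (b * e - c * d) / den
    else:
        s = 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    t = (b * s + e) / c if c > 1e-300 else 0.0
    if t < 0.0:
        t = 0.0
        s = -d / a if a > 1e-300 else 0.0
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    elif t > 1.0:
        t = 1.0
        s = (b - d) / a if a > 1e-300 else 0.0
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    dx = wx + s * ux - t * vx
    dy = wy + s * uy - t * vy
    dz = wz + s * uz - t * vz
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def closure_min_dist(chain_pts, arc_pts):
    """Minimum distance between the open-chain polyline and the closure-arc
    polyline. arc_pts runs from the chain's last bead back to its first bead
    (inclusive); the two segment pairs that share those junction vertices are
    skipped."""
    nc = chain_pts.shape[0]
    na = arc_pts.shape[0]
    best = 1e300
    for i in range(nc - 1):
        for j in range(na - 1):
            if (i == nc - 2 and j == 0) or (i == 0 and j == na - 2):
                continue
            d2 = _seg_seg_dist2(
                chain_pts[i, 0], chain_pts[i, 1], chain_pts[i, 2],
                chain_pts[i + 1, 0], chain_pts[i + 1, 1], chain_pts[i + 1, 2],
                arc_pts[j, 0], arc_pts[j, 1], arc_pts[j, 2],
                arc_pts[j + 1, 0], arc_pts[j + 1, 1], arc_pts[j + 1, 2])
            if d2 < best:
                best = d2
    return math.sqrt(best)


@njit(cache=True)
def min_nonadjacent_dist(pts):
    """Minimum distance between non-bonded beads of an open chain."""
    n = pts.shape[0]
    best = 1e300
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = pts[j, 0] - pts[i, 0]
            dy = pts[j, 1] - pts[i, 1]
            dz = pts[j, 2] - pts[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
    return math.sqrt(best)


@njit(cache=True)
def relax_drive(pos, mobile, n_sweeps, max_disp, sigma, eps, k, R0, kappa,
                temp, ev, wall_l, wall_feel, seed):
    """Capped-displacement Metropolis sweeps, optionally inside a wall slab.

    One sweep = N attempted single-bead moves. Immobile beads are skipped.
    Returns (accepted, attempted)."""
    np.random.seed(seed)
    n = pos.shape[0]
    beta = 1.0 / temp
    acc = 0
    att = 0
    for _ in range(n_sweeps * n):
        i = np.random.randint(0, n)
        if not mobile[i]:
            continue
        att += 1
        nx = pos[i, 0] + max_disp * (2.0 * np.random.random() - 1.0)
        ny = pos[i, 1] + max_disp * (2.0 * np.random.random() - 1.0)
        nz = pos[i, 2] + max_disp * (2.0 * np.random.random() - 1.0)
        de = _local_delta(pos, i, nx, ny, nz, sigma, eps, k, R0, kappa, ev)
        if wall_l > 0.0 and wall_feel[i]:
            oz = pos[i, 2]
            if nz <= 0.0 or nz >= wall_l:
                continue
            de += _wca_r2(nz * nz, sigma, eps) - _wca_r2(oz * oz, sigma, eps)
            dn = wall_l - nz
            do = wall_l - oz
            de += _wca_r2(dn * dn, sigma, eps) - _wca_r2(do * do, sigma, eps)
        if de <= 0.0 or (de < 700.0 and np.random.random() < math.exp(-beta * de)):
            pos[i, 0], pos[i, 1], pos[i, 2] = nx, ny, nz
            acc += 1
    return acc, att
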