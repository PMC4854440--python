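"""Numba force kernels.

All heavy per-step work lives here: nonbonded DPD forces through a linked
cell list (or an all-pairs reference path), harmonic bond and cosine
angle forces, and the conservative+bonded virial.

Two determinism constraints shape the code:

* the per-pair random number zeta_ij is generated by a counter-based hash
  of ``(stream, i, j)`` so it depends only on the pair identity and the
  force-evaluation counter, never on enumeration order, and is symmetric
  under i<->j by construction (i < j always);
* pairs are processed for each bead ``i`` in ascending order of ``j``, so
  the floating-point accumulation order of the cell-list path matches the
  all-pairs path exactly and the two give bitwise-identical forces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT3 = 1.7320508075688772
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53

_C0 = np.uint64(0x9E3779B97F4A7C15)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S32 = np.uint64(32)
_S11 = np.uint64(11)

# forward half of the 27-cell stencil (excluding the origin)
_STENCIL = np.array(
    [[ox, oy, oz]
     for oz in (-1, 0, 1) for oy in (-1, 0, 1) for ox in (-1, 0, 1)
     if (oz > 0) or (oz == 0 and oy > 0) or (oz == 0 and oy == 0 and ox > 0)],
    dtype=np.int64,
)


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = x + _C0
    z = (z ^ (z >> _S30)) * _C1
    z = (z ^ (z >> _S27)) * _C2
    return z ^ (z >> _S31)


@njit(cache=True, inline="always")
def _pair_zeta(stream, i, j):
    """Uniform random number on [-sqrt(3), sqrt(3)] (zero mean, unit var)."""
    h = _splitmix64(stream ^ (np.uint64(i) << _S32) ^ np.uint64(j))
    u = np.float64(h >> _S11) * _INV_2_53
    return _SQRT3 * (2.0 * u - 1.0)


def rng_stream(seed: int, counter: int) -> np.uint64:
    """Stream key for one force evaluation, derived from (seed, counter)."""
    mask = (1 << 64) - 1
    z = ((seed & 0xFFFFFFFF) << 32 | (counter & 0xFFFFFFFF)) & mask
    z = (z + 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z ^= z >> 31
    return np.uint64(z)


# NOTE: the DPD pair interaction appears twice below (pair-list and
# all-pairs enumeration) with the inner body kept textually identical;
# sharing a helper function costs ~5x in call overhead under numba, and
# identical expressions are what guarantees the two paths agree bitwise.

@njit(cache=True)
def _nonbonded_all_pairs(pos, vel, box, tidx, aij, gij, sij,
                         inv_sqrt_dt, stream, forces, virial):
    n = pos.shape[0]
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            if dx > hx:
                dx -= Lx
            elif dx < -hx:
                dx += Lx
            dy = pos[i, 1] - pos[j, 1]
            if dy > hy:
                dy -= Ly
            elif dy < -hy:
                dy += Ly
            dz = pos[i, 2] - pos[j, 2]
            if dz > hz:
                dz -= Lz
            elif dz < -hz:
                dz += Lz
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= 1.0 or r2 <= 1.0e-24:
                continue
            r = np.sqrt(r2)
            omega = 1.0 - r
            ti = tidx[i]
            tj = tidx[j]
            inv_r = 1.0 / r
            ex = dx * inv_r
            ey = dy * inv_r
            ez = dz * inv_r
            vdot = (ex * (vel[i, 0] - vel[j, 0])
                    + ey * (vel[i, 1] - vel[j, 1])
                    + ez * (vel[i, 2] - vel[j, 2]))
            fc = aij[ti, tj] * omega
            zeta = _pair_zeta(stream, i, j)
            fr = sij[ti, tj] * omega * zeta * inv_sqrt_dt
            fd = -gij[ti, tj] * omega * omega * vdot
            fmag = fc + fr + fd
            fx = fmag * ex
            fy = fmag * ey
            fz = fmag * ez
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            # conservative part only enters the virial
            virial[0] += dx * (fc * ex)
            virial[1] += dy * (fc * ey)
            virial[2] += dz * (fc * ez)


@njit(cache=True)
def _accumulate_pair_list(pair_i, pair_j, pos, vel, box, tidx, aij, gij, sij,
                          inv_sqrt_dt, stream, forces, virial):
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    for q in range(pair_i.shape[0]):
        i = pair_i[q]
        j = pair_j[q]
        dx = pos[i, 0] - pos[j, 0]
        if dx > hx:
            dx -= Lx
        elif dx < -hx:
            dx += Lx
        dy = pos[i, 1] - pos[j, 1]
        if dy > hy:
            dy -= Ly
        elif dy < -hy:
            dy += Ly
        dz = pos[i, 2] - pos[j, 2]
        if dz > hz:
            dz -= Lz
        elif dz < -hz:
            dz += Lz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= 1.0 or r2 <= 1.0e-24:
            continue
        r = np.sqrt(r2)
        omega = 1.0 - r
        ti = tidx[i]
        tj = tidx[j]
        inv_r = 1.0 / r
        ex = dx * inv_r
        ey = dy * inv_r
        ez = dz * inv_r
        vdot = (ex * (vel[i, 0] - vel[j, 0])
                + ey * (vel[i, 1] - vel[j, 1])
                + ez * (vel[i, 2] - vel[j, 2]))
        fc = aij[ti, tj] * omega
        zeta = _pair_zeta(stream, i, j)
        fr = sij[ti, tj] * omega * zeta * inv_sqrt_dt
        fd = -gij[ti, tj] * omega * omega * vdot
        fmag = fc + fr + fd
        fx = fmag * ex
        fy = fmag * ey
        fz = fmag * ez
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        # conservative part only enters the virial
        virial[0] += dx * (fc * ex)
        virial[1] += dy * (fc * ey)
        virial[2] += dz * (fc * ez)


@njit(cache=True, fastmath=True)
def _build_pair_list(pos, box, rlist, cap):
    # fastmath is safe here: the list cutoff carries slack and every
    # candidate is re-checked with exact arithmetic at accumulation time
    # Binned candidate search: beads are gathered into cell-sorted SoA
    # coordinate arrays and each cell is paired with itself plus a 13-cell
    # half stencil whose periodic image shift is constant per cell pair, so
    # the inner distance loop is branch-free.  Candidates pass a slightly
    # enlarged list cutoff and are returned in canonical ascending (i, j)
    # order; the exact r < 1 check happens at accumulation time, making
    # the result bitwise identical to the all-pairs reference.
    n = pos.shape[0]
    ncx = max(1, int(box[0] / rlist))
    ncy = max(1, int(box[1] / rlist))
    ncz = max(1, int(box[2] / rlist))
    ncells = ncx * ncy * ncz
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ncells + 1, dtype=np.int64)
    for i in range(n):
        # clamp both ends: guards rounding at L and non-finite coordinates
        ix = int(pos[i, 0] / box[0] * ncx)
        iy = int(pos[i, 1] / box[1] * ncy)
        iz = int(pos[i, 2] / box[2] * ncz)
        if ix >= ncx:
            ix = ncx - 1
        elif ix < 0:
            ix = 0
        if iy >= ncy:
            iy = ncy - 1
        elif iy < 0:
            iy = 0
        if iz >= ncz:
            iz = ncz - 1
        elif iz < 0:
            iz = 0
        c = (ix * ncy + iy) * ncz + iz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncells):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    xs = np.empty(n)
    ys = np.empty(n)
    zs = np.empty(n)
    for s in range(n):
        i = order[s]
        xs[s] = pos[i, 0]
        ys[s] = pos[i, 1]
        zs[s] = pos[i, 2]

    cutoff2 = rlist * rlist + 1.0e-9  # slack: exact re-check at accumulation
    cand_i = np.empty(cap, dtype=np.int64)
    cand_j = np.empty(cap, dtype=np.int64)
    m = 0
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                ca = (cx * ncy + cy) * ncz + cz
                a0 = counts[ca]
                a1 = counts[ca + 1]
                # self cell
                for sa in range(a0, a1):
                    xi = xs[sa]
                    yi = ys[sa]
                    zi = zs[sa]
                    for sb in range(sa + 1, a1):
                        dx = xi - xs[sb]
                        dy = yi - ys[sb]
                        dz = zi - zs[sb]
                        if dx * dx + dy * dy + dz * dz < cutoff2:
                            if m == cap:
                                return cand_i[:0], cand_j[:0], False
                            cand_i[m] = order[sa]
                            cand_j[m] = order[sb]
                            m += 1
                # half stencil (13 forward neighbours)
                for st in range(13):
                    ox = _STENCIL[st, 0]
                    oy = _STENCIL[st, 1]
                    oz = _STENCIL[st, 2]
                    bx = cx + ox
                    by = cy + oy
                    bz = cz + oz
                    shx = 0.0
                    shy = 0.0
                    shz = 0.0
                    if bx < 0:
                        bx += ncx
                        shx = -box[0]
                    elif bx >= ncx:
                        bx -= ncx
                        shx = box[0]
                    if by < 0:
                        by += ncy
                        shy = -box[1]
                    elif by >= ncy:
                        by -= ncy
                        shy = box[1]
                    if bz < 0:
                        bz += ncz
                        shz = -box[2]
                    elif bz >= ncz:
                        bz -= ncz
                        shz = box[2]
                    cb = (bx * ncy + by) * ncz + bz
                    b0 = counts[cb]
                    b1 = counts[cb + 1]
                    for sa in range(a0, a1):
                        xi = xs[sa] - shx
                        yi = ys[sa] - shy
                        zi = zs[sa] - shz
                        for sb in range(b0, b1):
                            dx = xi - xs[sb]
                            dy = yi - ys[sb]
                            dz = zi - zs[sb]
                            if dx * dx + dy * dy + dz * dz < cutoff2:
                                if m == cap:
                                    return cand_i[:0], cand_j[:0], False
                                cand_i[m] = order[sa]
                                cand_j[m] = order[sb]
                                m += 1

    # canonical ordering: i < j, bucketed by i, ascending j inside buckets
    head = np.zeros(n + 1, dtype=np.int64)
    for q in range(m):
        a = cand_i[q]
        b = cand_j[q]
        if a > b:
            cand_i[q] = b
            cand_j[q] = a
            a = b
        head[a + 1] += 1
    for i in range(n):
        head[i + 1] += head[i]
    jbuf = np.empty(m, dtype=np.int64)
    fill2 = head[:-1].copy()
    for q in range(m):
        a = cand_i[q]
        jbuf[fill2[a]] = cand_j[q]
        fill2[a] += 1
    for i in range(n):
        s0 = head[i]
        s1 = head[i + 1]
        for a in range(s0 + 1, s1):
            key = jbuf[a]
            b = a - 1
            while b >= s0 and jbuf[b] > key:
                jbuf[b + 1] = jbuf[b]
                b -= 1
            jbuf[b + 1] = key
    ibuf = np.empty(m, dtype=np.int64)
    for i in range(n):
        for a in range(head[i], head[i + 1]):
            ibuf[a] = i
    return ibuf, jbuf, True


@njit(cache=True)
def _bonded(pos, box, bond_index, bond_params, angle_index, angle_params,
            forces, virial):
    nb = bond_index.shape[0]
    for b in range(nb):
        i = bond_index[b, 0]
        j = bond_index[b, 1]
        L0 = bond_params[b, 0]
        K2 = bond_params[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1.0e-12:
            continue
        fmag = -K2 * (r - L0) / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += dx * fx
        virial[1] += dy * fy
        virial[2] += dz * fz

    na = angle_index.shape[0]
    for t in range(na):
        i = angle_index[t, 0]
        j = angle_index[t, 1]
        k = angle_index[t, 2]
        t0 = angle_params[t, 0]
        K3 = angle_params[t, 1]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ux -= box[0] * np.rint(ux / box[0])
        uy -= box[1] * np.rint(uy / box[1])
        uz -= box[2] * np.rint(uz / box[2])
        vx -= box[0] * np.rint(vx / box[0])
        vy -= box[1] * np.rint(vy / box[1])
        vz -= box[2] * np.rint(vz / box[2])
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if ru < 1.0e-12 or rv < 1.0e-12:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s = np.sqrt(1.0 - c * c)
        if s < 1.0e-8:
            s = 1.0e-8  # collinear guard
        theta = np.arccos(c)
        coef = K3 * np.sin(theta - t0) / s
        inv_uv = 1.0 / (ru * rv)
        inv_u2 = 1.0 / (ru * ru)
        inv_v2 = 1.0 / (rv * rv)
        fix = coef * (vx * inv_uv - c * ux * inv_u2)
        fiy = coef * (vy * inv_uv - c * uy * inv_u2)
        fiz = coef * (vz * inv_uv - c * uz * inv_u2)
        fkx = coef * (ux * inv_uv - c * vx * inv_v2)
        fky = coef * (uy * inv_uv - c * vy * inv_v2)
        fkz = coef * (uz * inv_uv - c * vz * inv_v2)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        virial[0] += ux * fix + vx * fkx
        virial[1] += uy * fiy + vy * fky
        virial[2] += uz * fiz + vz * fkz


@njit(cache=True)
def bonded_energy(pos, box, bond_index, bond_params, angle_index, angle_params):
    """Total bonded potential energy (for force-consistency checks)."""
    e = 0.0
    for b in range(bond_index.shape[0]):
        i = bond_index[b, 0]
        j = bond_index[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - bond_params[b, 0]
        e += 0.5 * bond_params[b, 1] * d * d
    for t in range(angle_index.shape[0]):
        i = angle_index[t, 0]
        j = angle_index[t, 1]
        k = angle_index[t, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ux -= box[0] * np.rint(ux / box[0])
        uy -= box[1] * np.rint(uy / box[1])
        uz -= box[2] * np.rint(uz / box[2])
        vx -= box[0] * np.rint(vx / box[0])
        vy -= box[1] * np.rint(vy / box[1])
        vz -= box[2] * np.rint(vz / box[2])
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        e += angle_params[t, 1] * (1.0 - np.cos(theta - angle_params[t, 0]))
    return e


def build_pair_list(pos, box, rlist=1.4):
    """Candidate pair list (canonical ascending order) within ``rlist``.

    Falls back to the exhaustive i<j list when any box edge admits fewer
    than three cells of edge >= ``rlist``; either way the list is a
    superset of the interacting pairs, and remains valid until some bead
    moves more than ``(rlist - 1)/2``.
    """
    can_cell = all(int(box[a] / rlist) >= 3 for a in range(3))
    if can_cell:
        n = pos.shape[0]
        cap = 64 + int(14.0 * rlist**3 * n)
        while True:
            pi, pj, ok = _build_pair_list(pos, box, rlist, cap)
            if ok:
                return pi, pj
            cap *= 2
    n = pos.shape[0]
    iu = np.triu_indices(n, k=1)
    return iu[0].astype(np.int64), iu[1].astype(np.int64)


def compute_forces(pos, vel, box, tidx, aij, gij, sij, dt, stream,
                   use_cell_list=True, pairs=None):
    """Evaluate total nonbonded DPD forces and the conservative virial.

    With ``use_cell_list`` the nonbonded pairs come from a binned
    candidate list (``pairs`` may pass a prebuilt one); otherwise an
    all-pairs double loop runs.  Both paths apply the exact r < 1 check
    pair by pair in the same order, so they agree bitwise.  Returns
    ``(forces, virial)`` where ``virial`` is the diagonal (W_xx, W_yy,
    W_zz) excluding random and dissipative contributions.

    Bonded terms are evaluated by the caller via :func:`add_bonded`.
    """
    forces = np.zeros_like(pos)
    virial = np.zeros(3)
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    if use_cell_list:
        if pairs is None:
            pairs = build_pair_list(pos, box)
        _accumulate_pair_list(pairs[0], pairs[1], pos, vel, box, tidx,
                              aij, gij, sij, inv_sqrt_dt, stream,
                              forces, virial)
    else:
        _nonbonded_all_pairs(pos, vel, box, tidx, aij, gij, sij,
                             inv_sqrt_dt, stream, forces, virial)
    return forces, virial


def add_bonded(pos, box, bond_index, bond_params, angle_index, angle_params,
               forces, virial):
    """Accumulate bond and angle forces and their virial in place."""
    if bond_index.shape[0] or angle_index.shape[0]:
        _bonded(pos, box, bond_index, bond_params, angle_index, angle_params,
                forces, virial)
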