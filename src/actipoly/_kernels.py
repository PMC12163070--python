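"""Numba kernels: neighbor lists, force evaluation, Langevin integration.

All kernels work on contiguous float64 arrays in reduced units and assume a
cubic periodic box with beads stored chain-contiguous (chain c occupies rows
c*Np .. (c+1)*Np-1 in rank order).  Nonbonded pairs go through a Verlet list
(cutoff + skin) rebuilt from a linked-cell grid whenever accumulated
displacements could invalidate it.  The pure-numpy implementations in
:mod:`actipoly.forcefield` are the readable reference; the test suite checks
both routes against each other to machine precision.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RC_WCA = 2.0 ** (1.0 / 6.0)
SKIN = 0.35

# accumulator layout produced by compute_forces:
#   acc[0:6]  raw virial sums  sum F^a r^b  for (xx, yy, zz, xy, xz, yz)
#   acc[6]    pair (WCA or soft-core) energy
#   acc[7]    FENE energy
#   acc[8]    bending energy
#   acc[9]    minimum listed pair distance (>= cutoff means "none closer")
#   acc[10]   maximum bond length
#   acc[11]   minimum bond length
ACC_LEN = 12

STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_NOT_FINITE = 2
STATUS_LIST_OVERFLOW = 3


@njit(cache=True, inline="always")
def _minimg(dx, box):
    # valid for differences of wrapped coordinates (|dx| < box)
    if dx > 0.5 * box:
        return dx - box
    if dx < -0.5 * box:
        return dx + box
    return dx


@njit(cache=True)
def build_pairs(pos, box, rlist, pair_i, pair_j):
    """Fill (pair_i, pair_j) with all pairs within ``rlist`` (minimum image).

    Uses a linked-cell grid when the box accommodates >= 3 cells, otherwise a
    brute-force double loop.  Returns the pair count, or -1 on capacity
    overflow.
    """
    n = pos.shape[0]
    cap = pair_i.shape[0]
    half = 0.5 * box
    r2max = rlist * rlist
    npairs = 0
    ncell = int(box / rlist)
    # cells only pay off when the grid is small relative to the bead count
    if ncell < 3 or n < 32 or ncell * ncell * ncell > 8 * n + 1024:
        for i in range(n - 1):
            xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
            for j in range(i + 1, n):
                dx = xi - pos[j, 0]
                if dx > half:
                    dx -= box
                elif dx < -half:
                    dx += box
                dy = yi - pos[j, 1]
                if dy > half:
                    dy -= box
                elif dy < -half:
                    dy += box
                dz = zi - pos[j, 2]
                if dz > half:
                    dz -= box
                elif dz < -half:
                    dz += box
                if dx * dx + dy * dy + dz * dz < r2max:
                    if npairs >= cap:
                        return -1
                    pair_i[npairs] = i
                    pair_j[npairs] = j
                    npairs += 1
        return npairs
    cell_sz = box / ncell
    ntot = ncell * ncell * ncell
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ntot + 1, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell_sz)
        cy = int(pos[i, 1] / cell_sz)
        cz = int(pos[i, 2] / cell_sz)
        if cx >= ncell:
            cx = ncell - 1
        elif cx < 0:
            cx = 0
        if cy >= ncell:
            cy = ncell - 1
        elif cy < 0:
            cy = 0
        if cz >= ncell:
            cz = ncell - 1
        elif cz < 0:
            cz = 0
        c = (cx * ncell + cy) * ncell + cz
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ntot):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:ntot].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                if count[c] == count[c + 1]:
                    continue
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        for oz in range(-1, 2):
                            nx = cx + ox
                            if nx < 0:
                                nx += ncell
                            elif nx >= ncell:
                                nx -= ncell
                            ny = cy + oy
                            if ny < 0:
                                ny += ncell
                            elif ny >= ncell:
                                ny -= ncell
                            nz = cz + oz
                            if nz < 0:
                                nz += ncell
                            elif nz >= ncell:
                                nz -= ncell
                            c2 = (nx * ncell + ny) * ncell + nz
                            if c2 < c:
                                continue
                            same = c2 == c
                            for ii in range(count[c], count[c + 1]):
                                i = order[ii]
                                xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
                                j0 = ii + 1 if same else count[c2]
                                for jj in range(j0, count[c2 + 1]):
                                    j = order[jj]
                                    dx = xi - pos[j, 0]
                                    if dx > half:
                                        dx -= box
                                    elif dx < -half:
                                        dx += box
                                    dy = yi - pos[j, 1]
                                    if dy > half:
                                        dy -= box
                                    elif dy < -half:
                                        dy += box
                                    dz = zi - pos[j, 2]
                                    if dz > half:
                                        dz -= box
                                    elif dz < -half:
                                        dz += box
                                    if dx * dx + dy * dy + dz * dz < r2max:
                                        if npairs >= cap:
                                            return -1
                                        pair_i[npairs] = i
                                        pair_j[npairs] = j
                                        npairs += 1
    return npairs


@njit(cache=True)
def compute_forces(
    pos, box, Np, eps_wca, k_fene, R0, kappa, Fp,
    use_soft, soft_a, include_active_stress,
    pair_i, pair_j, npairs, f, acc,
):
    """Total deterministic forces plus virial/energy accumulators.

    Nonbonded interactions run over the supplied pair list.  Returns
    STATUS_OK, or STATUS_OVERSTRETCH if a FENE bond reached R0.
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for k in range(ACC_LEN):
        acc[k] = 0.0
    acc[9] = 1e30
    acc[11] = 1e30

    half = 0.5 * box
    rc = RC_WCA
    rc2 = rc * rc
    if eps_wca != 0.0 or use_soft:
        s0 = s1 = s2 = s3 = s4 = s5 = 0.0
        epair = 0.0
        minr = 1e30
        pi_rc = np.pi / rc
        for p in range(npairs):
            i = pair_i[p]
            j = pair_j[p]
            dx = pos[i, 0] - pos[j, 0]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            dy = pos[i, 1] - pos[j, 1]
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            dz = pos[i, 2] - pos[j, 2]
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            r = np.sqrt(r2)
            if r < minr:
                minr = r
            if use_soft:
                if r < 1e-12:
                    epair += 2.0 * soft_a
                    continue
                fmag = soft_a * pi_rc * np.sin(pi_rc * r) / r
                epair += soft_a * (1.0 + np.cos(pi_rc * r))
            else:
                if r2 < 1e-24:
                    epair += 1e300
                    continue
                sr2 = 1.0 / r2
                sr6 = sr2 * sr2 * sr2
                fmag = 24.0 * eps_wca * (2.0 * sr6 * sr6 - sr6) * sr2
                epair += 4.0 * eps_wca * (sr6 * sr6 - sr6) + eps_wca
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            f[i, 0] += fx
            f[i, 1] += fy
            f[i, 2] += fz
            f[j, 0] -= fx
            f[j, 1] -= fy
            f[j, 2] -= fz
            # both ordered entries of the printed virial double sum
            s0 += 2.0 * fx * dx
            s1 += 2.0 * fy * dy
            s2 += 2.0 * fz * dz
            s3 += 2.0 * fx * dy
            s4 += 2.0 * fx * dz
            s5 += 2.0 * fy * dz
        acc[0] += s0
        acc[1] += s1
        acc[2] += s2
        acc[3] += s3
        acc[4] += s4
        acc[5] += s5
        acc[6] = epair
        acc[9] = minr

    nchain = n // Np
    r02 = R0 * R0
    s0 = s1 = s2 = s3 = s4 = s5 = 0.0
    e_fene = 0.0
    e_bend = 0.0
    bmax = 0.0
    bmin = 1e30
    for c in range(nchain):
        base = c * Np
        for k in range(Np - 1):
            i = base + k
            j = i + 1
            dx = _minimg(pos[i, 0] - pos[j, 0], box)
            dy = _minimg(pos[i, 1] - pos[j, 1], box)
            dz = _minimg(pos[i, 2] - pos[j, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r > bmax:
                bmax = r
            if r < bmin:
                bmin = r
            if k_fene != 0.0:
                if r2 >= r02:
                    acc[10] = r
                    return STATUS_OVERSTRETCH
                fmag = -k_fene / (1.0 - r2 / r02)
                fx = fmag * dx
                fy = fmag * dy
                fz = fmag * dz
                f[i, 0] += fx
                f[i, 1] += fy
                f[i, 2] += fz
                f[j, 0] -= fx
                f[j, 1] -= fy
                f[j, 2] -= fz
                s0 += 2.0 * fx * dx
                s1 += 2.0 * fy * dy
                s2 += 2.0 * fz * dz
                s3 += 2.0 * fx * dy
                s4 += 2.0 * fx * dz
                s5 += 2.0 * fy * dz
                e_fene += -0.5 * k_fene * r02 * np.log(1.0 - r2 / r02)
        if kappa != 0.0 and Np >= 3:
            for k in range(Np - 2):
                i1 = base + k
                i2 = i1 + 1
                i3 = i1 + 2
                ux = _minimg(pos[i2, 0] - pos[i1, 0], box)
                uy = _minimg(pos[i2, 1] - pos[i1, 1], box)
                uz = _minimg(pos[i2, 2] - pos[i1, 2], box)
                vx = _minimg(pos[i3, 0] - pos[i2, 0], box)
                vy = _minimg(pos[i3, 1] - pos[i2, 1], box)
                vz = _minimg(pos[i3, 2] - pos[i2, 2], box)
                bu = np.sqrt(ux * ux + uy * uy + uz * uz)
                bv = np.sqrt(vx * vx + vy * vy + vz * vz)
                if bu < 1e-12 or bv < 1e-12:
                    continue
                tux, tuy, tuz = ux / bu, uy / bu, uz / bu
                tvx, tvy, tvz = vx / bv, vy / bv, vz / bv
                cth = tux * tvx + tuy * tvy + tuz * tvz
                e_bend += kappa * (1.0 - cth)
                # dc/du = (tv - c tu)/|u| ; dc/dv = (tu - c tv)/|v|
                f1x = -kappa * (tvx - cth * tux) / bu
                f1y = -kappa * (tvy - cth * tuy) / bu
                f1z = -kappa * (tvz - cth * tuz) / bu
                f3x = kappa * (tux - cth * tvx) / bv
                f3y = kappa * (tuy - cth * tvy) / bv
                f3z = kappa * (tuz - cth * tvz) / bv
                f[i1, 0] += f1x
                f[i1, 1] += f1y
                f[i1, 2] += f1z
                f[i3, 0] += f3x
                f[i3, 1] += f3y
                f[i3, 2] += f3z
                f[i2, 0] -= f1x + f3x
                f[i2, 1] -= f1y + f3y
                f[i2, 2] -= f1z + f3z
                # three-body virial: F1 (x) (r1-r2) + F3 (x) (r3-r2)
                s0 += 2.0 * (f1x * (-ux) + f3x * vx)
                s1 += 2.0 * (f1y * (-uy) + f3y * vy)
                s2 += 2.0 * (f1z * (-uz) + f3z * vz)
                s3 += 2.0 * (f1x * (-uy) + f3x * vy)
                s4 += 2.0 * (f1x * (-uz) + f3x * vz)
                s5 += 2.0 * (f1y * (-uz) + f3y * vz)
        # tangential active force, constant magnitude Fp per bead
        if Fp != 0.0:
            for k in range(Np):
                i = base + k
                uxp = uyp = uzp = 0.0
                uxn = uyn = uzn = 0.0
                bp = 0.0
                bn = 0.0
                if k > 0:
                    uxp = _minimg(pos[i, 0] - pos[i - 1, 0], box)
                    uyp = _minimg(pos[i, 1] - pos[i - 1, 1], box)
                    uzp = _minimg(pos[i, 2] - pos[i - 1, 2], box)
                    bp = np.sqrt(uxp * uxp + uyp * uyp + uzp * uzp)
                if k < Np - 1:
                    uxn = _minimg(pos[i + 1, 0] - pos[i, 0], box)
                    uyn = _minimg(pos[i + 1, 1] - pos[i, 1], box)
                    uzn = _minimg(pos[i + 1, 2] - pos[i, 2], box)
                    bn = np.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                if k == 0:
                    if bn < 1e-12:
                        continue
                    sx, sy, sz = uxn / bn, uyn / bn, uzn / bn
                    snorm = 1.0
                elif k == Np - 1:
                    if bp < 1e-12:
                        continue
                    sx, sy, sz = uxp / bp, uyp / bp, uzp / bp
                    snorm = 1.0
                else:
                    if bp < 1e-12 or bn < 1e-12:
                        continue
                    sx = uxp / bp + uxn / bn
                    sy = uyp / bp + uyn / bn
                    sz = uzp / bp + uzn / bn
                    snorm = np.sqrt(sx * sx + sy * sy + sz * sz)
                    if snorm < 1e-8:
                        continue
                    sx /= snorm
                    sy /= snorm
                    sz /= snorm
                f[i, 0] += Fp * sx
                f[i, 1] += Fp * sy
                f[i, 2] += Fp * sz
                if include_active_stress:
                    # attribute each tangent piece to its generating bond pair
                    scale = Fp / snorm if (0 < k < Np - 1) else Fp
                    if k > 0:
                        gx = scale * uxp / bp
                        gy = scale * uyp / bp
                        gz = scale * uzp / bp
                        s0 += gx * uxp
                        s1 += gy * uyp
                        s2 += gz * uzp
                        s3 += gx * uyp
                        s4 += gx * uzp
                        s5 += gy * uzp
                    if k < Np - 1:
                        gx = scale * uxn / bn
                        gy = scale * uyn / bn
                        gz = scale * uzn / bn
                        s0 += gx * (-uxn)
                        s1 += gy * (-uyn)
                        s2 += gz * (-uzn)
                        s3 += gx * (-uyn)
                        s4 += gx * (-uzn)
                        s5 += gy * (-uzn)
    acc[0] += s0
    acc[1] += s1
    acc[2] += s2
    acc[3] += s3
    acc[4] += s4
    acc[5] += s5
    acc[7] = e_fene
    acc[8] = e_bend
    acc[10] = bmax
    acc[11] = bmin
    return STATUS_OK


@njit(cache=True)
def forces_once(pos, box, Np, eps_wca, k_fene, R0, kappa, Fp,
                use_soft, soft_a, include_active_stress, f, acc):
    """Convenience single-shot force evaluation (builds its own pair list)."""
    n = pos.shape[0]
    cap = max(64 * n, 4096)
    pair_i = np.empty(cap, dtype=np.int32)
    pair_j = np.empty(cap, dtype=np.int32)
    npairs = 0
    if eps_wca != 0.0 or use_soft:
        npairs = build_pairs(pos, box, RC_WCA, pair_i, pair_j)
        if npairs < 0:
            return STATUS_LIST_OVERFLOW
    return compute_forces(
        pos, box, Np, eps_wca, k_fene, R0, kappa, Fp,
        use_soft, soft_a, include_active_stress,
        pair_i, pair_j, npairs, f, acc,
    )


@njit(cache=True)
def run_bd(
    pos, img, box, Np, dt, zeta, kT,
    eps_wca, k_fene, R0, kappa, Fp,
    use_soft, soft_a0, soft_a1, ramp_total, step0, include_active_stress,
    n_steps, stress_stride, noise, out,
):
    """Euler-Maruyama integration of the overdamped Langevin equation.

    r <- r + (dt/zeta)(F_det + F_p) + xi with xi = sqrt(2 (kT/zeta) dt) * g,
    ``noise`` holding the (n_steps, n, 3) standard normals g for this block.
    When ``stress_stride > 0`` the configuration at global step ``step0 + s``
    (before the update) is sampled whenever it divides the stride and a row
    [global_step, sxx, syy, szz, sxy, sxz, syz, e_pair, e_fene, e_bend,
    maxbond, minpair] is written to ``out``.  Under ``use_soft`` the capped
    amplitude ramps linearly from soft_a0 to soft_a1 over ``ramp_total``
    global steps.  The Verlet list (skin ``SKIN``) is rebuilt whenever the
    largest accumulated displacement exceeds half the skin.

    Returns (status, step_reached_in_block, n_rows).
    """
    n = pos.shape[0]
    f = np.empty((n, 3), dtype=np.float64)
    acc = np.empty(ACC_LEN, dtype=np.float64)
    vol = box * box * box
    amp = np.sqrt(2.0 * (kT / zeta) * dt)
    mob = dt / zeta
    nonbonded = eps_wca != 0.0 or use_soft
    rlist = RC_WCA + SKIN
    cap = max(96 * n, 8192)
    pair_i = np.empty(cap, dtype=np.int32)
    pair_j = np.empty(cap, dtype=np.int32)
    npairs = 0
    disp = np.zeros((n, 3), dtype=np.float64)
    need_build = True
    half_skin2 = (0.5 * SKIN) ** 2
    nrows = 0
    for s in range(n_steps):
        if use_soft and ramp_total > 1:
            frac = (step0 + s) / (ramp_total - 1.0)
            if frac > 1.0:
                frac = 1.0
            soft_a = soft_a0 + (soft_a1 - soft_a0) * frac
        else:
            soft_a = soft_a1
        if nonbonded and need_build:
            npairs = build_pairs(pos, box, rlist, pair_i, pair_j)
            if npairs < 0:
                return STATUS_LIST_OVERFLOW, s, nrows
            for i in range(n):
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                disp[i, 2] = 0.0
            need_build = False
        status = compute_forces(
            pos, box, Np, eps_wca, k_fene, R0, kappa, Fp,
            use_soft, soft_a, include_active_stress,
            pair_i, pair_j, npairs, f, acc,
        )
        if status != STATUS_OK:
            return status, s, nrows
        if stress_stride > 0 and (step0 + s) % stress_stride == 0:
            out[nrows, 0] = step0 + s
            for k in range(6):
                out[nrows, 1 + k] = -acc[k] / (2.0 * vol)
            out[nrows, 7] = acc[6]
            out[nrows, 8] = acc[7]
            out[nrows, 9] = acc[8]
            out[nrows, 10] = acc[10]
            out[nrows, 11] = min(acc[9], RC_WCA)
            if not np.isfinite(out[nrows, 1] + out[nrows, 4]):
                return STATUS_NOT_FINITE, s, nrows
            nrows += 1
        maxd2 = 0.0
        for i in range(n):
            ddx = mob * f[i, 0] + amp * noise[s, i, 0]
            ddy = mob * f[i, 1] + amp * noise[s, i, 1]
            ddz = mob * f[i, 2] + amp * noise[s, i, 2]
            dx = disp[i, 0] + ddx
            dy = disp[i, 1] + ddy
            dz = disp[i, 2] + ddz
            disp[i, 0] = dx
            disp[i, 1] = dy
            disp[i, 2] = dz
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
            x = pos[i, 0] + ddx
            if x >= box:
                x -= box
                img[i, 0] += 1
                if x >= box:
                    sh = np.floor(x / box)
                    x -= sh * box
                    img[i, 0] += np.int64(sh)
            elif x < 0.0:
                x += box
                img[i, 0] -= 1
                if x < 0.0:
                    sh = np.floor(x / box)
                    x -= sh * box
                    img[i, 0] += np.int64(sh)
            pos[i, 0] = x
            y = pos[i, 1] + ddy
            if y >= box:
                y -= box
                img[i, 1] += 1
                if y >= box:
                    sh = np.floor(y / box)
                    y -= sh * box
                    img[i, 1] += np.int64(sh)
            elif y < 0.0:
                y += box
                img[i, 1] -= 1
                if y < 0.0:
                    sh = np.floor(y / box)
                    y -= sh * box
                    img[i, 1] += np.int64(sh)
            pos[i, 1] = y
            z = pos[i, 2] + ddz
            if z >= box:
                z -= box
                img[i, 2] += 1
                if z >= box:
                    sh = np.floor(z / box)
                    z -= sh * box
                    img[i, 2] += np.int64(sh)
            elif z < 0.0:
                z += box
                img[i, 2] -= 1
                if z < 0.0:
                    sh = np.floor(z / box)
                    z -= sh * box
                    img[i, 2] += np.int64(sh)
            pos[i, 2] = z
        if maxd2 > half_skin2:
            need_build = True
    return STATUS_OK, n_steps, nrows


@njit(cache=True)
def min_pair_distance(pos, box):
    """Brute-force minimum pair distance under minimum image (diagnostics)."""
    n = pos.shape[0]
    best = 1e30
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _minimg(pos[i, 0] - pos[j, 0], box)
            dy = _minimg(pos[i, 1] - pos[j, 1], box)
            dz = _minimg(pos[i, 2] - pos[j, 2], box)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < best:
                best = r
    return best
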