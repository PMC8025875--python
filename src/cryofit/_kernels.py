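"""Numba-compiled numerical kernels.

Units: length Angstrom, energy kcal/mol, mass amu, time ps.  The
conversion factor between (kcal/mol/A)/amu and A/ps^2 is 418.4
(thermochemical calorie).  All kernels are deterministic: no random
numbers are drawn inside them.
"""
from __future__ import annotations

import numpy as np
from numba import njit

KCAL_TO_AKMA = 418.4  # a [A/ps^2] = F [kcal/mol/A] / m [amu] * KCAL_TO_AKMA
KB = 0.0019872041  # kcal/mol/K


# ---------------------------------------------------------------------------
# Go-model energy and forces
# ---------------------------------------------------------------------------

@njit(cache=True)
def _switch(r, r_on, r_off):
    """CHARMM switching function value and d/dr on [r_on, r_off]."""
    if r <= r_on:
        return 1.0, 0.0
    if r >= r_off:
        return 0.0, 0.0
    c2, o2, r2 = r_off * r_off, r_on * r_on, r * r
    denom = (c2 - o2) ** 3
    s = (c2 - r2) ** 2 * (c2 + 2.0 * r2 - 3.0 * o2) / denom
    ds = 12.0 * r * (c2 - r2) * (o2 - r2) / denom
    return s, ds


@njit(cache=True)
def go_energy_forces(pos,
                     bond_i, bond_j, bond_r0, bond_k,
                     ang_i, ang_j, ang_k, ang_t0, ang_ka,
                     dih_i, dih_j, dih_k, dih_l, dih_p0, dih_k1, dih_k3,
                     con_i, con_j, con_r0, con_eps,
                     nn_i, nn_j, nn_sigma, nn_eps,
                     cutoff, switch_on):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0

    # harmonic pseudo-bonds (usually SHAKE-constrained; kept for NVE use)
    for b in range(bond_i.shape[0]):
        i, j = bond_i[b], bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-6:
            return np.nan, forces
        dr = r - bond_r0[b]
        energy += bond_k[b] * dr * dr
        f = -2.0 * bond_k[b] * dr / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    # harmonic angles
    for a in range(ang_i.shape[0]):
        i, j, k = ang_i[a], ang_j[a], ang_k[a]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        nij = np.sqrt(ax * ax + ay * ay + az * az)
        nkj = np.sqrt(bx * bx + by * by + bz * bz)
        cs = (ax * bx + ay * by + az * bz) / (nij * nkj)
        if cs > 1.0:
            cs = 1.0
        if cs < -1.0:
            cs = -1.0
        theta = np.arccos(cs)
        dtheta = theta - ang_t0[a]
        energy += ang_ka[a] * dtheta * dtheta
        sn = np.sqrt(1.0 - cs * cs)
        if sn < 1e-8:
            sn = 1e-8
        coef = 2.0 * ang_ka[a] * dtheta / sn
        fix = coef / nij * (bx / nkj - cs * ax / nij)
        fiy = coef / nij * (by / nkj - cs * ay / nij)
        fiz = coef / nij * (bz / nkj - cs * az / nij)
        fkx = coef / nkj * (ax / nij - cs * bx / nkj)
        fky = coef / nkj * (ay / nij - cs * by / nkj)
        fkz = coef / nkj * (az / nij - cs * bz / nkj)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    # Fourier dihedrals: k1*(1-cos(phi-phi0)) + k3*(1-cos(3(phi-phi0)))
    for d in range(dih_i.shape[0]):
        i, j, k, l = dih_i[d], dih_j[d], dih_k[d], dih_l[d]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        mx = b1y * b2z - b1z * b2y
        my = b1z * b2x - b1x * b2z
        mz = b1x * b2y - b1y * b2x
        nx_ = b2y * b3z - b2z * b3y
        ny_ = b2z * b3x - b2x * b3z
        nz_ = b2x * b3y - b2y * b3x
        m2 = mx * mx + my * my + mz * mz
        n2 = nx_ * nx_ + ny_ * ny_ + nz_ * nz_
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if m2 < 1e-12 or n2 < 1e-12:
            continue
        x = mx * nx_ + my * ny_ + mz * nz_
        crx = my * nz_ - mz * ny_
        cry = mz * nx_ - mx * nz_
        crz = mx * ny_ - my * nx_
        y = (crx * b2x + cry * b2y + crz * b2z) / nb2
        phi = np.arctan2(y, x)
        dphi = phi - dih_p0[d]
        energy += dih_k1[d] * (1.0 - np.cos(dphi)) \
            + dih_k3[d] * (1.0 - np.cos(3.0 * dphi))
        dV = dih_k1[d] * np.sin(dphi) + 3.0 * dih_k3[d] * np.sin(3.0 * dphi)
        q1 = -nb2 / m2
        t1x, t1y, t1z = q1 * mx, q1 * my, q1 * mz
        q4 = nb2 / n2
        t4x, t4y, t4z = q4 * nx_, q4 * ny_, q4 * nz_
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        a2 = -(1.0 + c12)
        t2x = a2 * t1x + c32 * t4x
        t2y = a2 * t1y + c32 * t4y
        t2z = a2 * t1z + c32 * t4z
        t3x = c12 * t1x - (1.0 + c32) * t4x
        t3y = c12 * t1y - (1.0 + c32) * t4y
        t3z = c12 * t1z - (1.0 + c32) * t4z
        forces[i, 0] -= dV * t1x
        forces[i, 1] -= dV * t1y
        forces[i, 2] -= dV * t1z
        forces[j, 0] -= dV * t2x
        forces[j, 1] -= dV * t2y
        forces[j, 2] -= dV * t2z
        forces[k, 0] -= dV * t3x
        forces[k, 1] -= dV * t3y
        forces[k, 2] -= dV * t3z
        forces[l, 0] -= dV * t4x
        forces[l, 1] -= dV * t4y
        forces[l, 2] -= dV * t4z

    # native contacts: 12-10-6 well with minimum -eps at r0
    cut2 = cutoff * cutoff
    for c in range(con_i.shape[0]):
        i, j = con_i[c], con_j[c]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        if r2 < 1e-12:
            return np.nan, forces
        r = np.sqrt(r2)
        x2 = con_r0[c] * con_r0[c] / r2
        x6 = x2 * x2 * x2
        x10 = x6 * x2 * x2
        x12 = x6 * x6
        eps = con_eps[c]
        v = eps * (13.0 * x12 - 18.0 * x10 + 4.0 * x6)
        dv = -eps * (156.0 * x12 - 180.0 * x10 + 24.0 * x6) / r
        s, ds = _switch(r, switch_on, cutoff)
        energy += v * s
        fmag = -(dv * s + v * ds) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # non-native excluded volume: WCA-style repulsion with compact
    # support, eps*((s/r)^12 - 2(s/r)^6 + 1) for r < s, zero (value and
    # force) at and beyond r = s
    nns2 = nn_sigma * nn_sigma
    for c in range(nn_i.shape[0]):
        i, j = nn_i[c], nn_j[c]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= nns2:
            continue
        if r2 < 1e-12:
            return np.nan, forces
        x2 = nns2 / r2
        x6 = x2 * x2 * x2
        energy += nn_eps * (x6 * x6 - 2.0 * x6 + 1.0)
        fmag = 12.0 * nn_eps * x6 * (x6 - 1.0) / r2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    return energy, forces


# ---------------------------------------------------------------------------
# Density synthesis, cross-correlation and its gradient
# ---------------------------------------------------------------------------

@njit(cache=True)
def synthesize_map(pos, weights, origin, spacing, grid, sigma, rcut):
    """Add truncated Gaussians (one per bead) into ``grid`` (pre-zeroed).

    The Gaussian is evaluated separably per axis; truncation is
    spherical (contributions beyond ``rcut`` from the bead are zero).
    """
    nx, ny, nz = grid.shape
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    rcut2 = rcut * rcut
    nmax = max(nx, max(ny, nz))
    ex = np.empty(nmax)
    ey = np.empty(nmax)
    ez = np.empty(nmax)
    for b in range(pos.shape[0]):
        x, y, z = pos[b, 0], pos[b, 1], pos[b, 2]
        ilo = max(0, int(np.ceil((x - rcut - origin[0]) / spacing[0])))
        ihi = min(nx - 1, int(np.floor((x + rcut - origin[0]) / spacing[0])))
        jlo = max(0, int(np.ceil((y - rcut - origin[1]) / spacing[1])))
        jhi = min(ny - 1, int(np.floor((y + rcut - origin[1]) / spacing[1])))
        klo = max(0, int(np.ceil((z - rcut - origin[2]) / spacing[2])))
        khi = min(nz - 1, int(np.floor((z + rcut - origin[2]) / spacing[2])))
        w = weights[b]
        for i in range(ilo, ihi + 1):
            d = origin[0] + i * spacing[0] - x
            ex[i] = np.exp(-d * d * inv2s2)
        for j in range(jlo, jhi + 1):
            d = origin[1] + j * spacing[1] - y
            ey[j] = np.exp(-d * d * inv2s2)
        for k in range(klo, khi + 1):
            d = origin[2] + k * spacing[2] - z
            ez[k] = np.exp(-d * d * inv2s2)
        for i in range(ilo, ihi + 1):
            dx = origin[0] + i * spacing[0] - x
            dx2 = dx * dx
            wex = w * ex[i]
            for j in range(jlo, jhi + 1):
                dy = origin[1] + j * spacing[1] - y
                dxy2 = dx2 + dy * dy
                if dxy2 > rcut2:
                    continue
                wexy = wex * ey[j]
                for k in range(klo, khi + 1):
                    dz = origin[2] + k * spacing[2] - z
                    if dxy2 + dz * dz <= rcut2:
                        grid[i, j, k] += wexy * ez[k]


@njit(cache=True)
def cc_and_gradient(pos, weights, origin, spacing, target, t_sq_sum,
                    sigma, rcut, buf):
    """Cross-correlation of the synthesized map with ``target`` and its
    analytic gradient with respect to bead positions.

    ``buf`` is a scratch grid with the same shape as ``target``; it is
    zeroed and refilled here.  Returns (cc, grad); cc is NaN when the
    synthesized map is identically zero on the lattice.
    """
    nx, ny, nz = target.shape
    buf[:, :, :] = 0.0
    synthesize_map(pos, weights, origin, spacing, buf, sigma, rcut)
    a = 0.0  # sum t*c
    csq = 0.0  # sum c^2
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = buf[i, j, k]
                if c != 0.0:
                    a += target[i, j, k] * c
                    csq += c * c
    grad = np.zeros((pos.shape[0], 3))
    if csq <= 0.0 or t_sq_sum <= 0.0:
        return np.nan, grad
    sb = np.sqrt(t_sq_sum)
    sc = np.sqrt(csq)
    cc = a / (sb * sc)
    # dCC/dc_v = t_v/(sb*sc) - a*c_v/(sb*sc^3)
    p1 = 1.0 / (sb * sc)
    p2 = a / (sb * sc * csq)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    invs2 = 1.0 / (sigma * sigma)
    rcut2 = rcut * rcut
    nmax = max(nx, max(ny, nz))
    ex = np.empty(nmax)
    ey = np.empty(nmax)
    ez = np.empty(nmax)
    for b in range(pos.shape[0]):
        x, y, z = pos[b, 0], pos[b, 1], pos[b, 2]
        ilo = max(0, int(np.ceil((x - rcut - origin[0]) / spacing[0])))
        ihi = min(nx - 1, int(np.floor((x + rcut - origin[0]) / spacing[0])))
        jlo = max(0, int(np.ceil((y - rcut - origin[1]) / spacing[1])))
        jhi = min(ny - 1, int(np.floor((y + rcut - origin[1]) / spacing[1])))
        klo = max(0, int(np.ceil((z - rcut - origin[2]) / spacing[2])))
        khi = min(nz - 1, int(np.floor((z + rcut - origin[2]) / spacing[2])))
        w = weights[b]
        for i in range(ilo, ihi + 1):
            d = origin[0] + i * spacing[0] - x
            ex[i] = np.exp(-d * d * inv2s2)
        for j in range(jlo, jhi + 1):
            d = origin[1] + j * spacing[1] - y
            ey[j] = np.exp(-d * d * inv2s2)
        for k in range(klo, khi + 1):
            d = origin[2] + k * spacing[2] - z
            ez[k] = np.exp(-d * d * inv2s2)
        gx = 0.0
        gy = 0.0
        gz = 0.0
        for i in range(ilo, ihi + 1):
            dx = origin[0] + i * spacing[0] - x
            dx2 = dx * dx
            wex = w * ex[i]
            for j in range(jlo, jhi + 1):
                dy = origin[1] + j * spacing[1] - y
                dxy2 = dx2 + dy * dy
                if dxy2 > rcut2:
                    continue
                wexy = wex * ey[j]
                for k in range(klo, khi + 1):
                    dz = origin[2] + k * spacing[2] - z
                    if dxy2 + dz * dz <= rcut2:
                        g = wexy * ez[k]
                        # d g / d r_b = g * (x_v - r_b) / sigma^2
                        pref = (p1 * target[i, j, k] - p2 * buf[i, j, k]) * g * invs2
                        gx += pref * dx
                        gy += pref * dy
                        gz += pref * dz
        grad[b, 0] = gx
        grad[b, 1] = gy
        grad[b, 2] = gz
    return cc, grad


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

@njit(cache=True)
def shake(pos_new, pos_old, ci, cj, d0, invm, tol, maxiter):
    """Iteratively restore constrained distances (SHAKE, Gauss-Seidel).

    Returns the number of iterations used, or -1 on non-convergence.
    """
    nb = ci.shape[0]
    for it in range(maxiter):
        done = True
        for b in range(nb):
            i, j = ci[b], cj[b]
            sx = pos_new[i, 0] - pos_new[j, 0]
            sy = pos_new[i, 1] - pos_new[j, 1]
            sz = pos_new[i, 2] - pos_new[j, 2]
            s2 = sx * sx + sy * sy + sz * sz
            diff = s2 - d0[b] * d0[b]
            if abs(np.sqrt(s2) - d0[b]) > tol:
                rx = pos_old[i, 0] - pos_old[j, 0]
                ry = pos_old[i, 1] - pos_old[j, 1]
                rz = pos_old[i, 2] - pos_old[j, 2]
                sr = sx * rx + sy * ry + sz * rz
                if abs(sr) < 1e-12:
                    return -1
                g = diff / (2.0 * sr * (invm[i] + invm[j]))
                pos_new[i, 0] -= g * invm[i] * rx
                pos_new[i, 1] -= g * invm[i] * ry
                pos_new[i, 2] -= g * invm[i] * rz
                pos_new[j, 0] += g * invm[j] * rx
                pos_new[j, 1] += g * invm[j] * ry
                pos_new[j, 2] += g * invm[j] * rz
                done = False
        if done:
            return it + 1
    return -1


@njit(cache=True)
def rattle_velocities(pos, vel, ci, cj, invm, tol, maxiter):
    """Project velocity components along constrained bonds (RATTLE)."""
    nb = ci.shape[0]
    for it in range(maxiter):
        done = True
        for b in range(nb):
            i, j = ci[b], cj[b]
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            vx = vel[i, 0] - vel[j, 0]
            vy = vel[i, 1] - vel[j, 1]
            vz = vel[i, 2] - vel[j, 2]
            rv = rx * vx + ry * vy + rz * vz
            r2 = rx * rx + ry * ry + rz * rz
            if abs(rv) > tol * r2:
                kgam = rv / (r2 * (invm[i] + invm[j]))
                vel[i, 0] -= kgam * invm[i] * rx
                vel[i, 1] -= kgam * invm[i] * ry
                vel[i, 2] -= kgam * invm[i] * rz
                vel[j, 0] += kgam * invm[j] * rx
                vel[j, 1] += kgam * invm[j] * ry
                vel[j, 2] += kgam * invm[j] * rz
                done = False
        if done:
            return it + 1
    return -1


# ---------------------------------------------------------------------------
# Kabsch superposition (for targeted MD, inside the step loop)
# ---------------------------------------------------------------------------

@njit(cache=True)
def fit_reference(pos, ref):
    """Superpose ``ref`` onto ``pos`` (Kabsch); returns fitted reference
    coordinates and the best-fit RMSD."""
    n = pos.shape[0]
    cm = np.zeros(3)
    cr = np.zeros(3)
    for i in range(n):
        cm += pos[i]
        cr += ref[i]
    cm /= n
    cr /= n
    h = np.zeros((3, 3))
    for i in range(n):
        for a in range(3):
            for bb in range(3):
                h[a, bb] += (ref[i, a] - cr[a]) * (pos[i, bb] - cm[bb])
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dd = np.eye(3)
    dd[2, 2] = d
    rot = vt.T @ dd @ u.T
    fitted = np.empty_like(ref)
    ssq = 0.0
    for i in range(n):
        fitted[i] = rot @ (ref[i] - cr) + cm
        dxv = pos[i] - fitted[i]
        ssq += dxv[0] ** 2 + dxv[1] ** 2 + dxv[2] ** 2
    return fitted, np.sqrt(ssq / n)


# ---------------------------------------------------------------------------
# Integration segments
# ---------------------------------------------------------------------------

@njit(cache=True)
def kinetic_energy(vel, masses):
    ke = 0.0
    for i in range(vel.shape[0]):
        ke += masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    return 0.5 * ke / KCAL_TO_AKMA


@njit(cache=True)
def md_segment(pos, vel, masses,
               bond_i, bond_j, bond_r0, bond_k,
               ang_i, ang_j, ang_k, ang_t0, ang_ka,
               dih_i, dih_j, dih_k, dih_l, dih_p0, dih_k1, dih_k3,
               con_i, con_j, con_r0, con_eps,
               nn_i, nn_j, nn_sigma, nn_eps,
               cutoff, switch_on,
               use_shake, shake_tol, shake_maxiter,
               has_map, target, t_sq_sum, origin, spacing, sigma, rcut,
               map_weights, k_bias, buf,
               dt, nsteps, temp0, tau_ps,
               cc_series, track_best, best_pos):
    """Run ``nsteps`` of velocity-Verlet dynamics in place.

    Thermostat: Berendsen with coupling time ``tau_ps`` (off when
    ``tau_ps <= 0``).  Bias force ``k_bias * dCC/dr`` is applied when
    ``has_map``.  ``cc_series`` (length nsteps) receives the CC after
    each step when a map is present.  Returns (status, best_cc) where
    status is 0 on success, 1 on SHAKE failure, 2 on non-finite forces.
    """
    n = pos.shape[0]
    invm = 1.0 / masses
    ndof = 3.0 * n - bond_i.shape[0] if use_shake else 3.0 * n
    if ndof < 1.0:
        ndof = 1.0
    e, forces = go_energy_forces(
        pos, bond_i, bond_j, bond_r0, bond_k,
        ang_i, ang_j, ang_k, ang_t0, ang_ka,
        dih_i, dih_j, dih_k, dih_l, dih_p0, dih_k1, dih_k3,
        con_i, con_j, con_r0, con_eps, nn_i, nn_j, nn_sigma, nn_eps,
        cutoff, switch_on)
    cc = 0.0
    if has_map:
        cc, grad = cc_and_gradient(pos, map_weights, origin, spacing, target,
                                   t_sq_sum, sigma, rcut, buf)
        if np.isnan(cc):
            return 2, -2.0
        forces += k_bias * grad
    best_cc = -2.0
    pos_old = np.empty_like(pos)
    for step in range(nsteps):
        # half kick
        for i in range(n):
            f = KCAL_TO_AKMA * invm[i] * 0.5 * dt
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]
        # drift
        for i in range(n):
            pos_old[i, 0] = pos[i, 0]
            pos_old[i, 1] = pos[i, 1]
            pos_old[i, 2] = pos[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        if use_shake and bond_i.shape[0] > 0:
            ok = shake(pos, pos_old, bond_i, bond_j, bond_r0, invm,
                       shake_tol, shake_maxiter)
            if ok < 0:
                return 1, best_cc
            # velocity correction from the position shift
            inv_dt = 1.0 / dt
            for i in range(n):
                vel[i, 0] += (pos[i, 0] - pos_old[i, 0] - dt * vel[i, 0]) * inv_dt
                vel[i, 1] += (pos[i, 1] - pos_old[i, 1] - dt * vel[i, 1]) * inv_dt
                vel[i, 2] += (pos[i, 2] - pos_old[i, 2] - dt * vel[i, 2]) * inv_dt
        e, forces = go_energy_forces(
            pos, bond_i, bond_j, bond_r0, bond_k,
            ang_i, ang_j, ang_k, ang_t0, ang_ka,
            dih_i, dih_j, dih_k, dih_l, dih_p0, dih_k1, dih_k3,
            con_i, con_j, con_r0, con_eps, nn_i, nn_j, nn_sigma, nn_eps,
            cutoff, switch_on)
        if np.isnan(e):
            return 2, best_cc
        if has_map:
            cc, grad = cc_and_gradient(pos, map_weights, origin, spacing,
                                       target, t_sq_sum, sigma, rcut, buf)
            if np.isnan(cc):
                return 2, best_cc
            forces += k_bias * grad
        # half kick
        for i in range(n):
            f = KCAL_TO_AKMA * invm[i] * 0.5 * dt
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]
        if use_shake and bond_i.shape[0] > 0:
            rattle_velocities(pos, vel, bond_i, bond_j, invm, 1e-10,
                              shake_maxiter)
        if tau_ps > 0.0:
            ke = kinetic_energy(vel, masses)
            tcur = 2.0 * ke / (KB * ndof)
            if tcur > 1e-12:
                lam = np.sqrt(1.0 + dt / tau_ps * (temp0 / tcur - 1.0))
                for i in range(n):
                    vel[i, 0] *= lam
                    vel[i, 1] *= lam
                    vel[i, 2] *= lam
        if has_map:
            cc_series[step] = cc
            if track_best and cc > best_cc:
                best_cc = cc
                for i in range(n):
                    best_pos[i, 0] = pos[i, 0]
                    best_pos[i, 1] = pos[i, 1]
                    best_pos[i, 2] = pos[i, 2]
    return 0, best_cc


@njit(cache=True)
def tmd_segment(pos, vel, masses,
                bond_i, bond_j, bond_r0, bond_k,
                ang_i, ang_j, ang_k, ang_t0, ang_ka,
                dih_i, dih_j, dih_k, dih_l, dih_p0, dih_k1, dih_k3,
                con_i, con_j, con_r0, con_eps,
                nn_i, nn_j, nn_sigma, nn_eps,
                cutoff, switch_on,
                use_shake, shake_tol, shake_maxiter,
                ref, k_rmsd, rho_series,
                dt, temp0, tau_ps, rmsd_series):
    """Targeted-MD segment: harmonic restraint on best-fit RMSD to ``ref``
    with per-step target values ``rho_series``.  Returns status as in
    :func:`md_segment`."""
    n = pos.shape[0]
    nsteps = rho_series.shape[0]
    invm = 1.0 / masses
    ndof = 3.0 * n - bond_i.shape[0] if use_shake else 3.0 * n
    if ndof < 1.0:
        ndof = 1.0

    def _forces(p, rho_t):
        e, forces = go_energy_forces(
            p, bond_i, bond_j, bond_r0, bond_k,
            ang_i, ang_j, ang_k, ang_t0, ang_ka,
            dih_i, dih_j, dih_k, dih_l, dih_p0, dih_k1, dih_k3,
            con_i, con_j, con_r0, con_eps, nn_i, nn_j, nn_sigma, nn_eps,
            cutoff, switch_on)
        fitted, cur = fit_reference(p, ref)
        if cur > 1e-10:
            coef = -k_rmsd * (cur - rho_t) / (n * cur)
            for i in range(n):
                forces[i, 0] += coef * (p[i, 0] - fitted[i, 0])
                forces[i, 1] += coef * (p[i, 1] - fitted[i, 1])
                forces[i, 2] += coef * (p[i, 2] - fitted[i, 2])
        return e, forces, cur

    e, forces, cur = _forces(pos, rho_series[0])
    pos_old = np.empty_like(pos)
    for step in range(nsteps):
        rho_t = rho_series[step]
        for i in range(n):
            f = KCAL_TO_AKMA * invm[i] * 0.5 * dt
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]
        for i in range(n):
            pos_old[i, 0] = pos[i, 0]
            pos_old[i, 1] = pos[i, 1]
            pos_old[i, 2] = pos[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        if use_shake and bond_i.shape[0] > 0:
            ok = shake(pos, pos_old, bond_i, bond_j, bond_r0, invm,
                       shake_tol, shake_maxiter)
            if ok < 0:
                return 1
            inv_dt = 1.0 / dt
            for i in range(n):
                vel[i, 0] += (pos[i, 0] - pos_old[i, 0] - dt * vel[i, 0]) * inv_dt
                vel[i, 1] += (pos[i, 1] - pos_old[i, 1] - dt * vel[i, 1]) * inv_dt
                vel[i, 2] += (pos[i, 2] - pos_old[i, 2] - dt * vel[i, 2]) * inv_dt
        e, forces, cur = _forces(pos, rho_t)
        if np.isnan(e):
            return 2
        for i in range(n):
            f = KCAL_TO_AKMA * invm[i] * 0.5 * dt
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]
        if use_shake and bond_i.shape[0] > 0:
            rattle_velocities(pos, vel, bond_i, bond_j, invm, 1e-10,
                              shake_maxiter)
        if tau_ps > 0.0:
            ke = kinetic_energy(vel, masses)
            tcur = 2.0 * ke / (KB * ndof)
            if tcur > 1e-12:
                lam = np.sqrt(1.0 + dt / tau_ps * (temp0 / tcur - 1.0))
                for i in range(n):
                    vel[i, 0] *= lam
                    vel[i, 1] *= lam
                    vel[i, 2] *= lam
        rmsd_series[step] = cur
    return 0
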