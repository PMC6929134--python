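"""Numba kernels: force/torque evaluation and the Langevin integration loop.

Everything here operates on plain float64/int64 arrays.  Forces are exact
gradients of the potential terms; the integrator is a BAOAB-splitting
Langevin scheme for translations plus its rotational analogue for the MNP
moment directions (unit vectors rotated by the angular velocity, with
per-step renormalization).
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
_CAP_FRACTION = 0.6  # forces are capped below this fraction of sigma


# ---------------------------------------------------------------------------
# elastic shell terms
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def stretch_kernel(pos, edges, l0, k, F):
    """Harmonic edge springs.  Returns (energy, error_flag)."""
    E = 0.0
    for n in range(edges.shape[0]):
        i, j = edges[n, 0], edges[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        if l < 1e-10:
            return np.nan, 1
        c = -k * (l - l0[n]) / l
        fx, fy, fz = c * dx, c * dy, c * dz
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz
        E += 0.5 * k * (l - l0[n]) ** 2
    return E, 0


@njit(cache=True, fastmath=True)
def area_kernel(pos, tris, A0, k, F):
    """Triangle-area restoring term: E = (k/2) (dA/A0)^2 A0 per triangle."""
    E = 0.0
    for n in range(tris.shape[0]):
        i, j, l = tris[n, 0], tris[n, 1], tris[n, 2]
        ux = pos[j, 0] - pos[i, 0]
        uy = pos[j, 1] - pos[i, 1]
        uz = pos[j, 2] - pos[i, 2]
        vx = pos[l, 0] - pos[i, 0]
        vy = pos[l, 1] - pos[i, 1]
        vz = pos[l, 2] - pos[i, 2]
        nx = uy * vz - uz * vy
        ny = uz * vx - ux * vz
        nz = ux * vy - uy * vx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < 1e-12:
            return np.nan, 1
        A = 0.5 * nn
        nhx, nhy, nhz = nx / nn, ny / nn, nz / nn
        pref = -k * (A - A0[n]) / A0[n]
        # grad_i A = ((r_j - r_l) x nhat)/2 ; cyclic for j, l
        wx = pos[j, 0] - pos[l, 0]
        wy = pos[j, 1] - pos[l, 1]
        wz = pos[j, 2] - pos[l, 2]
        F[i, 0] += pref * 0.5 * (wy * nhz - wz * nhy)
        F[i, 1] += pref * 0.5 * (wz * nhx - wx * nhz)
        F[i, 2] += pref * 0.5 * (wx * nhy - wy * nhx)
        F[j, 0] += pref * 0.5 * (vy * nhz - vz * nhy)
        F[j, 1] += pref * 0.5 * (vz * nhx - vx * nhz)
        F[j, 2] += pref * 0.5 * (vx * nhy - vy * nhx)
        F[l, 0] += pref * 0.5 * (nhy * uz - nhz * uy)
        F[l, 1] += pref * 0.5 * (nhz * ux - nhx * uz)
        F[l, 2] += pref * 0.5 * (nhx * uy - nhy * ux)
        E += 0.5 * k * (A - A0[n]) ** 2 / A0[n]
    return E, 0


@njit(cache=True, fastmath=True)
def bend_kernel(pos, quads, theta0, k, F):
    """Dihedral bending: E = (k/2) (theta - theta0)^2 per shared edge.

    ``quads`` rows are (i, j, k, l): edge i-j, opposite vertices k (in the
    triangle (i, j, k)) and l (in (j, i, l)); theta is the signed dihedral
    angle between the two triangle normals about the edge.
    """
    E = 0.0
    for n in range(quads.shape[0]):
        i, j, kk, ll = quads[n, 0], quads[n, 1], quads[n, 2], quads[n, 3]
        ex = pos[j, 0] - pos[i, 0]
        ey = pos[j, 1] - pos[i, 1]
        ez = pos[j, 2] - pos[i, 2]
        el = np.sqrt(ex * ex + ey * ey + ez * ez)
        ax = pos[kk, 0] - pos[i, 0]
        ay = pos[kk, 1] - pos[i, 1]
        az = pos[kk, 2] - pos[i, 2]
        bx = pos[ll, 0] - pos[j, 0]
        by = pos[ll, 1] - pos[j, 1]
        bz = pos[ll, 2] - pos[j, 2]
        # n1 = e x a, n2 = (-e) x b
        n1x = ey * az - ez * ay
        n1y = ez * ax - ex * az
        n1z = ex * ay - ey * ax
        n2x = -(ey * bz - ez * by)
        n2y = -(ez * bx - ex * bz)
        n2z = -(ex * by - ey * bx)
        N1 = n1x * n1x + n1y * n1y + n1z * n1z
        N2 = n2x * n2x + n2y * n2y + n2z * n2z
        if N1 < 1e-24 or N2 < 1e-24 or el < 1e-12:
            return np.nan, 1
        c = (n1x * n2x + n1y * n2y + n1z * n2z) / np.sqrt(N1 * N2)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        s = (cxx * ex + cxy * ey + cxz * ez) / (np.sqrt(N1 * N2) * el)
        th = np.arctan2(s, c)
        dth = th - theta0[n]
        E += 0.5 * k * dth * dth
        pref = -k * dth  # force = -dE/dtheta * grad theta
        gk = -el / N1
        gl = -el / N2
        # grad_i theta = ((xj-xk).e)/(el*N1) n1 + ((xj-xl).e)/(el*N2) n2
        wk = ((pos[j, 0] - pos[kk, 0]) * ex + (pos[j, 1] - pos[kk, 1]) * ey
              + (pos[j, 2] - pos[kk, 2]) * ez) / (el * N1)
        wl = ((pos[j, 0] - pos[ll, 0]) * ex + (pos[j, 1] - pos[ll, 1]) * ey
              + (pos[j, 2] - pos[ll, 2]) * ez) / (el * N2)
        gix = wk * n1x + wl * n2x
        giy = wk * n1y + wl * n2y
        giz = wk * n1z + wl * n2z
        gkx, gky, gkz = gk * n1x, gk * n1y, gk * n1z
        glx, gly, glz = gl * n2x, gl * n2y, gl * n2z
        gjx = -(gix + gkx + glx)
        gjy = -(giy + gky + gly)
        gjz = -(giz + gkz + glz)
        F[i, 0] += pref * gix
        F[i, 1] += pref * giy
        F[i, 2] += pref * giz
        F[j, 0] += pref * gjx
        F[j, 1] += pref * gjy
        F[j, 2] += pref * gjz
        F[kk, 0] += pref * gkx
        F[kk, 1] += pref * gky
        F[kk, 2] += pref * gkz
        F[ll, 0] += pref * glx
        F[ll, 1] += pref * gly
        F[ll, 2] += pref * glz
    return E, 0


@njit(cache=True, fastmath=True)
def bond_kernel(pos, bonds, h0, k, F):
    """Intershell harmonic springs of rest length h0 (global bead indices)."""
    E = 0.0
    for n in range(bonds.shape[0]):
        i, j = bonds[n, 0], bonds[n, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        if l < 1e-10:
            return np.nan, 1
        c = -k * (l - h0) / l
        F[i, 0] += c * dx
        F[i, 1] += c * dy
        F[i, 2] += c * dz
        F[j, 0] -= c * dx
        F[j, 1] -= c * dy
        F[j, 2] -= c * dz
        E += 0.5 * k * (l - h0) ** 2
    return E, 0


# ---------------------------------------------------------------------------
# steric (WCA) terms
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _wca_pair(r2, sigma, eps):
    """WCA energy and force scalar f such that F_i = f * r_vec (r = ri-rj).

    Returns (energy, f, overlap) with the force capped at its value at
    0.6*sigma for deep overlaps (integrator safety).
    """
    rc2 = (WCA_CUT * sigma) ** 2
    if r2 >= rc2 or eps <= 0.0:
        return 0.0, 0.0, 0
    overlap = 0
    rcap2 = (_CAP_FRACTION * sigma) ** 2
    r2e = r2
    if r2 < rcap2:
        r2e = rcap2
        overlap = 1
    s2 = sigma * sigma / r2e
    s6 = s2 * s2 * s2
    s12 = s6 * s6
    U = 4.0 * eps * (s12 - s6) + eps
    f = 24.0 * eps * (2.0 * s12 - s6) / r2e
    return U, f, overlap


@njit(cache=True, fastmath=True)
def wca_cross_kernel(pos_a, pos_b, sig_ab, eps, F_a, F_b):
    """Brute-force WCA between two species; sig_ab indexed by b-particle."""
    E = 0.0
    overlaps = 0
    for i in range(pos_a.shape[0]):
        for j in range(pos_b.shape[0]):
            dx = pos_a[i, 0] - pos_b[j, 0]
            dy = pos_a[i, 1] - pos_b[j, 1]
            dz = pos_a[i, 2] - pos_b[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            U, f, ov = _wca_pair(r2, sig_ab[j], eps)
            if f != 0.0:
                F_a[i, 0] += f * dx
                F_a[i, 1] += f * dy
                F_a[i, 2] += f * dz
                F_b[j, 0] -= f * dx
                F_b[j, 1] -= f * dy
                F_b[j, 2] -= f * dz
            E += U
            overlaps += ov
    return E, overlaps


@njit(cache=True, fastmath=True)
def mnp_shell_kernel(pos_m, pos_b, sig_mb, eps, F_m, F_b):
    """Cell-list accelerated WCA between MNPs and shell beads."""
    nm, nb = pos_m.shape[0], pos_b.shape[0]
    if nm == 0 or nb == 0:
        return 0.0, 0
    sig_max = 0.0
    for j in range(nb):
        if sig_mb[j] > sig_max:
            sig_max = sig_mb[j]
    rc = WCA_CUT * sig_max
    # bounding box over both species so every query cell index is valid
    lo = np.empty(3)
    hi = np.empty(3)
    for d in range(3):
        lo[d] = pos_b[0, d]
        hi[d] = pos_b[0, d]
    for j in range(nb):
        for d in range(3):
            if pos_b[j, d] < lo[d]:
                lo[d] = pos_b[j, d]
            if pos_b[j, d] > hi[d]:
                hi[d] = pos_b[j, d]
    for i in range(nm):
        for d in range(3):
            if pos_m[i, d] < lo[d]:
                lo[d] = pos_m[i, d]
            if pos_m[i, d] > hi[d]:
                hi[d] = pos_m[i, d]
    nx = int((hi[0] - lo[0]) / rc) + 3
    ny = int((hi[1] - lo[1]) / rc) + 3
    nz = int((hi[2] - lo[2]) / rc) + 3
    head = np.full(nx * ny * nz, -1, dtype=np.int64)
    nxt = np.empty(nb, dtype=np.int64)
    for j in range(nb):
        cx = int((pos_b[j, 0] - lo[0]) / rc) + 1
        cy = int((pos_b[j, 1] - lo[1]) / rc) + 1
        cz = int((pos_b[j, 2] - lo[2]) / rc) + 1
        c = (cx * ny + cy) * nz + cz
        nxt[j] = head[c]
        head[c] = j
    E = 0.0
    overlaps = 0
    for i in range(nm):
        cx = int((pos_m[i, 0] - lo[0]) / rc) + 1
        cy = int((pos_m[i, 1] - lo[1]) / rc) + 1
        cz = int((pos_m[i, 2] - lo[2]) / rc) + 1
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    c = ((cx + ox) * ny + (cy + oy)) * nz + (cz + oz)
                    j = head[c]
                    while j >= 0:
                        dx = pos_m[i, 0] - pos_b[j, 0]
                        dy = pos_m[i, 1] - pos_b[j, 1]
                        dz = pos_m[i, 2] - pos_b[j, 2]
                        r2 = dx * dx + dy * dy + dz * dz
                        U, f, ov = _wca_pair(r2, sig_mb[j], eps)
                        if f != 0.0:
                            F_m[i, 0] += f * dx
                            F_m[i, 1] += f * dy
                            F_m[i, 2] += f * dz
                            F_b[j, 0] -= f * dx
                            F_b[j, 1] -= f * dy
                            F_b[j, 2] -= f * dz
                        E += U
                        overlaps += ov
                        j = nxt[j]
    return E, overlaps


# ---------------------------------------------------------------------------
# magnetic terms
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def mnp_mnp_kernel(pos, e, C, mu, eps, sigma, F, B):
    """All-pairs dipole-dipole forces/fields plus fused MNP-MNP WCA.

    Pair energy: C [ e_i.e_j - 3 (e_i.rh)(e_j.rh) ] / r^3 with C = mu0 mu^2
    in reduced units; B accumulates the dipolar field mu [3(e_j.rh) rh -
    e_j]/r^3 at each particle.  Set eps <= 0 to skip the steric part.
    Returns (E_dipolar, E_wca, overlaps, error_flag).
    """
    n = pos.shape[0]
    Ed = 0.0
    Ew = 0.0
    overlaps = 0
    if C == 0.0 and eps <= 0.0:
        return Ed, Ew, overlaps, 0  # non-interacting (free-dipole) limit
    rc2 = (WCA_CUT * sigma) ** 2
    rcap2 = (_CAP_FRACTION * sigma) ** 2
    sig2 = sigma * sigma
    min_r2 = 1e300
    for i in range(n):
        pix, piy, piz = pos[i, 0], pos[i, 1], pos[i, 2]
        eix, eiy, eiz = e[i, 0], e[i, 1], e[i, 2]
        fix = fiy = fiz = 0.0  # i-side accumulators stay in registers
        bix = biy = biz = 0.0
        for j in range(i + 1, n):
            dx = pix - pos[j, 0]
            dy = piy - pos[j, 1]
            dz = piz - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < min_r2:
                min_r2 = r2
                if r2 < 1e-20:  # coincident centers: flag after the loop
                    continue
            inv_r = 1.0 / np.sqrt(r2)
            rhx, rhy, rhz = dx * inv_r, dy * inv_r, dz * inv_r
            ejx, ejy, ejz = e[j, 0], e[j, 1], e[j, 2]
            ee = eix * ejx + eiy * ejy + eiz * ejz
            di = eix * rhx + eiy * rhy + eiz * rhz
            dj = ejx * rhx + ejy * rhy + ejz * rhz
            ir3 = inv_r * inv_r * inv_r
            Ed += C * (ee - 3.0 * di * dj) * ir3
            g = 3.0 * C * ir3 * inv_r
            fx = g * (ee * rhx + di * ejx + dj * eix - 5.0 * di * dj * rhx)
            fy = g * (ee * rhy + di * ejy + dj * eiy - 5.0 * di * dj * rhy)
            fz = g * (ee * rhz + di * ejz + dj * eiz - 5.0 * di * dj * rhz)
            if r2 < rc2:  # fused steric repulsion (rare branch)
                r2e = r2
                if r2 < rcap2:
                    r2e = rcap2
                    overlaps += 1
                s2 = sig2 / r2e
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                Ew += 4.0 * eps * (s12 - s6) + eps
                fw = 24.0 * eps * (2.0 * s12 - s6) / r2e
                fx += fw * dx
                fy += fw * dy
                fz += fw * dz
            fix += fx
            fiy += fy
            fiz += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
            bm = mu * ir3
            bix += bm * (3.0 * dj * rhx - ejx)
            biy += bm * (3.0 * dj * rhy - ejy)
            biz += bm * (3.0 * dj * rhz - ejz)
            B[j, 0] += bm * (3.0 * di * rhx - eix)
            B[j, 1] += bm * (3.0 * di * rhy - eiy)
            B[j, 2] += bm * (3.0 * di * rhz - eiz)
        F[i, 0] += fix
        F[i, 1] += fiy
        F[i, 2] += fiz
        B[i, 0] += bix
        B[i, 1] += biy
        B[i, 2] += biz
    if min_r2 < 1e-20:
        return np.nan, np.nan, overlaps, 1  # coincident dipole centers
    return Ed, Ew, overlaps, 0


@njit(cache=True, fastmath=True)
def torque_kernel(e, B, mu, xiKT, hx, hy, hz, T):
    """T = mu e x B_dipolar + xi kBT e x hhat.  Returns Zeeman energy."""
    E = 0.0
    for i in range(e.shape[0]):
        bx = mu * B[i, 0] + xiKT * hx
        by = mu * B[i, 1] + xiKT * hy
        bz = mu * B[i, 2] + xiKT * hz
        T[i, 0] += e[i, 1] * bz - e[i, 2] * by
        T[i, 1] += e[i, 2] * bx - e[i, 0] * bz
        T[i, 2] += e[i, 0] * by - e[i, 1] * bx
        E -= xiKT * (e[i, 0] * hx + e[i, 1] * hy + e[i, 2] * hz)
    return E


# ---------------------------------------------------------------------------
# total force evaluation
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def compute_all(pos_b, pos_m, e,
                edges, l0, ks, tris, A0, ka, bonds, h0, kb,
                quads, theta0, kbe,
                sig_mb, eps, sig_mm, C, mu, xiKT, hx, hy, hz,
                F_b, F_m, T_m, B):
    """Zero the output arrays and accumulate every force/torque term.

    Returns (E_potential, overlaps, error_flag).
    """
    F_b[:] = 0.0
    F_m[:] = 0.0
    T_m[:] = 0.0
    B[:] = 0.0
    Es, err1 = stretch_kernel(pos_b, edges, l0, ks, F_b)
    if err1 != 0:
        return np.nan, 0, 1
    Ea, err2 = area_kernel(pos_b, tris, A0, ka, F_b)
    if err2 != 0:
        return np.nan, 0, 2
    Eb, err3 = bond_kernel(pos_b, bonds, h0, kb, F_b)
    if err3 != 0:
        return np.nan, 0, 3
    Ebe, err5 = bend_kernel(pos_b, quads, theta0, kbe, F_b)
    if err5 != 0:
        return np.nan, 0, 5
    Ed, Ew, ov1, err4 = mnp_mnp_kernel(pos_m, e, C, mu, eps, sig_mm, F_m, B)
    if err4 != 0:
        return np.nan, ov1, 4
    Ems, ov2 = mnp_shell_kernel(pos_m, pos_b, sig_mb, eps, F_m, F_b)
    Ez = torque_kernel(e, B, mu, xiKT, hx, hy, hz, T_m)
    return Es + Ea + Eb + Ebe + Ed + Ew + Ems + Ez, ov1 + ov2, 0


# ---------------------------------------------------------------------------
# Langevin integration (BAOAB + rotational analogue)
# ---------------------------------------------------------------------------

@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True, inline="always")
def _rotate(e, i, wx, wy, wz, dt):
    """Rotate unit vector e[i] about omega by |omega| dt (Rodrigues)."""
    w = np.sqrt(wx * wx + wy * wy + wz * wz)
    th = w * dt
    if th < 1e-14:
        return
    ux, uy, uz = wx / w, wy / w, wz / w
    ct = np.cos(th)
    st = np.sin(th)
    ex, ey, ez = e[i, 0], e[i, 1], e[i, 2]
    dot = ux * ex + uy * ey + uz * ez
    cx = uy * ez - uz * ey
    cy = uz * ex - ux * ez
    cz = ux * ey - uy * ex
    ex2 = ex * ct + cx * st + ux * dot * (1.0 - ct)
    ey2 = ey * ct + cy * st + uy * dot * (1.0 - ct)
    ez2 = ez * ct + cz * st + uz * dot * (1.0 - ct)
    norm = np.sqrt(ex2 * ex2 + ey2 * ey2 + ez2 * ez2)
    e[i, 0] = ex2 / norm
    e[i, 1] = ey2 / norm
    e[i, 2] = ez2 / norm


@njit(cache=True, fastmath=True)
def run_chunk(n_steps, dt,
              pos_b, vel_b, pos_m, vel_m, e, om,
              edges, l0, ks, tris, A0, ka, bonds, h0, kb,
              quads, theta0, kbe,
              sig_mb, eps, sig_mm, C, mu, xiKT, hx, hy, hz,
              zeta_t, zeta_r, mass, inertia, kBT,
              F_b, F_m, T_m, B, max_step_disp):
    """Integrate n_steps of coupled translational/rotational Langevin
    dynamics (BAOAB splitting, one force evaluation per step).

    Returns (E_potential_last, max_velocity, overlaps, error_flag).
    """
    nb, nm = pos_b.shape[0], pos_m.shape[0]
    dth = 0.5 * dt
    c1 = np.exp(-zeta_t * dt / mass)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(kBT / mass)
    c1r = np.exp(-zeta_r * dt / inertia)
    c2r = np.sqrt(max(0.0, 1.0 - c1r * c1r)) * np.sqrt(kBT / inertia)
    E, ov_tot, err = compute_all(pos_b, pos_m, e,
                                 edges, l0, ks, tris, A0, ka, bonds, h0, kb,
                                 quads, theta0, kbe,
                                 sig_mb, eps, sig_mm, C, mu, xiKT,
                                 hx, hy, hz, F_b, F_m, T_m, B)
    if err != 0:
        return E, 0.0, ov_tot, err
    vmax = 0.0
    for _ in range(n_steps):
        # B: half kick
        for i in range(nb):
            for d in range(3):
                vel_b[i, d] += dth * F_b[i, d] / mass
        for i in range(nm):
            for d in range(3):
                vel_m[i, d] += dth * F_m[i, d] / mass
                om[i, d] += dth * T_m[i, d] / inertia
        # A: half drift
        for i in range(nb):
            for d in range(3):
                pos_b[i, d] += dth * vel_b[i, d]
        for i in range(nm):
            for d in range(3):
                pos_m[i, d] += dth * vel_m[i, d]
            _rotate(e, i, om[i, 0], om[i, 1], om[i, 2], dth)
        # O: thermostat
        if zeta_t > 0.0:
            for i in range(nb):
                for d in range(3):
                    vel_b[i, d] = c1 * vel_b[i, d] + c2 * np.random.normal()
            for i in range(nm):
                for d in range(3):
                    vel_m[i, d] = c1 * vel_m[i, d] + c2 * np.random.normal()
        if zeta_r > 0.0:
            for i in range(nm):
                for d in range(3):
                    om[i, d] = c1r * om[i, d] + c2r * np.random.normal()
        # A: half drift
        for i in range(nb):
            for d in range(3):
                pos_b[i, d] += dth * vel_b[i, d]
        for i in range(nm):
            for d in range(3):
                pos_m[i, d] += dth * vel_m[i, d]
            _rotate(e, i, om[i, 0], om[i, 1], om[i, 2], dth)
        # force evaluation + B: half kick
        E, ov, err = compute_all(pos_b, pos_m, e,
                                 edges, l0, ks, tris, A0, ka, bonds, h0, kb,
                                 quads, theta0, kbe,
                                 sig_mb, eps, sig_mm, C, mu, xiKT,
                                 hx, hy, hz, F_b, F_m, T_m, B)
        ov_tot += ov
        if err != 0:
            return E, vmax, ov_tot, err
        for i in range(nb):
            for d in range(3):
                vel_b[i, d] += dth * F_b[i, d] / mass
            v2 = vel_b[i, 0] ** 2 + vel_b[i, 1] ** 2 + vel_b[i, 2] ** 2
            if v2 > vmax:
                vmax = v2
        for i in range(nm):
            for d in range(3):
                vel_m[i, d] += dth * F_m[i, d] / mass
                om[i, d] += dth * T_m[i, d] / inertia
            v2 = vel_m[i, 0] ** 2 + vel_m[i, 1] ** 2 + vel_m[i, 2] ** 2
            if v2 > vmax:
                vmax = v2
        if np.sqrt(vmax) * dt > max_step_disp:
            return E, np.sqrt(vmax), ov_tot, 100  # timestep too large
    return E, np.sqrt(vmax), ov_tot, 0
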