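"""Jitted numerical kernels: forces, the NVT integrator loop and the
pairwise energy sums used by the Monte Carlo sampler.

These are internal. The reference implementations live in
:mod:`nanopost.model`; tests assert that the kernels agree with them.
Reduced units throughout (epsilon = sigma = m_o = 1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

CUT = 2.0 ** (1.0 / 6.0)
CUT2 = CUT * CUT

# status codes returned by the integrator
STATUS_OK = 0
STATUS_OVERSTRETCH = 1
STATUS_OVERLAP = 2


@njit(cache=True)
def energy_forces(pos, kappa, r_max2, bkt, use_posts, S_p, Dp_half, f):
    """Fill ``f`` with forces; return (status, e_wca, e_fene, e_bend, e_post)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e_wca = 0.0
    e_fene = 0.0
    e_bend = 0.0
    e_post = 0.0

    # WCA between all bead pairs (bonded neighbours included)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < CUT2:
                inv = 1.0 / d2
                s6 = inv * inv * inv
                e_wca += 4.0 * (s6 * s6 - s6) + 1.0
                c = 24.0 * (2.0 * s6 * s6 - s6) * inv
                f[i, 0] += c * dx
                f[i, 1] += c * dy
                f[i, 2] += c * dz
                f[j, 0] -= c * dx
                f[j, 1] -= c * dy
                f[j, 2] -= c * dz

    # FENE springs on consecutive pairs
    for i in range(n - 1):
        bx = pos[i + 1, 0] - pos[i, 0]
        by = pos[i + 1, 1] - pos[i, 1]
        bz = pos[i + 1, 2] - pos[i, 2]
        l2 = bx * bx + by * by + bz * bz
        if l2 >= r_max2:
            return STATUS_OVERSTRETCH, e_wca, e_fene, e_bend, e_post
        x = l2 / r_max2
        e_fene += -0.5 * kappa * r_max2 * np.log(1.0 - x)
        c = kappa / (1.0 - x)
        f[i, 0] += c * bx
        f[i, 1] += c * by
        f[i, 2] += c * bz
        f[i + 1, 0] -= c * bx
        f[i + 1, 1] -= c * by
        f[i + 1, 2] -= c * bz

    # bending U = bkt * (1 - u_i . u_{i+1}) at every interior joint
    if bkt > 0.0 and n >= 3:
        for i in range(n - 2):
            b1x = pos[i + 1, 0] - pos[i, 0]
            b1y = pos[i + 1, 1] - pos[i, 1]
            b1z = pos[i + 1, 2] - pos[i, 2]
            b2x = pos[i + 2, 0] - pos[i + 1, 0]
            b2y = pos[i + 2, 1] - pos[i + 1, 1]
            b2z = pos[i + 2, 2] - pos[i + 1, 2]
            l1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            l2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            u1x = b1x / l1
            u1y = b1y / l1
            u1z = b1z / l1
            u2x = b2x / l2n
            u2y = b2y / l2n
            u2z = b2z / l2n
            cth = u1x * u2x + u1y * u2y + u1z * u2z
            e_bend += bkt * (1.0 - cth)
            # dc/dr1 and dc/dr2 (r1, r2 = bond vectors)
            g1x = (u2x - cth * u1x) / l1
            g1y = (u2y - cth * u1y) / l1
            g1z = (u2z - cth * u1z) / l1
            g2x = (u1x - cth * u2x) / l2n
            g2y = (u1y - cth * u2y) / l2n
            g2z = (u1z - cth * u2z) / l2n
            # U = bkt(1-c): F = bkt * dc/dx
            f[i, 0] += -bkt * g1x
            f[i, 1] += -bkt * g1y
            f[i, 2] += -bkt * g1z
            f[i + 1, 0] += bkt * (g1x - g2x)
            f[i + 1, 1] += bkt * (g1y - g2y)
            f[i + 1, 2] += bkt * (g1z - g2z)
            f[i + 2, 0] += bkt * g2x
            f[i + 2, 1] += bkt * g2y
            f[i + 2, 2] += bkt * g2z

    # monomer-post WCA against the four posts bounding each bead's cell
    if use_posts:
        for i in range(n):
            by = np.floor(pos[i, 1] / S_p)
            bz = np.floor(pos[i, 2] / S_p)
            for cy in range(2):
                for cz in range(2):
                    ay = (by + cy) * S_p
                    az = (bz + cz) * S_p
                    ry = pos[i, 1] - ay
                    rz = pos[i, 2] - az
                    r = np.sqrt(ry * ry + rz * rz)
                    sh = r - Dp_half
                    if sh <= 0.0:
                        return STATUS_OVERLAP, e_wca, e_fene, e_bend, e_post
                    if sh < CUT:
                        inv = 1.0 / (sh * sh)
                        s6 = inv * inv * inv
                        e_post += 4.0 * (s6 * s6 - s6) + 1.0
                        dudsh = -24.0 * (2.0 * s6 * s6 - s6) / sh
                        fr = -dudsh / r
                        f[i, 1] += fr * ry
                        f[i, 2] += fr * rz

    return STATUS_OK, e_wca, e_fene, e_bend, e_post


@njit(cache=True)
def run_nvt(pos, vel, kappa, r_max2, bkt, use_posts, S_p, Dp_half,
            dt, n_equil, n_prod, stride, thermostat, tau_t, temp, gamma, seed,
            frames, times, temps, epots):
    """NVT dynamics: velocity Verlet with a Nose-Hoover (thermostat=1),
    Langevin/BAOAB (thermostat=2) or no (thermostat=0) thermostat.

    Frames are recorded every ``stride`` production steps (the first
    ``n_equil`` steps are discarded).  Returns (status, failed_step,
    frames_written).  ``pos``/``vel`` are updated in place.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros_like(pos)
    g = 3.0 * n - 3.0  # COM momentum is zero and conserved
    q_nh = g * temp * tau_t * tau_t
    zeta = 0.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * temp)

    status, ew, ef, eb, ep = energy_forces(
        pos, kappa, r_max2, bkt, use_posts, S_p, Dp_half, f)
    if status != STATUS_OK:
        return status, 0, 0

    n_total = n_equil + n_prod
    written = 0
    for step in range(n_total):
        if thermostat == 1:
            k2 = 0.0
            for i in range(n):
                k2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            zeta += 0.25 * dt * (k2 - g * temp) / q_nh
            s = np.exp(-0.5 * dt * zeta)
            for i in range(n):
                vel[i, 0] *= s
                vel[i, 1] *= s
                vel[i, 2] *= s
            k2 *= s * s
            zeta += 0.25 * dt * (k2 - g * temp) / q_nh

        for i in range(n):
            vel[i, 0] += 0.5 * dt * f[i, 0]
            vel[i, 1] += 0.5 * dt * f[i, 1]
            vel[i, 2] += 0.5 * dt * f[i, 2]

        if thermostat == 2:
            for i in range(n):
                pos[i, 0] += 0.5 * dt * vel[i, 0]
                pos[i, 1] += 0.5 * dt * vel[i, 1]
                pos[i, 2] += 0.5 * dt * vel[i, 2]
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.normal()
            for i in range(n):
                pos[i, 0] += 0.5 * dt * vel[i, 0]
                pos[i, 1] += 0.5 * dt * vel[i, 1]
                pos[i, 2] += 0.5 * dt * vel[i, 2]
        else:
            for i in range(n):
                pos[i, 0] += dt * vel[i, 0]
                pos[i, 1] += dt * vel[i, 1]
                pos[i, 2] += dt * vel[i, 2]

        status, ew, ef, eb, ep = energy_forces(
            pos, kappa, r_max2, bkt, use_posts, S_p, Dp_half, f)
        if status != STATUS_OK:
            return status, step, written

        for i in range(n):
            vel[i, 0] += 0.5 * dt * f[i, 0]
            vel[i, 1] += 0.5 * dt * f[i, 1]
            vel[i, 2] += 0.5 * dt * f[i, 2]

        if thermostat == 1:
            k2 = 0.0
            for i in range(n):
                k2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            zeta += 0.25 * dt * (k2 - g * temp) / q_nh
            s = np.exp(-0.5 * dt * zeta)
            for i in range(n):
                vel[i, 0] *= s
                vel[i, 1] *= s
                vel[i, 2] *= s
            k2 *= s * s
            zeta += 0.25 * dt * (k2 - g * temp) / q_nh

        prod_step = step - n_equil + 1
        if prod_step > 0 and prod_step % stride == 0 and written < frames.shape[0]:
            for i in range(n):
                frames[written, i, 0] = pos[i, 0]
                frames[written, i, 1] = pos[i, 1]
                frames[written, i, 2] = pos[i, 2]
            times[written] = (step + 1) * dt
            k2 = 0.0
            for i in range(n):
                k2 += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            temps[written] = k2 / g
            epots[written] = ew + ef + eb + ep
            written += 1

    return STATUS_OK, n_total, written


@njit(cache=True)
def total_potential(pos, kappa, r_max2, bkt, use_posts, S_p, Dp_half):
    f = np.zeros_like(pos)
    status, ew, ef, eb, ep = energy_forces(
        pos, kappa, r_max2, bkt, use_posts, S_p, Dp_half, f)
    return status, ew + ef + eb + ep


@njit(cache=True)
def wca_cross_energy(a, b, cap):
    """Sum of WCA pair energies between bead sets ``a`` and ``b``.

    Returns early once the running sum exceeds ``cap`` (use np.inf for an
    exact sum): in Metropolis acceptance an energy far above the current
    one is a certain rejection.
    """
    e = 0.0
    for i in range(a.shape[0]):
        ax = a[i, 0]
        ay = a[i, 1]
        az = a[i, 2]
        for j in range(b.shape[0]):
            dx = ax - b[j, 0]
            dy = ay - b[j, 1]
            dz = az - b[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < CUT2:
                inv = 1.0 / d2
                s6 = inv * inv * inv
                e += 4.0 * (s6 * s6 - s6) + 1.0
                if e > cap:
                    return e
    return e


@njit(cache=True)
def wca_one_vs_rest(pos, k, point, cap):
    """WCA energy of ``point`` against every bead of ``pos`` except index k."""
    e = 0.0
    for j in range(pos.shape[0]):
        if j == k:
            continue
        dx = point[0] - pos[j, 0]
        dy = point[1] - pos[j, 1]
        dz = point[2] - pos[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < CUT2:
            inv = 1.0 / d2
            s6 = inv * inv * inv
            e += 4.0 * (s6 * s6 - s6) + 1.0
            if e > cap:
                return e
    return e
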