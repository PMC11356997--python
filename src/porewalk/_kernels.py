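"""Compiled inner loop for trajectory simulation.

One step = one translation attempt followed by one rotation attempt; the step
counter advances whether or not either attempt is accepted.  The trajectory
RNG is numba's internal legacy MT19937, reseeded per trajectory, which makes
every trajectory independently replayable from its sub-seed.  Draw order per
step is fixed: 3 translation normals, then (cos-polar, azimuth) uniforms for
the rotation axis, then 1 rotation-angle normal.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

#: sentinel returned in place of a first-passage time when the step cap is hit
CENSORED = -1


@njit(cache=True)
def capsule_hits_wall(x: float, y: float, ux: float, uy: float,
                      half_l: float, r: float, radius: float) -> bool:
    """Radial collision test, endpoint-maximum reduction (exact for a convex
    cross-section): the capsule pokes the wall iff
    max over core-segment endpoints of sqrt(px^2+py^2) + r > radius."""
    e1 = math.sqrt((x + half_l * ux) ** 2 + (y + half_l * uy) ** 2)
    e2 = math.sqrt((x - half_l * ux) ** 2 + (y - half_l * uy) ** 2)
    return max(e1, e2) + r > radius


@njit(cache=True)
def run_capsule_trajectory(seed, half_l, r, radius, L, sigma_x, Mxx, Mzz,
                           max_steps, record_stride, rec):
    """Simulate one particle from x=(0,0,0), u=+z until absorption at z >= L.

    Parameters are plain scalars (body-frame moments precomputed).  ``rec``
    is a preallocated (n, 4) buffer receiving (t, x, y, z) rows every
    ``record_stride`` steps while the particle is still inside.

    Returns ``(fpt, exit_theta, accepted_translations, accepted_rotations,
    n_recorded)``; ``fpt`` is ``CENSORED`` (-1) if ``max_steps`` elapsed, in
    which case ``exit_theta`` is meaningless.  The exit angle is taken at the
    moment of absorption, i.e. after the accepted translation and before any
    further rotation.
    """
    np.random.seed(seed)
    x = 0.0; y = 0.0; z = 0.0
    ux = 0.0; uy = 0.0; uz = 1.0
    acc_t = 0
    acc_r = 0
    n_rec = 0
    if rec.shape[0] > 0:
        rec[0, 0] = 0.0; rec[0, 1] = 0.0; rec[0, 2] = 0.0; rec[0, 3] = 0.0
        n_rec = 1
    for t in range(1, max_steps + 1):
        # --- translation attempt ---
        dx = np.random.normal() * sigma_x
        dy = np.random.normal() * sigma_x
        dz = np.random.normal() * sigma_x
        nz = z + dz
        if nz >= 0.0:  # reflecting entrance: moves to z < 0 are rejected
            nx = x + dx
            ny = y + dy
            if not capsule_hits_wall(nx, ny, ux, uy, half_l, r, radius):
                x = nx; y = ny; z = nz
                acc_t += 1
                if z >= L:  # absorbed at the exit
                    return t, math.acos(min(1.0, max(-1.0, uz))), acc_t, acc_r, n_rec
        # --- rotation attempt ---
        cz = 2.0 * np.random.random() - 1.0
        ph = 2.0 * math.pi * np.random.random()
        s = math.sqrt(max(0.0, 1.0 - cz * cz))
        ax = s * math.cos(ph); ay = s * math.sin(ph); az = cz
        c = ax * ux + ay * uy + az * uz
        mom = Mzz * c * c + Mxx * (1.0 - c * c)   # A^T M A in the lab frame
        dphi = np.random.normal() * sigma_x / math.sqrt(mom)
        cd = math.cos(dphi); sd = math.sin(dphi)
        crx = ay * uz - az * uy
        cry = az * ux - ax * uz
        crz = ax * uy - ay * ux
        omc = 1.0 - cd
        nux = ux * cd + crx * sd + ax * c * omc
        nuy = uy * cd + cry * sd + ay * c * omc
        nuz = uz * cd + crz * sd + az * c * omc
        nn = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
        nux /= nn; nuy /= nn; nuz /= nn
        if not capsule_hits_wall(x, y, nux, nuy, half_l, r, radius):
            ux = nux; uy = nuy; uz = nuz
            acc_r += 1
        if t % record_stride == 0 and n_rec < rec.shape[0]:
            rec[n_rec, 0] = t
            rec[n_rec, 1] = x
            rec[n_rec, 2] = y
            rec[n_rec, 3] = z
            n_rec += 1
    return CENSORED, 0.0, acc_t, acc_r, n_rec
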