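"""Independent oracles used by the test suite.

These deliberately avoid the package's own arithmetic: the collision oracle
samples the capsule surface pointwise, and the inertia oracle integrates the
mass distribution by 1D quadrature over cross-sections.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import integrate


def capsule_surface_max_radial(x, u, l, r, n_points, rng):
    """Max distance from the channel (z-)axis over sampled capsule surface points.

    Points are drawn area-uniformly from the cylindrical side and the two
    hemispherical caps of a capsule centered at ``x`` with axis ``u``.
    """
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    # orthonormal basis (e1, e2, u)
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    area_side = 2.0 * math.pi * r * l
    area_caps = 4.0 * math.pi * r * r
    n_side = int(round(n_points * area_side / (area_side + area_caps)))
    n_caps = n_points - n_side
    pts = []
    if n_side > 0:
        phi = rng.uniform(0.0, 2.0 * math.pi, n_side)
        h = rng.uniform(-0.5 * l, 0.5 * l, n_side)
        pts.append(
            x[None, :]
            + r * np.cos(phi)[:, None] * e1
            + r * np.sin(phi)[:, None] * e2
            + h[:, None] * u
        )
    if n_caps > 0:
        # uniform on the full sphere, folded onto the hemisphere facing outward
        v = rng.normal(size=(n_caps, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        axial = v @ u
        sign = np.where(rng.random(n_caps) < 0.5, 1.0, -1.0)
        v = v * np.where((axial * sign)[:, None] < 0, -1.0, 1.0)  # flip toward cap
        centers = x[None, :] + (0.5 * l) * sign[:, None] * u[None, :]
        pts.append(centers + r * v)
    pts = np.vstack(pts)
    return float(np.max(np.hypot(pts[:, 0], pts[:, 1])))


def capsule_moments_quad(l, r):
    """(Mxx, Mzz) of a unit-mass uniform capsule by cross-section quadrature.

    A slice at axial coordinate z is a disk of radius s(z); its contributions
    are dMxx = rho * (pi s^4 / 4 + pi s^2 z^2) dz and dMzz = rho * pi s^4 / 2 dz.
    """
    volume = math.pi * r * r * l + 4.0 / 3.0 * math.pi * r**3
    rho = 1.0 / volume

    def s2(z):
        az = abs(z)
        if az <= 0.5 * l:
            return r * r
        return max(0.0, r * r - (az - 0.5 * l) ** 2)

    def dmxx(z):
        ss = s2(z)
        return rho * (math.pi * ss * ss / 4.0 + math.pi * ss * z * z)

    def dmzz(z):
        ss = s2(z)
        return rho * math.pi * ss * ss / 2.0

    zmax = 0.5 * l + r
    pieces = [(-zmax, -0.5 * l), (-0.5 * l, 0.5 * l), (0.5 * l, zmax)]
    mxx = sum(integrate.quad(dmxx, a, b, epsabs=1e-13, epsrel=1e-12)[0] for a, b in pieces)
    mzz = sum(integrate.quad(dmzz, a, b, epsabs=1e-13, epsrel=1e-12)[0] for a, b in pieces)
    return mxx, mzz


def bootstrap_median_sd(samples, n_boot=300, seed=0):
    """Bootstrap standard deviation of the sample median."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(samples), size=(n_boot, len(samples)))
    return float(np.std(np.median(np.asarray(samples)[idx], axis=1)))
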