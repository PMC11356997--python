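"""Spherocylinder and channel geometry.

A spherocylinder (capsule) is a cylinder of length ``l`` and diameter ``d``
capped by two hemispheres; its total length is ``l + d`` and its aspect ratio
is ``f = 1 + l/d``.  The channel is an infinite cylinder about the z-axis
whose diameter is the unit of length, so its radius is fixed at 0.5.

All geometric kernels here are pure functions on numpy arrays; the compiled
simulation loop in :mod:`porewalk._kernels` re-implements the same arithmetic
for speed and is cross-checked against these reference routines in the test
suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: renormalization tolerance for unit vectors
NORM_TOL = 1e-12


@dataclass(frozen=True)
class Spherocylinder:
    """Rigid capsule of uniform density and unit total mass.

    Parameters
    ----------
    l : float
        Length of the cylindrical core, in channel-width units (``>= 0``;
        ``l == 0`` is a sphere).
    d : float
        Particle diameter in channel-width units, ``0 < d < 1`` so the
        particle fits the channel.

    The mass is split between the core (``m1``) and each hemispherical cap
    (``m2``) according to uniform density, ``m1/m2 = 3 l / (2 r)``, and
    normalized so that ``m1 + 2 m2 = 1``.  With unit total mass the
    rotational step scale depends on shape only.
    """

    l: float
    d: float

    def __post_init__(self) -> None:
        if not self.l >= 0:
            raise ValueError(f"core length l must be >= 0, got {self.l}")
        if not 0 < self.d < 1:
            raise ValueError(
                f"diameter d must lie in (0, 1) channel-width units, got {self.d}"
            )

    @classmethod
    def from_aspect(cls, f: float, d: float) -> "Spherocylinder":
        """Build from aspect ratio ``f = 1 + l/d`` and diameter ``d``."""
        if f < 1:
            raise ValueError(f"aspect ratio f must be >= 1, got {f}")
        return cls(l=d * (f - 1.0), d=d)

    @property
    def r(self) -> float:
        """Radius, ``d / 2``."""
        return 0.5 * self.d

    @property
    def f(self) -> float:
        """Aspect ratio ``1 + l/d``."""
        return 1.0 + self.l / self.d

    @property
    def m1(self) -> float:
        """Mass of the cylindrical core (unit total mass)."""
        return 1.0 - 2.0 * self.m2

    @property
    def m2(self) -> float:
        """Mass of one hemispherical cap (unit total mass)."""
        # m1/m2 = 3l/(2r) for uniform density; m1 + 2 m2 = 1
        return 1.0 / (3.0 * self.l / (2.0 * self.r) + 2.0)

    @property
    def Mxx(self) -> float:
        """Transverse moment of inertia in the body frame (== Myy)."""
        l, r, m1, m2 = self.l, self.r, self.m1, self.m2
        return m1 * (l * l / 12.0 + r * r / 4.0) + 2.0 * m2 * (
            2.0 * r * r / 5.0 + l * l / 4.0 + 3.0 * l * r / 8.0
        )

    @property
    def Mzz(self) -> float:
        """Axial moment of inertia in the body frame (z along the particle axis)."""
        return (self.m1 / 2.0 + 4.0 * self.m2 / 5.0) * self.r**2


@dataclass(frozen=True)
class Channel:
    """Cylindrical pore of length ``L``; the diameter is the unit of length."""

    L: float
    #: fixed — the channel diameter defines the unit length
    radius: float = field(default=0.5, init=False)

    def __post_init__(self) -> None:
        if not self.L >= 0:
            raise ValueError(f"channel length L must be >= 0, got {self.L}")


@dataclass
class ParticleState:
    """Center position ``x``, axis direction ``u`` (unit), elapsed steps ``t``."""

    x: np.ndarray
    u: np.ndarray
    t: int = 0

    def copy(self) -> "ParticleState":
        return ParticleState(self.x.copy(), self.u.copy(), self.t)


def inertia_tensor(p: Spherocylinder) -> np.ndarray:
    """Body-frame inertia tensor of the capsule, diagonal (Mxx, Mxx, Mzz).

    The body z-axis is the particle axis.  For ``l == 0`` (sphere) this
    reduces to the solid-sphere value ``(2/5) m r**2`` on the diagonal.
    """
    return np.diag([p.Mxx, p.Mxx, p.Mzz])


def axial_moment(p: Spherocylinder, u: np.ndarray, A: np.ndarray) -> float:
    """Moment of inertia of the capsule about lab axis ``A``.

    The particle axis points along ``u``.  Because the body tensor is
    axisymmetric (Mxx == Myy) the roll angle about ``u`` is immaterial and
    the contraction reduces to ``Mzz c**2 + Mxx (1 - c**2)`` with
    ``c = A . u``.
    """
    c = float(np.dot(u, A))
    return p.Mzz * c * c + p.Mxx * (1.0 - c * c)


def collides(p: Spherocylinder, x: np.ndarray, u: np.ndarray, ch: Channel) -> bool:
    """True iff the capsule is not entirely inside the channel's cylindrical wall.

    The radial distance from the channel axis is convex along the capsule's
    core segment, so the maximum of (segment radial distance + r) is attained
    at one of the two segment endpoints.  The channel ends impose no wall:
    only the radial coordinate is tested here.
    """
    half = 0.5 * p.l
    e = half * u[:2]
    c = x[:2]
    reach = max(float(np.hypot(*(c + e))), float(np.hypot(*(c - e))))
    return reach + p.r > ch.radius


def rotate_axis(u: np.ndarray, A: np.ndarray, dphi: float) -> np.ndarray:
    """Rodrigues rotation of ``u`` about unit axis ``A`` by angle ``dphi``.

    Right-handed convention; the result is renormalized to guard against
    floating-point drift over long trajectories.  The rotation axis passes
    through the particle center, so the center is unchanged.
    """
    c, s = math.cos(dphi), math.sin(dphi)
    v = u * c + np.cross(A, u) * s + A * np.dot(A, u) * (1.0 - c)
    return v / np.linalg.norm(v)


def random_unit_axis(rng: np.random.Generator) -> np.ndarray:
    """Unit vector uniform on the sphere (normalized Gaussian triple)."""
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > NORM_TOL:
            return v / n
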