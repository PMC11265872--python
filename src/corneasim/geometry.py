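"""Reference (unloaded) geometry of the corneal slice.

The unloaded cornea is idealized as a planar annular sector: anterior and
posterior surfaces are concentric circular arcs of radii ``R_A`` and
``R_P = R_A - T`` spanning a half-aperture ``Phi_star``.  The discrete model
places ``N + 1`` concentric lamellar arcs, each subdivided into ``M`` straight
segments; this module constructs the node lattice, the rest lengths of the
three structural-element families (lamellar, radial, diagonal) and the
dimensionless microstructure ratios shared by the discrete and continuum
scales.

Index conventions: ``i = 0..N`` runs radially from the posterior surface
(``i = 0``) to the anterior surface (``i = N``); ``j = 0..M`` runs
counterclockwise in azimuth from ``Phi = -Phi_star`` (``j = 0``) to
``Phi = +Phi_star`` (``j = M``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError

__all__ = [
    "CorneaGeometry",
    "Discretization",
    "NodeGrid",
    "RestLengths",
    "MicrostructureFunctions",
    "phi_star",
    "build_nodes",
    "rest_lengths",
    "microstructure",
]


def phi_star(R_A: float, D_A: float) -> float:
    """Half-aperture angle from the anterior radius and in-plane diameter.

    The anterior in-plane diameter is the chord of the anterior arc,
    ``D_A = 2 R_A sin(Phi_star)``, hence ``Phi_star = arcsin(D_A / (2 R_A))``.

    Parameters
    ----------
    R_A : float
        Anterior radius of curvature (any length unit).
    D_A : float
        Anterior in-plane diameter (same unit).

    Returns
    -------
    float
        Half-aperture angle in radians, in (0, pi/2).
    """
    if R_A <= 0 or D_A <= 0:
        raise InvalidGeometryError(
            f"radius and diameter must be positive, got R_A={R_A}, D_A={D_A}"
        )
    if D_A >= 2.0 * R_A:
        raise InvalidGeometryError(
            f"in-plane diameter D_A={D_A} must be smaller than 2*R_A={2 * R_A}"
        )
    return math.asin(D_A / (2.0 * R_A))


@dataclass(frozen=True)
class CorneaGeometry:
    """Macroscale geometry of the unloaded corneal slice.

    All lengths carry the same unit (mm at the I/O boundary; divided by the
    thickness for internal, dimensionless computation).

    Attributes
    ----------
    R_A : float
        Radius of the anterior surface.
    T : float
        Uniform slice thickness.
    D_A : float
        Anterior in-plane diameter (chord of the anterior arc).
    D : float
        Out-of-plane slice depth (plane strain).
    """

    R_A: float = 7.8
    T: float = 0.62
    D_A: float = 11.46
    D: float = 1.0

    def __post_init__(self):
        if not (0 < self.T < self.R_A):
            raise InvalidGeometryError(
                f"thickness must satisfy 0 < T < R_A, got T={self.T}, R_A={self.R_A}"
            )
        if self.D <= 0:
            raise InvalidGeometryError(f"depth must be positive, got D={self.D}")
        phi_star(self.R_A, self.D_A)  # validates D_A

    @property
    def R_P(self) -> float:
        """Radius of the posterior surface, ``R_A - T``."""
        return self.R_A - self.T

    @property
    def Phi_star(self) -> float:
        """Half-aperture angle (rad)."""
        return phi_star(self.R_A, self.D_A)

    @property
    def Y_max(self) -> float:
        """Y coordinate where the anterior surface meets the limbus."""
        return self.R_A * math.sin(self.Phi_star)

    def nondimensional(self) -> "CorneaGeometry":
        """Return the same geometry with all lengths divided by ``T``."""
        return CorneaGeometry(
            R_A=self.R_A / self.T, T=1.0, D_A=self.D_A / self.T, D=self.D / self.T
        )


@dataclass(frozen=True)
class Discretization:
    """Lattice resolution: ``N`` radial layers and ``M = gamma * N`` azimuthal
    segments, with the aspect ratio ``gamma`` held fixed under refinement."""

    N: int = 32
    gamma: float = 20.0

    def __post_init__(self):
        if self.N < 1:
            raise InvalidGeometryError(f"need at least one radial layer, got N={self.N}")
        M = self.gamma * self.N
        if abs(M - round(M)) > 1e-9:
            raise InvalidGeometryError(
                f"gamma*N must be an integer, got gamma={self.gamma}, N={self.N}"
            )
        if round(M) % 2 != 0:
            raise InvalidGeometryError(f"M = gamma*N must be even, got M={M}")

    @property
    def M(self) -> int:
        """Number of azimuthal segments per arc (even)."""
        return int(round(self.gamma * self.N))


@dataclass(frozen=True)
class NodeGrid:
    """Cartesian reference positions of the lattice nodes.

    ``X[i, j], Y[i, j]`` with ``i = 0..N`` (radial), ``j = 0..M`` (azimuthal);
    node ``(i, j)`` sits at radius ``R[i]`` and polar angle ``Phi[j]``.
    """

    X: np.ndarray
    Y: np.ndarray
    R: np.ndarray
    Phi: np.ndarray

    @property
    def N(self) -> int:
        return self.X.shape[0] - 1

    @property
    def M(self) -> int:
        return self.X.shape[1] - 1


def build_nodes(geom: CorneaGeometry, disc: Discretization) -> NodeGrid:
    """Place the ``(N+1) x (M+1)`` reference node lattice.

    Radii are ``R_i = R_P + i*T/N`` and angles ``Phi_j = (j - M/2) * 2*Phi_star/M``,
    so ``j = 0`` and ``j = M`` lie on the limbus at ``-Phi_star`` and ``+Phi_star``.
    """
    N, M = disc.N, disc.M
    R = geom.R_P + np.arange(N + 1) * (geom.T / N)
    Phi = (np.arange(M + 1) - M / 2) * (2.0 * geom.Phi_star / M)
    X = R[:, None] * np.cos(Phi)[None, :]
    Y = R[:, None] * np.sin(Phi)[None, :]
    return NodeGrid(X=X, Y=Y, R=R, Phi=Phi)


@dataclass(frozen=True)
class RestLengths:
    """Rest lengths of the three element families and their dimensionless ratios.

    Attributes
    ----------
    L1 : ndarray, shape (N+1,)
        Lamellar segment rest length per layer, ``2 R_i sin(Phi_star/M)``.
    L2 : float
        Radial crosslink rest length ``T/N`` (uniform).
    L3 : ndarray, shape (N,)
        Diagonal crosslink rest length for inter-layer ``i+1/2``, from
        ``L3^2 = L1_i * L1_{i+1} + L2^2``.
    q : ndarray, shape (N+1,)
        ``L2 / L1_i``.
    w : ndarray, shape (N,)
        ``L2 / L3_{i+1/2}``.
    """

    L1: np.ndarray
    L2: float
    L3: np.ndarray
    q: np.ndarray
    w: np.ndarray


def rest_lengths(geom: CorneaGeometry, disc: Discretization) -> RestLengths:
    """Rest lengths of lamellar, radial and diagonal elements."""
    grid_R = geom.R_P + np.arange(disc.N + 1) * (geom.T / disc.N)
    L2 = geom.T / disc.N
    L1 = 2.0 * grid_R * math.sin(geom.Phi_star / disc.M)
    L3 = np.sqrt(L1[:-1] * L1[1:] + L2**2)
    return RestLengths(L1=L1, L2=L2, L3=L3, q=L2 / L1, w=L2 / L3)


@dataclass(frozen=True)
class MicrostructureFunctions:
    """Continuum-limit microstructure ratios on the dimensionless sector.

    With lengths scaled by the thickness, the lamellar-to-radial spacing ratio
    becomes ``q(R) = 1/(kappa R)`` with ``kappa = 2 Phi_star / gamma``, the
    diagonal ratio ``w(R) = q/sqrt(1+q^2)`` and the diagonal inclination angle
    ``beta(R) = arctan(q)`` (so ``sin beta = w`` and ``cos beta = kappa R w``).
    Valid for dimensionless radii ``R`` in ``[R_P/T, R_A/T]``.
    """

    kappa: float
    R_inner: float
    R_outer: float

    def _check(self, R):
        R = np.asarray(R, dtype=float)
        if np.any(R <= 0):
            raise InvalidGeometryError("microstructure functions require R > 0")
        return R

    def q(self, R):
        R = self._check(R)
        return 1.0 / (self.kappa * R)

    def w(self, R):
        R = self._check(R)
        return 1.0 / np.sqrt(1.0 + (self.kappa * R) ** 2)

    def beta(self, R):
        return np.arctan(self.q(R))


def microstructure(geom: CorneaGeometry, disc: Discretization) -> MicrostructureFunctions:
    """Continuum microstructure ratio functions for a given geometry/aspect ratio."""
    kappa = 2.0 * geom.Phi_star / disc.gamma
    return MicrostructureFunctions(
        kappa=kappa, R_inner=geom.R_P / geom.T, R_outer=geom.R_A / geom.T
    )
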