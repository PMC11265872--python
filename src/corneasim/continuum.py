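"""Upscaled anisotropic hyperelastic continuum model of the corneal slice.

In the limit of many lamellar layers (N -> infinity at fixed lattice aspect
ratio gamma) the spring lattice homogenizes to a continuum with strain-energy
density (lengths scaled by the thickness T, stiffness by the healthy lamellar
stiffness K1)

    W = 1/(2 kappa R D) * [ (kappa R)^2 K1 (lam_Phi - 1)^2
                            + K2 (lam_R - 1)^2
                            + (1 + (kappa R)^2) K3 ((lam_+ - 1)^2 + (lam_- - 1)^2) ]

where ``lam_a = sqrt(e_a . C e_a)`` is the stretch of the material direction
``e_a``, C is the right Cauchy-Green tensor in the orthonormal polar frame,
``kappa = 2 Phi_star / gamma``, and ``e_pm = sin(beta) e_R +/- cos(beta) e_Phi``
are the diagonal-crosslink directions with ``tan(beta) = 1/(kappa R)``.  The
second Piola-Kirchhoff stress is ``T = 2 dW/dC``; each family contributes a
rank-one term ``K (1 - lam_a^{-1}) e_a (x) e_a``.

The volume measure consistent with the lattice is ``dV = D R dR dPhi``; with
the 1/(2 kappa R D) prefactor of W the integrand of the total strain energy is
simply ``W D R = (1/2 kappa)[...]``.  The intraocular pressure enters through
its conservative potential ``-p D A`` with A the signed area enclosed by the
deformed posterior boundary and the fixed chord between its pinned endpoints.

Equilibria minimize the total potential over deformation fields ``(r, phi)``
discretized with structured bilinear elements on the (R, Phi) sector, pinned
to the identity at the limbus ``Phi = +/- Phi_star``; the solver is Newton
with analytic sparse Hessian, backtracking line search and continuation first
in pressure, then in damage amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .damage import DamageSpec, damage_profile
from .errors import ConvergenceError, CorneaSimError
from .discrete import MaterialSpec, KPA_TO_N_PER_MM2
from .geometry import CorneaGeometry

__all__ = [
    "FiberFrame",
    "StressTensor2",
    "DeformationField",
    "ContinuumSolution",
    "ContinuumModel",
    "ContinuumSolverOptions",
    "fiber_frame",
    "right_cauchy_green",
    "strain_energy_density",
    "second_pk_stress",
    "total_potential",
    "solve_continuum",
    "strong_form_residual",
]


# ---------------------------------------------------------------------------
# pointwise constitutive quantities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberFrame:
    """Unit material directions at a reference point, in the orthonormal
    polar frame (components w.r.t. ``(e_R, e_Phi)``)."""

    e_R: np.ndarray
    e_Phi: np.ndarray
    e_plus: np.ndarray
    e_minus: np.ndarray
    beta: float


def fiber_frame(R: float, kappa: float) -> FiberFrame:
    """Fiber directions at dimensionless radius ``R``: the diagonal crosslinks
    make angle ``beta = arctan(1/(kappa R))`` with the lamellar direction."""
    beta = math.atan2(1.0, kappa * R)
    s, c = math.sin(beta), math.cos(beta)
    return FiberFrame(
        e_R=np.array([1.0, 0.0]),
        e_Phi=np.array([0.0, 1.0]),
        e_plus=np.array([s, c]),
        e_minus=np.array([s, -c]),
        beta=beta,
    )


def _family_stretches(C: np.ndarray, R: float, kappa: float):
    """Stretches of the four material directions from C (2x2, polar frame)."""
    C = np.asarray(C, dtype=float)
    if C.shape != (2, 2):
        raise ValueError("C must be a 2x2 tensor in the (e_R, e_Phi) frame")
    if abs(C[0, 1] - C[1, 0]) > 1e-12 * max(1.0, abs(C).max()):
        raise ValueError("C must be symmetric")
    ev = np.linalg.eigvalsh(C)
    if ev[0] <= 0:
        raise CorneaSimError("C must be symmetric positive definite")
    fr = fiber_frame(R, kappa)
    lams = {}
    for name, e in (
        ("R", fr.e_R),
        ("Phi", fr.e_Phi),
        ("plus", fr.e_plus),
        ("minus", fr.e_minus),
    ):
        lams[name] = math.sqrt(float(e @ C @ e))
    return lams, fr


def strain_energy_density(
    C: np.ndarray,
    R: float,
    kappa: float,
    K1: float = 1.0,
    K2: float = 0.001,
    K3: float = 0.07,
    D: float = 1.0,
) -> float:
    """Dimensionless strain-energy density at a reference point.

    ``K1`` and ``K3`` may already include a local damage reduction.
    """
    lam, _ = _family_stretches(C, R, kappa)
    kR = kappa * R
    return (
        kR**2 * K1 * (lam["Phi"] - 1.0) ** 2
        + K2 * (lam["R"] - 1.0) ** 2
        + (1.0 + kR**2) * K3 * ((lam["plus"] - 1.0) ** 2 + (lam["minus"] - 1.0) ** 2)
    ) / (2.0 * kappa * R * D)


@dataclass(frozen=True)
class StressTensor2:
    """Second Piola-Kirchhoff stress components in the orthonormal polar frame."""

    T_RR: float
    T_RPhi: float
    T_PhiPhi: float

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.T_RR, self.T_RPhi], [self.T_RPhi, self.T_PhiPhi]])


def second_pk_stress(
    C: np.ndarray,
    R: float,
    kappa: float,
    K1: float = 1.0,
    K2: float = 0.001,
    K3: float = 0.07,
    D: float = 1.0,
) -> StressTensor2:
    """Second Piola-Kirchhoff stress ``T = 2 dW/dC`` at a reference point."""
    lam, _ = _family_stretches(C, R, kappa)
    kR = kappa * R
    gR = K2 * (1.0 - 1.0 / lam["R"])
    gPhi = K1 * (1.0 - 1.0 / lam["Phi"])
    gp = K3 * (1.0 - 1.0 / lam["plus"])
    gm = K3 * (1.0 - 1.0 / lam["minus"])
    T_RR = (gR + gp + gm) / (kR * D)
    T_RPhi = K3 * (1.0 / lam["minus"] - 1.0 / lam["plus"]) / D
    T_PhiPhi = kR * (gPhi + gp + gm) / D
    return StressTensor2(T_RR=T_RR, T_RPhi=T_RPhi, T_PhiPhi=T_PhiPhi)


# ---------------------------------------------------------------------------
# deformation fields
# ---------------------------------------------------------------------------


@dataclass
class DeformationField:
    """Deformed polar position field ``(R, Phi) -> (r, phi)``.

    ``r_fn`` and ``phi_fn`` are callables; if ``grad_fn`` is given it must
    return ``(r_R, r_Phi, phi_R, phi_Phi)``, otherwise derivatives are taken
    by central finite differences with step ``fd_step``.
    """

    r_fn: Callable[[float, float], float]
    phi_fn: Callable[[float, float], float]
    grad_fn: Optional[Callable] = None
    fd_step: float = 1e-6

    def __call__(self, R, Phi):
        return self.r_fn(R, Phi), self.phi_fn(R, Phi)

    def gradient(self, R, Phi):
        if self.grad_fn is not None:
            return self.grad_fn(R, Phi)
        h = self.fd_step
        r_R = (self.r_fn(R + h, Phi) - self.r_fn(R - h, Phi)) / (2 * h)
        r_P = (self.r_fn(R, Phi + h) - self.r_fn(R, Phi - h)) / (2 * h)
        p_R = (self.phi_fn(R + h, Phi) - self.phi_fn(R - h, Phi)) / (2 * h)
        p_P = (self.phi_fn(R, Phi + h) - self.phi_fn(R, Phi - h)) / (2 * h)
        return r_R, r_P, p_R, p_P

    @staticmethod
    def identity() -> "DeformationField":
        return DeformationField(
            r_fn=lambda R, Phi: R,
            phi_fn=lambda R, Phi: Phi,
            grad_fn=lambda R, Phi: (1.0, 0.0, 0.0, 1.0),
        )


def right_cauchy_green(field: DeformationField, point) -> np.ndarray:
    """Right Cauchy-Green tensor C at ``point = (R, Phi)`` in the orthonormal
    polar frame of the reference configuration.

    With ``F`` mapping ``(dR, R dPhi)`` to the deformed polar frame,
    ``C_RR = r_R^2 + r^2 phi_R^2``, ``C_PhiPhi = (r_Phi^2 + r^2 phi_Phi^2)/R^2``
    and ``C_RPhi = (r_R r_Phi + r^2 phi_R phi_Phi)/R``.
    """
    R, Phi = point
    r, _ = field(R, Phi)
    r_R, r_P, p_R, p_P = field.gradient(R, Phi)
    vals = np.array([r, r_R, r_P, p_R, p_P], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise CorneaSimError("non-finite field derivatives at evaluation point")
    C_RR = r_R**2 + r**2 * p_R**2
    C_PP = (r_P**2 + r**2 * p_P**2) / R**2
    C_RP = (r_R * r_P + r**2 * p_R * p_P) / R
    return np.array([[C_RR, C_RP], [C_RP, C_PP]])


# ---------------------------------------------------------------------------
# structured-grid energy minimization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContinuumSolverOptions:
    tol: float = 1e-10
    max_iter: int = 50
    n_pressure_steps: int = 10
    n_damage_steps: Optional[int] = None  # default: 20 if Dmax >= 0.9 else 5
    max_backtracks: int = 40


@dataclass
class ContinuumSolution:
    """Converged macroscale deformation on the structured (R, Phi) grid."""

    geom: CorneaGeometry
    material: MaterialSpec
    damage: Optional[DamageSpec]
    gamma: float
    kappa: float
    n_R: int
    n_Phi: int
    R: np.ndarray  # (n_R+1,) dimensionless
    Phi: np.ndarray  # (n_Phi+1,)
    r: np.ndarray  # (n_R+1, n_Phi+1) dimensionless
    phi: np.ndarray
    energy: float
    grad_norm: float
    pressure_kPa: float = 0.0

    @property
    def T_mm(self) -> float:
        return self.geom.T

    @property
    def R_A_mm(self) -> float:
        return self.geom.R_A

    @property
    def R_P_mm(self) -> float:
        return self.geom.R_P

    def surface_mm(self, which: str) -> np.ndarray:
        """Deformed surface polyline (x, y) in mm, ordered by increasing Y."""
        k = -1 if which == "anterior" else 0
        if which not in ("anterior", "posterior"):
            raise ValueError(f"unknown surface {which!r}")
        r = self.r[k] * self.T_mm
        return np.column_stack([r * np.cos(self.phi[k]), r * np.sin(self.phi[k])])

    def reference_surface_mm(self, which: str) -> np.ndarray:
        R = self.R_A_mm if which == "anterior" else self.R_P_mm
        return np.column_stack([R * np.cos(self.Phi), R * np.sin(self.Phi)])

    def apex_points_mm(self):
        j = self.n_Phi // 2
        ant = self.r[-1, j] * self.T_mm * np.array(
            [math.cos(self.phi[-1, j]), math.sin(self.phi[-1, j])]
        )
        post = self.r[0, j] * self.T_mm * np.array(
            [math.cos(self.phi[0, j]), math.sin(self.phi[0, j])]
        )
        return ant, post

    def as_field(self) -> DeformationField:
        """Spline interpolant of the solution as a DeformationField."""
        from scipy.interpolate import RectBivariateSpline

        rs = RectBivariateSpline(self.R, self.Phi, self.r, kx=3, ky=3)
        ps = RectBivariateSpline(self.R, self.Phi, self.phi, kx=3, ky=3)
        return DeformationField(
            r_fn=lambda R, P: float(rs(R, P)[0, 0]),
            phi_fn=lambda R, P: float(ps(R, P)[0, 0]),
            grad_fn=lambda R, P: (
                float(rs(R, P, dx=1)[0, 0]),
                float(rs(R, P, dy=1)[0, 0]),
                float(ps(R, P, dx=1)[0, 0]),
                float(ps(R, P, dy=1)[0, 0]),
            ),
        )

    def stress_at_nodes(self):
        """Second Piola-Kirchhoff components (kPa) at interior grid nodes.

        Derivatives by central differences on the grid; returns a dict of
        (n_R+1, n_Phi+1) arrays (edge values use one-sided stencils).
        """
        r_R = np.gradient(self.r, self.R, axis=0)
        r_P = np.gradient(self.r, self.Phi, axis=1)
        p_R = np.gradient(self.phi, self.R, axis=0)
        p_P = np.gradient(self.phi, self.Phi, axis=1)
        Rg = self.R[:, None]
        kap = self.kappa
        lam_R = np.sqrt(r_R**2 + self.r**2 * p_R**2)
        lam_P = np.sqrt(r_P**2 + self.r**2 * p_P**2) / Rg
        w = 1.0 / np.sqrt(1.0 + (kap * Rg) ** 2)
        hp = np.sqrt((r_R + kap * r_P) ** 2 + self.r**2 * (p_R + kap * p_P) ** 2)
        hm = np.sqrt((r_R - kap * r_P) ** 2 + self.r**2 * (p_R - kap * p_P) ** 2)
        lam_p, lam_m = w * hp, w * hm
        K2, K3 = self.material.K2_ratio(), self.material.K3_ratio()
        dam = np.ones_like(self.r)
        if self.damage is not None and self.damage.Dmax > 0:
            Y_mm = self.T_mm * Rg * np.sin(self.Phi)[None, :]
            dam = 1.0 - damage_profile(Y_mm, self.damage)
        D = self.geom.D / self.T_mm
        kR = kap * Rg
        gR = K2 * (1 - 1 / lam_R)
        gP = dam * 1.0 * (1 - 1 / lam_P)
        gp = dam * K3 * (1 - 1 / lam_p)
        gm = dam * K3 * (1 - 1 / lam_m)
        scale = self.material.K1 / self.T_mm / KPA_TO_N_PER_MM2  # -> kPa
        return {
            "T_RR_kPa": scale * (gR + gp + gm) / (kR * D),
            "T_RPhi_kPa": scale * dam * K3 * (1 / lam_m - 1 / lam_p) / D,
            "T_PhiPhi_kPa": scale * kR * (gP + gp + gm) / D,
        }


class ContinuumModel:
    """Bilinear-element discretization of the total potential on the sector.

    Nodes are ordered radial-index-fastest; element dofs are interleaved
    ``(r, phi)`` per node.  2x2 Gauss quadrature.  The per-quadrature-point
    energy is a sum over the four fiber families of ``k_f (lam_f - 1)^2``
    with ``lam_f = s_f |h_f|`` and ``h_f = (alpha_f . v, r * (beta_f . v))``
    where ``v = (r, r_R, r_Phi, phi_R, phi_Phi)`` depends linearly on the
    element dofs; gradients and Hessians are assembled analytically.
    """

    def __init__(
        self,
        geom: CorneaGeometry,
        material: MaterialSpec,
        gamma: float = 20.0,
        n_R: int = 64,
        n_Phi: Optional[int] = None,
        damage: Optional[DamageSpec] = None,
    ):
        self.geom = geom
        self.material = material
        self.gamma = gamma
        self.damage = damage
        self.n_R = n_R
        self.n_Phi = int(round(gamma * n_R)) if n_Phi is None else n_Phi

        nd = geom.nondimensional()
        self.kappa = 2.0 * geom.Phi_star / gamma
        self.R = np.linspace(nd.R_P, nd.R_A, n_R + 1)
        self.Phi = np.linspace(-geom.Phi_star, geom.Phi_star, self.n_Phi + 1)
        self.dR = self.R[1] - self.R[0]
        self.dPhi = self.Phi[1] - self.Phi[0]
        self.D = nd.D
        self.p_target = material.p_dimensionless(geom.T)

        self._build_topology()
        self._build_quadrature()
        self._fact = None  # cached banded Cholesky factor (chord Newton)
        self.set_damage_scale(1.0 if damage is not None else 0.0)

    # -- topology ----------------------------------------------------------
    def _node(self, k, l):
        return l * (self.n_R + 1) + k

    def _build_topology(self):
        nR, nP = self.n_R, self.n_Phi
        self.n_nodes = (nR + 1) * (nP + 1)
        k = np.arange(nR)
        l = np.arange(nP)
        K, L = np.meshgrid(k, l, indexing="ij")  # element (k, l)
        K = K.ravel(order="F")  # element index n = l*nR + k
        L = L.ravel(order="F")
        n1 = self._node(K, L)
        n2 = self._node(K + 1, L)
        n3 = self._node(K, L + 1)
        n4 = self._node(K + 1, L + 1)
        nodes = np.stack([n1, n2, n3, n4], axis=1)  # (nel, 4)
        dofs = np.empty((nodes.shape[0], 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * nodes
        dofs[:, 1::2] = 2 * nodes + 1
        self.el_k = K
        self.el_l = L
        self.el_dofs = dofs
        self.n_el = nodes.shape[0]

        # Dirichlet: limbus columns l = 0 and l = nP
        ll = np.arange(self.n_nodes) // (nR + 1)
        free_nodes = (ll != 0) & (ll != nP)
        self.free_dof_mask = np.repeat(free_nodes, 2)
        self.free_dofs = np.where(self.free_dof_mask)[0]

        # posterior boundary nodes (k = 0), ordered by l
        self.post_nodes = self._node(0, np.arange(nP + 1))

        # COO indices for the full (all-dof) Hessian scatter
        rows = np.repeat(dofs, 8, axis=1).ravel()
        cols = np.tile(dofs, (1, 8)).ravel()
        self._h_rows = rows
        self._h_cols = cols

        # pressure-Hessian structure (fixed): 4x4 blocks per posterior segment
        i1 = self.post_nodes[:-1]
        i2 = self.post_nodes[1:]
        segdofs = np.stack([2 * i1, 2 * i1 + 1, 2 * i2, 2 * i2 + 1], axis=1)
        self._p_rows = np.repeat(segdofs, 4, axis=1).ravel()
        self._p_cols = np.tile(segdofs, (1, 4)).ravel()

        # banded (upper) storage mapping for the free-dof Hessian:
        # reduced index keeps the radial-fastest order, so the half-bandwidth
        # is ~2*(n_R+2); entries outside free x free or in the lower triangle
        # are dropped (the matrix is symmetric).
        free_map = -np.ones(2 * self.n_nodes, dtype=np.int64)
        free_map[self.free_dofs] = np.arange(self.free_dofs.size)
        self.n_free = self.free_dofs.size
        all_rows = np.concatenate([self._h_rows, self._p_rows])
        all_cols = np.concatenate([self._h_cols, self._p_cols])
        fr, fc = free_map[all_rows], free_map[all_cols]
        keep = (fr >= 0) & (fc >= 0) & (fr <= fc)
        self._band_keep = keep
        bw = int((fc[keep] - fr[keep]).max())
        self._bw = bw
        self._band_flat = (bw + fr[keep] - fc[keep]) * self.n_free + fc[keep]
        self._n_el_hvals = self._h_rows.size

    def _build_quadrature(self):
        gp = np.array([0.5 - 0.5 / math.sqrt(3.0), 0.5 + 0.5 / math.sqrt(3.0)])
        xi, eta = np.meshgrid(gp, gp, indexing="ij")
        xi = xi.ravel()
        eta = eta.ravel()  # 4 quadrature points per element
        self.w_q = self.dR * self.dPhi / 4.0

        # B: (4 qp, 5 strains, 8 dofs); v = (r, r_R, r_Phi, phi_R, phi_Phi)
        B = np.zeros((4, 5, 8))
        for q in range(4):
            x, e = xi[q], eta[q]
            N = np.array([(1 - x) * (1 - e), x * (1 - e), (1 - x) * e, x * e])
            dNdx = np.array([-(1 - e), (1 - e), -e, e]) / self.dR
            dNde = np.array([-(1 - x), -x, (1 - x), x]) / self.dPhi
            B[q, 0, 0::2] = N
            B[q, 1, 0::2] = dNdx
            B[q, 2, 0::2] = dNde
            B[q, 3, 1::2] = dNdx
            B[q, 4, 1::2] = dNde
        self.B = B

        # reference R, Phi at quadrature points, (nel, 4)
        self.R_q = self.R[self.el_k][:, None] + xi[None, :] * self.dR
        Phi_q = self.Phi[self.el_l][:, None] + eta[None, :] * self.dPhi
        self.Y_q_mm = self.geom.T * self.R_q * np.sin(Phi_q)
        self.w_of_Rq = 1.0 / np.sqrt(1.0 + (self.kappa * self.R_q) ** 2)

    def set_damage_scale(self, scale: float):
        """Set the damage amplitude factor (continuation variable) and
        recompute the per-quadrature-point family stiffness weights."""
        dam = np.ones_like(self.R_q)
        if self.damage is not None and scale > 0.0:
            spec = DamageSpec(
                Dmax=scale * self.damage.Dmax, xi=self.damage.xi, Y_max=self.damage.Y_max
            )
            dam = 1.0 - damage_profile(self.Y_q_mm, spec)
        kap = self.kappa
        kR2 = (kap * self.R_q) ** 2
        K2, K3 = self.material.K2_ratio(), self.material.K3_ratio()
        c = self.w_q / (2.0 * kap)
        self.k_Phi = c * kR2 * dam  # K1 = 1 (healthy), damage-reduced
        self.k_R = c * K2 * np.ones_like(self.R_q)
        self.k_pm = c * (1.0 + kR2) * K3 * dam
        self.damage_scale = scale

    # -- kinematics at quadrature points -----------------------------------
    def _v(self, u: np.ndarray) -> np.ndarray:
        """Generalized strains v = (r, r_R, r_Phi, phi_R, phi_Phi), (nel, 4, 5)."""
        ue = u.ravel()[self.el_dofs]  # (nel, 8)
        return np.einsum("qvi,ni->nqv", self.B, ue)

    def identity_state(self) -> np.ndarray:
        u = np.empty((self.n_nodes, 2))
        kk = np.arange(self.n_nodes) % (self.n_R + 1)
        ll = np.arange(self.n_nodes) // (self.n_R + 1)
        u[:, 0] = self.R[kk]
        u[:, 1] = self.Phi[ll]
        return u

    _families = (
        # (alpha indices/coeffs, beta indices/coeffs) built lazily with kappa
    )

    def _family_defs(self):
        kap = self.kappa
        e = np.eye(5)
        return (
            # name, alpha (5,), beta (5,), s (nel, 4), k (nel, 4)
            ("Phi", e[2], e[4], 1.0 / self.R_q, self.k_Phi),
            ("R", e[1], e[3], np.ones_like(self.R_q), self.k_R),
            ("plus", e[1] + kap * e[2], e[3] + kap * e[4], self.w_of_Rq, self.k_pm),
            ("minus", e[1] - kap * e[2], e[3] - kap * e[4], self.w_of_Rq, self.k_pm),
        )

    def _det_F(self, v: np.ndarray) -> np.ndarray:
        """det F = r (r_R phi_Phi - r_Phi phi_R) / R at quadrature points."""
        r, a, b, c, d = (v[..., i] for i in range(5))
        return r * (a * d - b * c) / self.R_q

    # -- energy / gradient / Hessian ---------------------------------------
    def _pressure_area(self, u: np.ndarray) -> float:
        r = u[self.post_nodes, 0]
        ph = u[self.post_nodes, 1]
        # closed polygon: posterior polyline + chord between pinned endpoints
        seg = 0.5 * r[:-1] * r[1:] * np.sin(ph[1:] - ph[:-1])
        chord = 0.5 * r[-1] * r[0] * np.sin(ph[0] - ph[-1])
        return float(seg.sum() + chord)

    def energy(self, u: np.ndarray, p: Optional[float] = None, check_detF: bool = False) -> float:
        if p is None:
            p = self.p_target
        v = self._v(u)
        if check_detF and np.any(self._det_F(v) <= 0):
            return np.inf
        E = 0.0
        for _, alpha, beta, s, k in self._family_defs():
            h1 = np.einsum("v,nqv->nq", alpha, v)
            h2 = v[..., 0] * np.einsum("v,nqv->nq", beta, v)
            lam = s * np.hypot(h1, h2)
            E += float(np.sum(k * (lam - 1.0) ** 2))
        return E - p * self.D * self._pressure_area(u)

    def _pressure_grad_hess(self, u, p, want_hess):
        """Gradient (n_dofs,) and optional Hessian block values of -p*D*A.

        Hessian values align with the precomputed ``_p_rows/_p_cols``
        structure (4x4 block per posterior segment, dof order
        ``(r1, phi1, r2, phi2)``).
        """
        nodes = self.post_nodes
        r = u[nodes, 0]
        ph = u[nodes, 1]
        n_seg = nodes.size - 1
        G = np.zeros(2 * self.n_nodes)
        c = -p * self.D
        i1, i2 = nodes[:-1], nodes[1:]
        dphi = ph[1:] - ph[:-1]
        sn, cs = np.sin(dphi), np.cos(dphi)
        r1, r2 = r[:-1], r[1:]
        # dA/d(r1, ph1, r2, ph2) per segment
        dA = np.stack(
            [0.5 * r2 * sn, -0.5 * r1 * r2 * cs, 0.5 * r1 * sn, 0.5 * r1 * r2 * cs],
            axis=1,
        )
        np.add.at(G, 2 * i1, c * dA[:, 0])
        np.add.at(G, 2 * i1 + 1, c * dA[:, 1])
        np.add.at(G, 2 * i2, c * dA[:, 2])
        np.add.at(G, 2 * i2 + 1, c * dA[:, 3])
        if not want_hess:
            return G, None
        # Hessian blocks, order (r1, ph1, r2, ph2)
        Hseg = np.zeros((n_seg, 4, 4))
        Hseg[:, 0, 1] = Hseg[:, 1, 0] = -0.5 * r2 * cs
        Hseg[:, 0, 2] = Hseg[:, 2, 0] = 0.5 * sn
        Hseg[:, 0, 3] = Hseg[:, 3, 0] = 0.5 * r2 * cs
        Hseg[:, 1, 1] = -0.5 * r1 * r2 * sn
        Hseg[:, 1, 2] = Hseg[:, 2, 1] = -0.5 * r1 * cs
        Hseg[:, 1, 3] = Hseg[:, 3, 1] = 0.5 * r1 * r2 * sn
        Hseg[:, 2, 3] = Hseg[:, 3, 2] = 0.5 * r1 * cs
        Hseg[:, 3, 3] = -0.5 * r1 * r2 * sn
        Hseg *= c
        return G, Hseg.ravel()

    def gradient(self, u: np.ndarray, p: Optional[float] = None) -> np.ndarray:
        G, _, _ = self._grad_hess(u, p, want_hess=False)
        return G

    def hessian(self, u: np.ndarray, p: Optional[float] = None) -> sp.csr_matrix:
        """Full sparse Hessian of the total potential (all dofs)."""
        _, hvals, pvals = self._grad_hess(u, p, want_hess=True)
        rows = np.concatenate([self._h_rows, self._p_rows])
        cols = np.concatenate([self._h_cols, self._p_cols])
        vals = np.concatenate([hvals, pvals])
        return sp.coo_matrix((vals, (rows, cols)), shape=(2 * self.n_nodes,) * 2).tocsr()

    def _band_hessian(self, u, p) -> np.ndarray:
        """Free-dof Hessian in LAPACK upper-banded storage, shape (bw+1, n_free)."""
        _, hvals, pvals = self._grad_hess(u, p, want_hess=True)
        vals = np.concatenate([hvals, pvals])[self._band_keep]
        ab = np.bincount(
            self._band_flat, weights=vals, minlength=(self._bw + 1) * self.n_free
        )
        return ab.reshape(self._bw + 1, self.n_free)

    def _grad_hess(self, u: np.ndarray, p: Optional[float], want_hess: bool):
        if p is None:
            p = self.p_target
        v = self._v(u)
        r = v[..., 0]
        e_r = np.zeros(5)
        e_r[0] = 1.0
        gv = np.zeros_like(v)  # (nel, 4, 5)
        Mv = np.zeros(v.shape[:2] + (5, 5)) if want_hess else None

        for _, alpha, beta, s, k in self._family_defs():
            P = np.einsum("v,nqv->nq", alpha, v)
            Q = np.einsum("v,nqv->nq", beta, v)
            h1 = P
            h2 = r * Q
            nh = np.hypot(h1, h2)
            nh = np.maximum(nh, 1e-300)
            lam = s * nh
            hh1, hh2 = h1 / nh, h2 / nh
            c1 = 2.0 * k * (lam - 1.0) * s
            g1 = c1 * hh1
            g2 = c1 * hh2
            # m = dh2/dv = Q e_r + r beta
            m = Q[..., None] * e_r + r[..., None] * beta
            gv += g1[..., None] * alpha + g2[..., None] * m
            if want_hess:
                A1 = 2.0 * k * s**2
                A2 = 2.0 * k * (lam - 1.0) * s / nh
                H11 = A1 * hh1**2 + A2 * (1.0 - hh1**2)
                H12 = (A1 - A2) * hh1 * hh2
                H22 = A1 * hh2**2 + A2 * (1.0 - hh2**2)
                aa = np.einsum("a,b->ab", alpha, alpha)
                Mv += H11[..., None, None] * aa
                am = alpha[None, None, :, None] * m[..., None, :]
                Mv += H12[..., None, None] * (am + np.swapaxes(am, -1, -2))
                Mv += H22[..., None, None] * (m[..., :, None] * m[..., None, :])
                eb = np.einsum("a,b->ab", e_r, beta)
                Mv += g2[..., None, None] * (eb + eb.T)

        ge = np.einsum("qvi,nqv->ni", self.B, gv, optimize=True)  # (nel, 8)
        G = np.zeros(2 * self.n_nodes)
        np.add.at(G, self.el_dofs.ravel(), ge.ravel())
        Gp, pvals = self._pressure_grad_hess(u, p, want_hess)
        G += Gp
        if not want_hess:
            return G, None, None
        He = np.einsum("qai,nqab,qbj->nij", self.B, Mv, self.B, optimize=True)
        return G, He.ravel(), pvals

    # -- Newton solve -------------------------------------------------------
    def _factorize(self, u, p):
        """Banded Cholesky factor of the free-dof Hessian, regularizing the
        diagonal if the matrix is locally indefinite."""
        ab = self._band_hessian(u, p)
        try:
            return sla.cholesky_banded(ab, lower=False, check_finite=False)
        except np.linalg.LinAlgError:
            pass
        tau = 1e-10 * max(1.0, float(np.abs(ab[-1]).max()))
        for _ in range(30):
            ab_reg = ab.copy()
            ab_reg[-1] += tau
            try:
                return sla.cholesky_banded(ab_reg, lower=False, check_finite=False)
            except np.linalg.LinAlgError:
                tau *= 10.0
        raise ConvergenceError("Hessian factorization failed")

    def _newton(self, u, p, opts: ContinuumSolverOptions):
        """Newton iteration at fixed load, reusing the Hessian factorization
        across iterations (and continuation steps) while it still yields fast
        residual reduction; refactorized when progress degrades."""
        free = self.free_dofs
        prev_gnorm = None
        used_stale = False
        for it in range(opts.max_iter):
            G = self.gradient(u, p)
            g = G[free]
            gnorm = float(np.abs(g).max())
            if gnorm <= opts.tol:
                return u, gnorm
            if used_stale and prev_gnorm is not None and gnorm > 0.2 * prev_gnorm:
                self._fact = None  # stale factorization converging too slowly
            if self._fact is None:
                self._fact = self._factorize(u, p)
                used_stale = False
            else:
                used_stale = True
            delta = sla.cho_solve_banded((self._fact, False), -g, check_finite=False)
            if not np.all(np.isfinite(delta)) or float(-delta @ g) <= 0:
                self._fact = self._factorize(u, p)
                used_stale = False
                delta = sla.cho_solve_banded((self._fact, False), -g, check_finite=False)
                if not np.all(np.isfinite(delta)) or float(-delta @ g) <= 0:
                    raise ConvergenceError(
                        "could not produce a descent direction",
                        residual_norm=gnorm,
                        step=it,
                    )
            e0 = self.energy(u, p)
            t = 1.0
            for _ in range(opts.max_backtracks):
                u_try = u.copy()
                u_try.ravel()[free] += t * delta
                e1 = self.energy(u_try, p, check_detF=True)
                if e1 < e0 + 1e-12 * abs(e0):
                    break
                t *= 0.5
            else:
                raise ConvergenceError("line search stalled", residual_norm=gnorm, step=it)
            u = u_try
            if t < 1.0:
                self._fact = None  # state moved far; refresh next iteration
            prev_gnorm = gnorm
        G = self.gradient(u, p)
        gnorm = float(np.abs(G[free]).max())
        if gnorm > opts.tol:
            raise ConvergenceError(
                f"Newton did not converge (gradient {gnorm:.3e})", residual_norm=gnorm
            )
        return u, gnorm

    def solve(
        self,
        options: Optional[ContinuumSolverOptions] = None,
        initial: Optional[np.ndarray] = None,
    ) -> ContinuumSolution:
        """Minimize the total potential with continuation, first ramping the
        pressure (healthy stiffness), then the damage amplitude."""
        opts = options or ContinuumSolverOptions()
        has_damage = self.damage is not None and self.damage.Dmax > 0
        self.set_damage_scale(0.0)
        self._fact = None
        u = self.identity_state() if initial is None else initial.copy()
        gnorm = 0.0
        if self.p_target != 0.0:
            for k in range(1, opts.n_pressure_steps + 1):
                p_k = self.p_target * k / opts.n_pressure_steps
                u, gnorm = self._newton(u, p_k, opts)
        else:
            u, gnorm = self._newton(u, 0.0, opts)
        if has_damage:
            n_steps = opts.n_damage_steps
            if n_steps is None:
                n_steps = 20 if self.damage.Dmax >= 0.9 else 5
            for k in range(1, n_steps + 1):
                self.set_damage_scale(k / n_steps)
                u, gnorm = self._newton(u, self.p_target, opts)
        energy = self.energy(u)
        nR, nP = self.n_R, self.n_Phi
        r = u[:, 0].reshape(nP + 1, nR + 1).T
        phi = u[:, 1].reshape(nP + 1, nR + 1).T
        return ContinuumSolution(
            geom=self.geom,
            material=self.material,
            damage=self.damage if has_damage else None,
            gamma=self.gamma,
            kappa=self.kappa,
            n_R=nR,
            n_Phi=nP,
            R=self.R,
            Phi=self.Phi,
            r=r,
            phi=phi,
            energy=energy,
            grad_norm=gnorm,
            pressure_kPa=self.material.p,
        )


def total_potential(model: ContinuumModel, u: np.ndarray, p: Optional[float] = None) -> float:
    """Total potential of a nodal state: strain energy (measure D R dR dPhi)
    minus ``p D A_enc``; +inf if det F <= 0 at any quadrature point."""
    return model.energy(u, p, check_detF=True)


def solve_continuum(config, n_R: Optional[int] = None, healthy: Optional[bool] = None,
                    options: Optional[ContinuumSolverOptions] = None,
                    initial: Optional[np.ndarray] = None) -> ContinuumSolution:
    """Solve the macroscale equilibrium for a full configuration object.

    ``config`` provides ``geometry``, ``discretization`` (for gamma),
    ``material``, ``damage`` and ``continuum`` grid sizes (see
    :mod:`corneasim.config`).  ``healthy=True`` drops the damage field;
    ``n_R`` overrides the radial element count (azimuthal count follows the
    gamma-consistent aspect unless the config pins it).
    """
    damage = None if healthy else config.damage
    nR = n_R if n_R is not None else config.continuum.n_R
    nPhi = None
    if n_R is None and config.continuum.n_Phi is not None:
        nPhi = config.continuum.n_Phi
    model = ContinuumModel(
        geom=config.geometry,
        material=config.material,
        gamma=config.discretization.gamma,
        n_R=nR,
        n_Phi=nPhi,
        damage=damage,
    )
    return model.solve(options=options or config.continuum.solver_options(), initial=initial)


def strong_form_residual(sol: ContinuumSolution):
    """Interior residual of the upscaled strong-form balance equations.

    Evaluates the radial and azimuthal components of the macroscale momentum
    balance by central finite differences of the converged fields, using the
    family force-per-length functions ``G = g(lam)``; an independent check
    that the energy minimizer satisfies the upscaled equilibrium PDE.
    Returns ``(res_r, res_phi)`` on interior grid nodes,
    shape ``(n_R - 1, n_Phi - 1)``.
    """
    kap = sol.kappa
    R, Phi = sol.R, sol.Phi
    r, phi = sol.r, sol.phi
    K2, K3 = sol.material.K2_ratio(), sol.material.K3_ratio()

    def ddR(f):
        return np.gradient(f, R, axis=0)

    def ddP(f):
        return np.gradient(f, Phi, axis=1)

    r_R, r_P = ddR(r), ddP(r)
    p_R, p_P = ddR(phi), ddP(phi)

    dam = np.ones_like(r)
    if sol.damage is not None:
        Y_mm = sol.T_mm * R[:, None] * np.sin(Phi)[None, :]
        dam = 1.0 - damage_profile(Y_mm, sol.damage)
    w = 1.0 / np.sqrt(1.0 + (kap * R[:, None]) ** 2)
    q = 1.0 / (kap * R[:, None])

    lam_P = q * np.sqrt((kap * r_P) ** 2 + (kap * r * p_P) ** 2)
    lam_R = np.sqrt(r_R**2 + (r * p_R) ** 2)
    lam_p = w * np.sqrt((r_R + kap * r_P) ** 2 + (r * p_R + kap * r * p_P) ** 2)
    lam_m = w * np.sqrt((r_R - kap * r_P) ** 2 + (r * p_R - kap * r * p_P) ** 2)
    G1 = dam * (1.0 - 1.0 / lam_P)
    G2 = K2 * (1.0 - 1.0 / lam_R)
    Gp = dam * K3 * (1.0 - 1.0 / lam_p)
    Gm = dam * K3 * (1.0 - 1.0 / lam_m)

    res_r = (
        kap**2 * (ddP(r_P * G1) - r * p_P**2 * G1)
        + (ddR(r_R * G2) - r * p_R**2 * G2)
        + ddR((r_R + kap * r_P) * Gp + (r_R - kap * r_P) * Gm)
        + kap * ddP((r_R + kap * r_P) * Gp - (r_R - kap * r_P) * Gm)
        - (p_R + kap * p_P) * (r * p_R + kap * r * p_P) * Gp
        - (p_R - kap * p_P) * (r * p_R - kap * r * p_P) * Gm
    )
    res_phi = (
        kap**2 * (ddP(r * p_P * G1) + r_P * p_P * G1)
        + (ddR(r * p_R * G2) + r_R * p_R * G2)
        + ddR((r * p_R + kap * r * p_P) * Gp + (r * p_R - kap * r * p_P) * Gm)
        + kap * ddP((r * p_R + kap * r * p_P) * Gp - (r * p_R - kap * r * p_P) * Gm)
        + (p_R + kap * p_P) * (r_R + kap * r_P) * Gp
        + (p_R - kap * p_P) * (r_R - kap * r_P) * Gm
    )
    return res_r[1:-1, 1:-1], res_phi[1:-1, 1:-1]
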