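"""Finite-kinematics equilibrium of the corneal spring lattice.

The slice is a truss of three element families — lamellar segments along each
arc, radial crosslinks between arcs, and diagonal crosslinks resisting
inter-lamellar shear — loaded by the intraocular pressure (IOP) on the
posterior surface and pinned at the limbus.  Every element is a linear spring,
force ``f = K (l - L)``, stress-free in the reference configuration.

Internally everything is dimensionless: lengths are scaled by the thickness T
and forces by ``K1 * T`` where K1 is the (healthy) lamellar stiffness.  The
IOP enters through its conservative potential ``-p * D * A``, where A is the
signed area enclosed by the deformed posterior polyline and the fixed chord
between its pinned endpoints; the gradient of this potential reproduces the
half-segment nodal pressure forces of the follower load exactly, and keeps
the residual a true gradient so that the Jacobian is symmetric.

Equilibria are found by Newton's method with an analytic sparse Jacobian,
backtracking line search on the total potential, and incremental pressure
continuation from the stress-free reference state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .damage import DamageSpec, damage_profile
from .errors import ConvergenceError, DegenerateElementError
from .geometry import CorneaGeometry, Discretization, build_nodes, rest_lengths

__all__ = [
    "MaterialSpec",
    "DiscreteNetwork",
    "DiscreteState",
    "DiscreteSolution",
    "SolverOptions",
    "build_network",
    "force_per_length",
    "iop_nodal_forces",
    "residual",
    "jacobian",
    "total_potential",
    "solve_discrete",
    "lamellar_stress",
]

# element family codes
LAMELLAR, RADIAL, DIAGONAL = 1, 2, 3

KPA_TO_N_PER_MM2 = 1e-3  # 1 kPa = 1e-3 N/mm^2


@dataclass(frozen=True)
class MaterialSpec:
    """Element stiffness (N/mm) and intraocular pressure (kPa).

    ``K1``, ``K2``, ``K3`` are the axial stiffness of the lamellar, radial and
    diagonal families; optionally they derive from Young's moduli ``E`` (kPa)
    and a cross-sectional area ``A`` (mm^2) through ``K = E*A/L``, but the
    solver only ever consumes the stiffness values themselves.
    """

    K1: float = 7.2
    K2: float = 0.0072
    K3: float = 0.504
    p: float = 2.0
    E1: Optional[float] = None
    E2: Optional[float] = None
    E3: Optional[float] = None
    A: Optional[float] = None

    def __post_init__(self):
        if min(self.K1, self.K2, self.K3) <= 0:
            raise ValueError("all stiffness values must be positive")

    # dimensionless groups (forces scaled by K1*T)
    def K2_ratio(self) -> float:
        return self.K2 / self.K1

    def K3_ratio(self) -> float:
        return self.K3 / self.K1

    def p_dimensionless(self, T_mm: float) -> float:
        """``p * T / K1`` with p converted from kPa to N/mm^2."""
        return self.p * KPA_TO_N_PER_MM2 * T_mm / self.K1


def force_per_length(lam, K):
    """Force per unit current length of a spring at stretch ``lam``:
    ``g(lam) = K (1 - 1/lam)``; negative in compression, asymptote K in tension."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise DegenerateElementError(f"stretch must be positive, got min {lam.min()}")
    out = K * (1.0 - 1.0 / lam)
    return float(out) if out.ndim == 0 else out


def iop_nodal_forces(positions: np.ndarray, p: float, D: float) -> np.ndarray:
    """Equivalent nodal IOP forces on the posterior polyline.

    ``positions`` is the (M+1, 2) current posterior polyline ordered
    counterclockwise (limbus to limbus).  Interior node j receives
    ``(p D / 2) * (l_{j-1/2} n_{j-1/2} + l_{j+1/2} n_{j+1/2})`` with ``n`` the
    unit normal pointing from the posterior surface into the tissue; end nodes
    receive their single half-segment contribution (they are pinned anyway).
    """
    pos = np.asarray(positions, dtype=float)
    seg = pos[1:] - pos[:-1]  # (M, 2)
    ell = np.linalg.norm(seg, axis=1)
    if np.any(ell == 0):
        raise DegenerateElementError("posterior polyline has a zero-length segment")
    # counterclockwise traversal: into-tissue (outward from arc centre) normal
    ln = np.column_stack([seg[:, 1], -seg[:, 0]])  # l * n_hat
    forces = np.zeros_like(pos)
    forces[:-1] += 0.5 * p * D * ln
    forces[1:] += 0.5 * p * D * ln
    return forces


def _enclosed_area(pos: np.ndarray) -> float:
    """Signed area of the polygon (posterior polyline + closing chord)."""
    x, y = pos[:, 0], pos[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


@dataclass
class DiscreteNetwork:
    """Assembled lattice: dimensionless reference nodes, element connectivity,
    rest lengths, per-element (possibly damage-reduced) stiffness, and loads."""

    geom: CorneaGeometry  # dimensional (mm)
    disc: Discretization
    material: MaterialSpec
    damage: Optional[DamageSpec] = None
    # dimensionless quantities, filled by build_network
    X: np.ndarray = field(default=None, repr=False)  # (n_nodes, 2) reference
    family: np.ndarray = field(default=None, repr=False)  # (n_el,)
    conn: np.ndarray = field(default=None, repr=False)  # (n_el, 2) node ids
    L: np.ndarray = field(default=None, repr=False)  # (n_el,) rest lengths
    K: np.ndarray = field(default=None, repr=False)  # (n_el,) stiffness / K1
    free_nodes: np.ndarray = field(default=None, repr=False)
    posterior_nodes: np.ndarray = field(default=None, repr=False)
    p: float = 0.0  # dimensionless pressure p*T/K1
    D: float = 1.0  # dimensionless depth D/T

    def node_id(self, i, j):
        return i * (self.disc.M + 1) + j

    @property
    def n_nodes(self) -> int:
        return (self.disc.N + 1) * (self.disc.M + 1)

    @property
    def n_free(self) -> int:
        return self.free_nodes.size

    def grid_positions(self, x_flat: np.ndarray) -> np.ndarray:
        """Reshape flat (n_nodes, 2) positions to (N+1, M+1, 2)."""
        return x_flat.reshape(self.disc.N + 1, self.disc.M + 1, 2)


@dataclass
class DiscreteState:
    """Current nodal positions (dimensionless), full grid including pinned rows."""

    x: np.ndarray  # (n_nodes, 2)


@dataclass
class DiscreteSolution:
    """Converged equilibrium of the lattice at a given pressure."""

    network: DiscreteNetwork
    state: DiscreteState
    stretches: np.ndarray  # per element
    forces: np.ndarray  # per element, dimensionless (scaled by K1*T)
    residual_norm: float
    pressure_kPa: float

    # ---- unit-bearing views -------------------------------------------------
    @property
    def T_mm(self) -> float:
        return self.network.geom.T

    def displacements_mm(self) -> np.ndarray:
        """(n_nodes, 2) nodal displacement vectors in mm."""
        return (self.state.x - self.network.X) * self.T_mm

    def max_displacement_mm(self) -> float:
        return float(np.linalg.norm(self.displacements_mm(), axis=1).max())

    def _surface_nodes(self, i: int) -> np.ndarray:
        net = self.network
        ids = [net.node_id(i, j) for j in range(net.disc.M + 1)]
        return self.state.x[ids] * self.T_mm

    def surface_mm(self, which: str) -> np.ndarray:
        """Deformed surface polyline in mm, ordered by increasing Y.

        ``which`` is 'anterior' or 'posterior'.
        """
        if which == "anterior":
            return self._surface_nodes(self.network.disc.N)
        if which == "posterior":
            return self._surface_nodes(0)
        raise ValueError(f"unknown surface {which!r}")

    def reference_surface_mm(self, which: str) -> np.ndarray:
        net = self.network
        i = net.disc.N if which == "anterior" else 0
        ids = [net.node_id(i, j) for j in range(net.disc.M + 1)]
        return net.X[ids] * self.T_mm

    def apex_points_mm(self):
        """(anterior, posterior) deformed apex positions in mm."""
        net = self.network
        j = net.disc.M // 2
        ant = self.state.x[net.node_id(net.disc.N, j)] * self.T_mm
        post = self.state.x[net.node_id(0, j)] * self.T_mm
        return np.asarray(ant), np.asarray(post)

    @property
    def R_A_mm(self) -> float:
        return self.network.geom.R_A

    @property
    def R_P_mm(self) -> float:
        return self.network.geom.R_P


def build_network(
    geom: CorneaGeometry,
    disc: Discretization,
    material: MaterialSpec,
    damage: Optional[DamageSpec] = None,
) -> DiscreteNetwork:
    """Assemble the dimensionless lattice for the given parameters.

    Element families follow the lattice connectivity: lamellar segments
    ``(i,j)-(i,j+1)``, radial struts ``(i,j)-(i+1,j)`` and diagonal struts
    ``(i,j)-(i+1,j+1)`` and ``(i,j)-(i+1,j-1)``.  Damage, when present, is
    evaluated at the reference midpoint Y of each element and reduces the
    lamellar and diagonal stiffness only.
    """
    nd = geom.nondimensional()
    N, M = disc.N, disc.M
    grid = build_nodes(nd, disc)
    lengths = rest_lengths(nd, disc)

    X = np.column_stack([grid.X.ravel(), grid.Y.ravel()])

    def nid(i, j):
        return i * (M + 1) + j

    fam, conn, L = [], [], []
    # lamellar: along each arc
    for i in range(N + 1):
        for j in range(M):
            fam.append(LAMELLAR)
            conn.append((nid(i, j), nid(i, j + 1)))
            L.append(lengths.L1[i])
    # radial: between arcs
    for i in range(N):
        for j in range(M + 1):
            fam.append(RADIAL)
            conn.append((nid(i, j), nid(i + 1, j)))
            L.append(lengths.L2)
    # diagonal: (i,j)-(i+1,j+1) and (i,j)-(i+1,j-1)
    for i in range(N):
        for j in range(M):
            fam.append(DIAGONAL)
            conn.append((nid(i, j), nid(i + 1, j + 1)))
            L.append(lengths.L3[i])
        for j in range(1, M + 1):
            fam.append(DIAGONAL)
            conn.append((nid(i, j), nid(i + 1, j - 1)))
            L.append(lengths.L3[i])

    fam = np.asarray(fam)
    conn = np.asarray(conn)
    L = np.asarray(L)

    base = np.where(fam == LAMELLAR, 1.0, 0.0)
    base += np.where(fam == RADIAL, material.K2_ratio(), 0.0)
    base += np.where(fam == DIAGONAL, material.K3_ratio(), 0.0)
    K = base.copy()
    if damage is not None and damage.Dmax > 0:
        Ymid = 0.5 * (X[conn[:, 0], 1] + X[conn[:, 1], 1]) * geom.T  # back to mm
        d = damage_profile(Ymid, damage)
        reducible = fam != RADIAL
        K = np.where(reducible, (1.0 - d) * K, K)

    jj = np.arange((N + 1) * (M + 1)) % (M + 1)
    free_nodes = np.where((jj != 0) & (jj != M))[0]
    posterior_nodes = np.array([nid(0, j) for j in range(M + 1)])

    return DiscreteNetwork(
        geom=geom,
        disc=disc,
        material=material,
        damage=damage,
        X=X,
        family=fam,
        conn=conn,
        L=L,
        K=K,
        free_nodes=free_nodes,
        posterior_nodes=posterior_nodes,
        p=material.p_dimensionless(geom.T),
        D=geom.D / geom.T,
    )


# ---------------------------------------------------------------------------
# energy, residual, Jacobian
# ---------------------------------------------------------------------------


def _element_lengths(net: DiscreteNetwork, x: np.ndarray):
    d = x[net.conn[:, 1]] - x[net.conn[:, 0]]
    ell = np.linalg.norm(d, axis=1)
    if np.any(ell <= 0):
        raise DegenerateElementError("coincident connected nodes")
    return d, ell


def total_potential(net: DiscreteNetwork, x: np.ndarray, p: Optional[float] = None) -> float:
    """Total potential: spring energy minus ``p * D * (enclosed area)``."""
    if p is None:
        p = net.p
    _, ell = _element_lengths(net, x)
    e_spring = 0.5 * float(np.sum(net.K * (ell - net.L) ** 2))
    area = _enclosed_area(x[net.posterior_nodes])
    return e_spring - p * net.D * area


def _gradient(net: DiscreteNetwork, x: np.ndarray, p: float) -> np.ndarray:
    """Gradient of the total potential w.r.t. all nodal positions, (n_nodes, 2)."""
    d, ell = _element_lengths(net, x)
    u = d / ell[:, None]
    fmag = net.K * (ell - net.L)
    g = np.zeros_like(x)
    np.add.at(g, net.conn[:, 1], fmag[:, None] * u)
    np.add.at(g, net.conn[:, 0], -fmag[:, None] * u)
    # pressure: -p*D*dA/dx on posterior nodes
    pos = x[net.posterior_nodes]
    nxt = np.roll(pos, -1, axis=0)
    prv = np.roll(pos, 1, axis=0)
    dA = 0.5 * np.column_stack([nxt[:, 1] - prv[:, 1], prv[:, 0] - nxt[:, 0]])
    np.add.at(g, net.posterior_nodes, -p * net.D * dA)
    return g


def residual(net: DiscreteNetwork, state: DiscreteState, p: Optional[float] = None) -> np.ndarray:
    """Force imbalance (negative potential gradient) at free nodes, stacked
    as a flat ``(2 * n_free,)`` vector."""
    if p is None:
        p = net.p
    g = _gradient(net, state.x, p)
    return -g[net.free_nodes].ravel()


def jacobian(net: DiscreteNetwork, state: DiscreteState, p: Optional[float] = None) -> sp.csr_matrix:
    """Sparse Jacobian of the residual w.r.t. free nodal positions.

    Equals minus the Hessian of the total potential; includes the
    configuration dependence of the follower pressure load.
    """
    return (-_hessian_free(net, state.x, p if p is not None else net.p)).tocsr()


def _hessian_free(net: DiscreteNetwork, x: np.ndarray, p: float) -> sp.coo_matrix:
    """Hessian of the total potential restricted to free dofs (COO)."""
    d, ell = _element_lengths(net, x)
    u = d / ell[:, None]
    K = net.K
    c_uu = K  # coefficient of u u^T
    c_perp = K * (1.0 - net.L / ell)  # coefficient of (I - u u^T)
    I2 = np.eye(2)
    uu = u[:, :, None] * u[:, None, :]
    Hb = c_uu[:, None, None] * uu + c_perp[:, None, None] * (I2[None] - uu)  # (n_el,2,2)

    n_nodes = net.n_nodes
    free_index = -np.ones(n_nodes, dtype=int)
    free_index[net.free_nodes] = np.arange(net.n_free)

    rows, cols, vals = [], [], []

    def add_block(na, nb, B):
        """Accumulate 2x2 blocks B[k] at (node na[k], node nb[k]) for free pairs."""
        fa, fb = free_index[na], free_index[nb]
        m = (fa >= 0) & (fb >= 0)
        if not np.any(m):
            return
        fa, fb, Bm = fa[m], fb[m], B[m]
        for a in range(2):
            for b in range(2):
                rows.append(2 * fa + a)
                cols.append(2 * fb + b)
                vals.append(Bm[:, a, b])

    na, nb = net.conn[:, 0], net.conn[:, 1]
    add_block(na, na, Hb)
    add_block(nb, nb, Hb)
    add_block(na, nb, -Hb)
    add_block(nb, na, -Hb)

    # pressure Hessian: -p*D * d2A; A couples (x_k, y_{k+1}) pairs
    post = net.posterior_nodes
    nxt = np.roll(post, -1)
    half = 0.5 * p * net.D
    # d2A/dx_k dy_{k+1} = 1/2 ; d2A/dy_k dx_{k+1} = -1/2  (and symmetric)
    Bxy = np.zeros((post.size, 2, 2))
    Bxy[:, 0, 1] = -half  # -p*D * (+1/2) at (x_k, y_{k+1})
    Bxy[:, 1, 0] = half   # -p*D * (-1/2) at (y_k, x_{k+1})
    add_block(post, nxt, Bxy)
    add_block(nxt, post, np.transpose(Bxy, (0, 2, 1)))

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = 2 * net.n_free
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n))


@dataclass(frozen=True)
class SolverOptions:
    """Newton/continuation options for the discrete solve."""

    tol: float = 1e-10
    max_iter: int = 50
    n_pressure_steps: int = 10
    max_backtracks: int = 40


def _newton(net, x, p, opts: SolverOptions):
    """Newton iteration at fixed pressure; returns updated positions."""
    free = net.free_nodes
    for it in range(opts.max_iter):
        g = _gradient(net, x, p)
        r = -g[free].ravel()
        rnorm = float(np.abs(r).max()) if r.size else 0.0
        if rnorm <= opts.tol:
            return x, rnorm
        H = _hessian_free(net, x, p).tocsc()
        try:
            delta = spla.spsolve(H, r)
        except Exception:
            delta = None
        if delta is None or not np.all(np.isfinite(delta)) or float(delta @ r) <= 0:
            # regularized fallback: ensure a descent direction
            tau = 1e-6 * max(1.0, abs(H.diagonal()).max())
            for _ in range(20):
                try:
                    delta = spla.spsolve(H + tau * sp.identity(H.shape[0], format="csc"), r)
                except Exception:
                    delta = None
                if delta is not None and np.all(np.isfinite(delta)) and float(delta @ r) > 0:
                    break
                tau *= 10.0
            else:
                raise ConvergenceError(
                    "could not produce a descent direction", residual_norm=rnorm, step=it
                )
        # backtracking line search on the total potential
        e0 = total_potential(net, x, p)
        t = 1.0
        for _ in range(opts.max_backtracks):
            x_try = x.copy()
            x_try[free] += t * delta.reshape(-1, 2)
            try:
                e1 = total_potential(net, x_try, p)
            except DegenerateElementError:
                e1 = np.inf
            if e1 < e0 + 1e-12 * abs(e0):
                break
            t *= 0.5
        else:
            raise ConvergenceError(
                "line search stalled", residual_norm=rnorm, step=it
            )
        x = x_try
    g = _gradient(net, x, p)
    rnorm = float(np.abs(g[free]).max())
    if rnorm > opts.tol:
        raise ConvergenceError(
            f"Newton did not converge (residual {rnorm:.3e})", residual_norm=rnorm
        )
    return x, rnorm


def solve_discrete(
    net: DiscreteNetwork,
    options: Optional[SolverOptions] = None,
    initial: Optional[np.ndarray] = None,
) -> DiscreteSolution:
    """Solve the lattice equilibrium with pressure continuation.

    Starts from the stress-free reference configuration (or ``initial``) and
    ramps the pressure to its target in equal increments, carrying the
    converged state forward; Newton with analytic sparse Jacobian and
    backtracking line search at each increment.  Deterministic.
    """
    opts = options or SolverOptions()
    x = net.X.copy() if initial is None else initial.copy()
    p_target = net.p
    if p_target == 0.0:
        x, rnorm = _newton(net, x, 0.0, opts)
    else:
        for k in range(1, opts.n_pressure_steps + 1):
            p_k = p_target * k / opts.n_pressure_steps
            x, rnorm = _newton(net, x, p_k, opts)

    d, ell = _element_lengths(net, x)
    lam = ell / net.L
    forces = net.K * (ell - net.L)
    return DiscreteSolution(
        network=net,
        state=DiscreteState(x=x),
        stretches=lam,
        forces=forces,
        residual_norm=rnorm,
        pressure_kPa=net.material.p,
    )


def lamellar_stress(sol: DiscreteSolution) -> np.ndarray:
    """Azimuthal normal stress carried by each lamellar segment, in kPa.

    The axial force ``K1 (l - L1)`` in a segment is divided by its reference
    cross-sectional area ``L2 * D`` (radial spacing times slice depth).
    """
    net = sol.network
    mask = net.family == LAMELLAR
    geom = net.geom
    L2_mm = geom.T / net.disc.N
    # dimensional force (N) = dimensionless force * K1 * T
    f_N = sol.forces[mask] * net.material.K1 * geom.T
    stress_N_mm2 = f_N / (L2_mm * geom.D)
    return stress_N_mm2 / KPA_TO_N_PER_MM2  # -> kPa
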