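"""Headline shape and stress observables of a solved cornea.

Works with solutions from either scale (discrete lattice or continuum),
which expose the same small surface/apex interface:

* ``surface_mm(which)``        deformed surface polyline (x, y) in mm,
* ``reference_surface_mm``     undeformed counterpart,
* ``apex_points_mm()``         deformed (anterior, posterior) apex points,
* ``R_A_mm``, ``R_P_mm``, ``T_mm`` reference geometry.

Curvature of an interface uses the graph parametrization ``x = F(y)`` and the
formula ``K = F'' / (1 + F'^2)^(3/2)`` with 3-point centered finite
differences on the (generally non-uniform) y grid; the sign is chosen so the
unloaded cornea has positive curvature.  Maxima exclude the outer 10% of
points at both ends, where the pinned limbus dominates the shape.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import CorneaSimError

__all__ = [
    "MetricsReport",
    "apex_displacement",
    "central_thickness",
    "surface_curvature",
    "max_curvature",
    "metrics_report",
]


@dataclass(frozen=True)
class MetricsReport:
    """Apex displacement, central thickness and maximum interface curvature.

    ``AD`` is the radial displacement of the anterior apex (posterior value
    kept as auxiliary); ``CCT`` the distance between the deformed apex points;
    ``MAC``/``MPC`` the maximum anterior/posterior curvature over the central
    80% of each interface.
    """

    AD_mm: float
    CCT_mm: float
    MAC_per_mm: float
    MPC_per_mm: float
    AD_posterior_mm: float
    config_hash: Optional[str] = None
    grid: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        return cls(**json.loads(text))


def apex_displacement(solution, surface: str = "anterior") -> float:
    """Radial displacement (mm) of the apex point of the given surface."""
    ant, post = solution.apex_points_mm()
    if surface == "anterior":
        return float(np.linalg.norm(ant) - solution.R_A_mm)
    if surface == "posterior":
        return float(np.linalg.norm(post) - solution.R_P_mm)
    raise ValueError(f"unknown surface {surface!r}")


def central_thickness(solution) -> float:
    """Distance (mm) between the deformed anterior and posterior apex points."""
    ant, post = solution.apex_points_mm()
    return float(np.linalg.norm(ant - post))


def surface_curvature(curve: np.ndarray) -> np.ndarray:
    """Pointwise curvature (1/length) of a planar curve given as ordered
    ``(x, y)`` samples, single-valued as ``x = F(y)``.

    Centered 3-point finite differences on the non-uniform y grid; one-sided
    second-order stencils at the two ends.  Positive for the unloaded cornea
    (arc bulging toward +x).
    """
    curve = np.asarray(curve, dtype=float)
    x, y = curve[:, 0], curve[:, 1]
    if curve.shape[0] < 3:
        raise CorneaSimError("need at least 3 points for curvature")
    dy = np.diff(y)
    if not (np.all(dy > 0) or np.all(dy < 0)):
        raise CorneaSimError("curve is not single-valued as x = F(y) (fold-over)")
    n = y.size
    F1 = np.empty(n)
    F2 = np.empty(n)
    h1 = y[1:-1] - y[:-2]
    h2 = y[2:] - y[1:-1]
    F1[1:-1] = (
        -h2 / (h1 * (h1 + h2)) * x[:-2]
        + (h2 - h1) / (h1 * h2) * x[1:-1]
        + h1 / (h2 * (h1 + h2)) * x[2:]
    )
    F2[1:-1] = 2.0 * (
        x[:-2] / (h1 * (h1 + h2)) - x[1:-1] / (h1 * h2) + x[2:] / (h2 * (h1 + h2))
    )
    # second-order one-sided stencils at the ends
    for idx, sl in ((0, (0, 1, 2)), (n - 1, (n - 1, n - 2, n - 3))):
        y0, y1, y2 = y[list(sl)]
        a1, a2 = y1 - y0, y2 - y0
        # derivative weights from the 3-point Lagrange polynomial at y0
        F1[idx] = (
            x[sl[0]] * (-(a1 + a2)) / (a1 * a2)
            + x[sl[1]] * a2 / (a1 * (a2 - a1))
            + x[sl[2]] * (-a1) / (a2 * (a2 - a1))
        )
        F2[idx] = 2.0 * (
            x[sl[0]] / (a1 * a2)
            - x[sl[1]] / (a1 * (a2 - a1))
            + x[sl[2]] / (a2 * (a2 - a1))
        )
    return -F2 / (1.0 + F1**2) ** 1.5


def max_curvature(profile: np.ndarray, exclusion_fraction: float = 0.10) -> float:
    """Maximum of a curvature profile over the central points, excluding the
    outer ``exclusion_fraction`` of points at both ends (limbus boundary
    effects)."""
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    cut = int(np.floor(exclusion_fraction * n))
    if n - 2 * cut < 1:
        raise CorneaSimError("profile too short for the requested exclusion")
    return float(profile[cut : n - cut].max())


def _sorted_by_y(curve: np.ndarray) -> np.ndarray:
    return curve if curve[0, 1] < curve[-1, 1] else curve[::-1]


def metrics_report(solution, config_hash: Optional[str] = None) -> MetricsReport:
    """All headline metrics of a converged solution (either scale)."""
    ant = _sorted_by_y(solution.surface_mm("anterior"))
    post = _sorted_by_y(solution.surface_mm("posterior"))
    mac = max_curvature(surface_curvature(ant))
    mpc = max_curvature(surface_curvature(post))
    grid = None
    if hasattr(solution, "n_R"):
        grid = f"continuum {solution.n_R}x{solution.n_Phi}"
    elif hasattr(solution, "network"):
        d = solution.network.disc
        grid = f"discrete N={d.N} M={d.M}"
    return MetricsReport(
        AD_mm=apex_displacement(solution, "anterior"),
        CCT_mm=central_thickness(solution),
        MAC_per_mm=mac,
        MPC_per_mm=mpc,
        AD_posterior_mm=apex_displacement(solution, "posterior"),
        config_hash=config_hash,
        grid=grid,
    )
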