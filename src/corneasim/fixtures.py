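"""Deterministic small objects for oracle tests.

``make_fixture`` builds the tiny problems used by finite-difference,
symmetry and counting tests: a minimal lattice, a single unit cell, and a
manufactured deformation field with closed-form kinematics.
"""

from __future__ import annotations

import math

import numpy as np

from .continuum import DeformationField
from .discrete import MaterialSpec, build_network
from .geometry import CorneaGeometry, Discretization, build_nodes, rest_lengths

__all__ = ["make_fixture"]


def make_fixture(kind: str, **kwargs):
    """Build a named test fixture.

    Kinds
    -----
    ``tiny_lattice``
        Smallest useful network: N=2 layers, M=4 segments (15 nodes,
        12 lamellar + 10 radial + 16 diagonal elements), baseline material.
    ``unit_cell``
        Reference coordinates of one lattice cell (an isosceles trapezoid
        for finite N) together with its edge rest lengths.
    ``manufactured_field``
        Shear-like deformation ``r = R, phi = Phi + a R`` with closed-form
        gradient; the azimuthal stretch is 1 and the radial stretch is
        ``sqrt(1 + a^2 R^2)``.
    """
    if kind == "tiny_lattice":
        geom = kwargs.get("geom", CorneaGeometry())
        mat = kwargs.get("material", MaterialSpec())
        disc = Discretization(N=2, gamma=2.0)  # M = 4
        return build_network(geom, disc, mat, damage=kwargs.get("damage"))

    if kind == "unit_cell":
        geom = kwargs.get("geom", CorneaGeometry())
        disc = kwargs.get("disc", Discretization(N=4, gamma=20.0))
        grid = build_nodes(geom, disc)
        lengths = rest_lengths(geom, disc)
        i, j = kwargs.get("i", 0), kwargs.get("j", 0)
        corners = np.array(
            [
                [grid.X[i, j], grid.Y[i, j]],
                [grid.X[i, j + 1], grid.Y[i, j + 1]],
                [grid.X[i + 1, j + 1], grid.Y[i + 1, j + 1]],
                [grid.X[i + 1, j], grid.Y[i + 1, j]],
            ]
        )
        return {
            "corners": corners,
            "L1_bottom": lengths.L1[i],
            "L1_top": lengths.L1[i + 1],
            "L2": lengths.L2,
            "L3": lengths.L3[i],
        }

    if kind == "manufactured_field":
        a = kwargs.get("a", 0.05)
        return DeformationField(
            r_fn=lambda R, Phi: R,
            phi_fn=lambda R, Phi: Phi + a * R,
            grad_fn=lambda R, Phi: (1.0, 0.0, a, 1.0),
        )

    raise ValueError(f"unknown fixture kind {kind!r}")
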