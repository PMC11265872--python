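"""Result serialization: CSV tables and legacy ASCII VTK exports.

Every file carries the config hash in a header comment so that outputs are
traceable to the exact parameter set that produced them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .discrete import DiscreteSolution, LAMELLAR, RADIAL, DIAGONAL
from .continuum import ContinuumSolution
from .metrics import MetricsReport

__all__ = [
    "write_outputs",
    "write_nodes_csv",
    "write_elements_csv",
    "write_field_csv",
    "write_metrics_csv",
    "write_vtk_polylines",
    "write_vtk_structured_grid",
]

_FAMILY_NAMES = {LAMELLAR: "lamellar", RADIAL: "radial", DIAGONAL: "diagonal"}


def _write_with_header(df: pd.DataFrame, path, config_hash: Optional[str]):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def write_outputs(solution, report, out_dir, config_hash=None, vtk=False):
    """Write the standard output set for a converged solution into ``out_dir``.

    Discrete solutions get nodes/elements CSVs (and optionally a VTK
    polyline file); continuum solutions get a field CSV (and optionally a
    VTK structured grid).  Both get a one-row metrics CSV.  Returns the list
    of written paths.
    """
    out = Path(out_dir)
    paths = []
    if isinstance(solution, DiscreteSolution):
        paths.append(write_nodes_csv(solution, out / "nodes.csv", config_hash))
        paths.append(write_elements_csv(solution, out / "elements.csv", config_hash))
        if vtk:
            paths.append(write_vtk_polylines(solution, out / "lattice.vtk"))
    elif isinstance(solution, ContinuumSolution):
        paths.append(write_field_csv(solution, out / "field.csv", config_hash))
        if vtk:
            paths.append(write_vtk_structured_grid(solution, out / "field.vtk"))
    else:
        raise TypeError(f"unsupported solution type {type(solution).__name__}")
    paths.append(write_metrics_csv([report], out / "metrics.csv", config_hash))
    return paths


def write_nodes_csv(sol: DiscreteSolution, path, config_hash=None):
    """Reference and deformed nodal positions (mm), indexed by (i, j)."""
    net = sol.network
    N, M = net.disc.N, net.disc.M
    T = net.geom.T
    ii, jj = np.meshgrid(np.arange(N + 1), np.arange(M + 1), indexing="ij")
    X = net.X.reshape(N + 1, M + 1, 2) * T
    x = sol.state.x.reshape(N + 1, M + 1, 2) * T
    df = pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "X_mm": X[..., 0].ravel(),
            "Y_mm": X[..., 1].ravel(),
            "x_mm": x[..., 0].ravel(),
            "y_mm": x[..., 1].ravel(),
        }
    )
    return _write_with_header(df, path, config_hash)


def write_elements_csv(sol: DiscreteSolution, path, config_hash=None):
    """Per-element family, connectivity, rest length, stretch and force."""
    net = sol.network
    T, K1 = net.geom.T, net.material.K1
    M = net.disc.M
    n1, n2 = net.conn[:, 0], net.conn[:, 1]
    df = pd.DataFrame(
        {
            "family": [_FAMILY_NAMES[f] for f in net.family],
            "i1": n1 // (M + 1),
            "j1": n1 % (M + 1),
            "i2": n2 // (M + 1),
            "j2": n2 % (M + 1),
            "rest_length_mm": net.L * T,
            "stretch": sol.stretches,
            "force_N": sol.forces * K1 * T,
        }
    )
    return _write_with_header(df, path, config_hash)


def write_field_csv(sol: ContinuumSolution, path, config_hash=None):
    """Continuum grid values: reference (R, Phi), deformed (x, y) and stress."""
    T = sol.T_mm
    Rg, Pg = np.meshgrid(sol.R, sol.Phi, indexing="ij")
    x = sol.r * np.cos(sol.phi) * T
    y = sol.r * np.sin(sol.phi) * T
    stress = sol.stress_at_nodes()
    df = pd.DataFrame(
        {
            "R_mm": (Rg * T).ravel(),
            "Phi_rad": Pg.ravel(),
            "x_mm": x.ravel(),
            "y_mm": y.ravel(),
            "T_RR_kPa": stress["T_RR_kPa"].ravel(),
            "T_RPhi_kPa": stress["T_RPhi_kPa"].ravel(),
            "T_PhiPhi_kPa": stress["T_PhiPhi_kPa"].ravel(),
        }
    )
    return _write_with_header(df, path, config_hash)


def write_metrics_csv(reports, path, config_hash=None, extra_columns=None):
    """One row per metrics report; ``extra_columns`` is an optional list of
    dicts aligned with ``reports`` (sweep parameters etc.)."""
    rows = []
    for k, rep in enumerate(reports):
        row = {} if extra_columns is None else dict(extra_columns[k])
        row.update(
            {
                "AD_mm": rep.AD_mm,
                "CCT_mm": rep.CCT_mm,
                "MAC_per_mm": rep.MAC_per_mm,
                "MPC_per_mm": rep.MPC_per_mm,
                "AD_posterior_mm": rep.AD_posterior_mm,
            }
        )
        rows.append(row)
    return _write_with_header(pd.DataFrame(rows), path, config_hash)


def write_vtk_polylines(sol: DiscreteSolution, path, deformed=True):
    """Legacy ASCII VTK polydata of the lattice elements (for visualization)."""
    net = sol.network
    T = net.geom.T
    pts = (sol.state.x if deformed else net.X) * T
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncorneasim lattice\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for x, y in pts:
            fh.write(f"{x:.10g} {y:.10g} 0\n")
        ne = len(net.conn)
        fh.write(f"LINES {ne} {3 * ne}\n")
        for a, b in net.conn:
            fh.write(f"2 {a} {b}\n")
        fh.write(f"CELL_DATA {ne}\nSCALARS force_N double 1\nLOOKUP_TABLE default\n")
        for f in sol.forces * net.material.K1 * T:
            fh.write(f"{f:.10g}\n")
    return path


def write_vtk_structured_grid(sol: ContinuumSolution, path, deformed=True):
    """Legacy ASCII VTK structured grid of the continuum solution."""
    T = sol.T_mm
    if deformed:
        x = sol.r * np.cos(sol.phi) * T
        y = sol.r * np.sin(sol.phi) * T
    else:
        Rg, Pg = np.meshgrid(sol.R, sol.Phi, indexing="ij")
        x = Rg * np.cos(Pg) * T
        y = Rg * np.sin(Pg) * T
    nR, nP = x.shape
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncorneasim field\nASCII\n")
        fh.write("DATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nR} {nP} 1\n")
        fh.write(f"POINTS {nR * nP} double\n")
        for jp in range(nP):
            for ir in range(nR):
                fh.write(f"{x[ir, jp]:.10g} {y[ir, jp]:.10g} 0\n")
    return path
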