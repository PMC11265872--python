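"""Orchestration of the standard numerical experiments.

Three studies drive the two solvers:

* :func:`convergence_study` — discrete solutions for increasing layer count N
  (fixed aspect ratio) against one continuum solution; the apex-displacement
  error decays as O(1/N).
* :func:`damage_sweep` — continuum solves over a grid of damage amplitude and
  localization exponent.
* :func:`sensitivity_sweep` — continuum solves of the heavily damaged cornea
  over 2D slices of (gamma, K2, K3) through the baseline.

Each cell is solved independently with its own pressure/damage continuation,
so a sweep is an embarrassingly deterministic function of the configuration
(identical configs give identical tables) and failed cells cannot poison
their neighbours.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CorneaConfig
from .continuum import ContinuumModel, ContinuumSolution
from .damage import DamageSpec
from .discrete import build_network, solve_discrete
from .errors import ConvergenceError
from .geometry import Discretization
from .metrics import apex_displacement, metrics_report

__all__ = ["convergence_study", "damage_sweep", "sensitivity_sweep"]


@dataclass
class ConvergenceTable:
    """Discrete-to-continuum convergence of the apex displacement."""

    table: pd.DataFrame  # columns: N, AD_discrete_mm, AD_continuum_mm, abs_error_mm, runtime_s
    fitted_order: float  # log-log slope of abs_error vs N (expected ~ -1)
    AD_continuum_mm: float


def convergence_study(
    N_list: Sequence[int],
    config: Optional[CorneaConfig] = None,
    continuum_solution: Optional[ContinuumSolution] = None,
) -> ConvergenceTable:
    """Run discrete solves for each N and compare with the continuum value.

    ``N_list`` must be ascending; the mesh aspect ratio gamma is fixed.  An
    already-computed healthy continuum solution can be supplied to avoid
    re-solving.
    """
    config = config or CorneaConfig()
    if list(N_list) != sorted(N_list):
        raise ValueError("N_list must be ascending")
    cfg = config.healthy()
    if continuum_solution is None:
        model = ContinuumModel(
            geom=cfg.geometry,
            material=cfg.material,
            gamma=cfg.discretization.gamma,
            n_R=cfg.continuum.n_R,
            n_Phi=cfg.continuum.n_Phi,
        )
        continuum_solution = model.solve(cfg.continuum.solver_options())
    AD_cont = apex_displacement(continuum_solution)

    rows = []
    for N in N_list:
        t0 = time.perf_counter()
        net = build_network(
            cfg.geometry,
            Discretization(N=N, gamma=cfg.discretization.gamma),
            cfg.material,
        )
        sol = solve_discrete(net, cfg.discrete_solver)
        AD_d = apex_displacement(sol)
        rows.append(
            {
                "N": N,
                "AD_discrete_mm": AD_d,
                "AD_continuum_mm": AD_cont,
                "abs_error_mm": abs(AD_d - AD_cont),
                "runtime_s": time.perf_counter() - t0,
            }
        )
    table = pd.DataFrame(rows)
    slope = float(
        np.polyfit(np.log(table["N"]), np.log(table["abs_error_mm"]), 1)[0]
    )
    return ConvergenceTable(table=table, fitted_order=slope, AD_continuum_mm=AD_cont)


def _solve_with_damage(cfg: CorneaConfig, damage: Optional[DamageSpec], initial=None):
    model = ContinuumModel(
        geom=cfg.geometry,
        material=cfg.material,
        gamma=cfg.discretization.gamma,
        n_R=cfg.continuum.n_R,
        n_Phi=cfg.continuum.n_Phi,
        damage=damage,
    )
    return model.solve(cfg.continuum.solver_options(), initial=initial)


def damage_sweep(
    Dmax_list: Sequence[float],
    xi_list: Sequence[int],
    config: Optional[CorneaConfig] = None,
) -> pd.DataFrame:
    """Continuum metrics over a (Dmax, xi) grid.

    Rows where the solve fails record ``converged = False`` and NaN metrics;
    the sweep continues.
    """
    config = config or CorneaConfig()
    rows = []
    for xi in xi_list:
        for Dmax in Dmax_list:
            dmg = (
                DamageSpec(Dmax=Dmax, xi=xi, Y_max=config.geometry.Y_max)
                if Dmax > 0
                else None
            )
            row = {"Dmax": Dmax, "xi": xi, "gamma": config.discretization.gamma,
                   "K2_N_per_mm": config.material.K2, "K3_N_per_mm": config.material.K3}
            try:
                sol = _solve_with_damage(config, dmg)
                rep = metrics_report(sol, config_hash=config.hash())
                row.update(converged=True, AD_mm=rep.AD_mm,
                           AD_posterior_mm=rep.AD_posterior_mm, CCT_mm=rep.CCT_mm,
                           MAC_per_mm=rep.MAC_per_mm, MPC_per_mm=rep.MPC_per_mm)
            except ConvergenceError:
                row.update(converged=False, AD_mm=np.nan, AD_posterior_mm=np.nan,
                           CCT_mm=np.nan, MAC_per_mm=np.nan, MPC_per_mm=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_sweep(
    gamma_list: Sequence[float],
    K2_list: Sequence[float],
    K3_list: Sequence[float],
    config: Optional[CorneaConfig] = None,
) -> pd.DataFrame:
    """Metrics of the heavily damaged cornea over the three 2D parameter
    slices through the baseline: (gamma, K2), (gamma, K3) and (K2, K3)."""
    config = config or CorneaConfig()
    base = config
    rows = []

    def one(gamma, K2, K3):
        cfg = dataclasses.replace(
            base,
            discretization=dataclasses.replace(base.discretization, gamma=gamma),
            material=dataclasses.replace(base.material, K2=K2, K3=K3),
        )
        dmg = base.damage
        row = {"gamma": gamma, "K2_N_per_mm": K2, "K3_N_per_mm": K3,
               "Dmax": dmg.Dmax, "xi": dmg.xi}
        try:
            sol = _solve_with_damage(cfg, dmg)
            rep = metrics_report(sol, config_hash=cfg.hash())
            row.update(converged=True, AD_mm=rep.AD_mm,
                       AD_posterior_mm=rep.AD_posterior_mm, CCT_mm=rep.CCT_mm,
                       MAC_per_mm=rep.MAC_per_mm, MPC_per_mm=rep.MPC_per_mm)
        except ConvergenceError:
            row.update(converged=False, AD_mm=np.nan, AD_posterior_mm=np.nan,
                       CCT_mm=np.nan, MAC_per_mm=np.nan, MPC_per_mm=np.nan)
        rows.append(row)

    g0, K20, K30 = base.discretization.gamma, base.material.K2, base.material.K3
    seen = set()
    for gamma in gamma_list:
        for K2 in K2_list:
            key = (gamma, K2, K30)
            if key not in seen:
                seen.add(key)
                one(*key)
    for gamma in gamma_list:
        for K3 in K3_list:
            key = (gamma, K20, K3)
            if key not in seen:
                seen.add(key)
                one(*key)
    for K2 in K2_list:
        for K3 in K3_list:
            key = (g0, K2, K3)
            if key not in seen:
                seen.add(key)
                one(*key)
    return pd.DataFrame(rows)
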