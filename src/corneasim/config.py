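"""Configuration: a single validated parameter record drives both scales.

Defaults are the baseline values of the corneal model: geometry
(T = 0.62 mm, R_A = 7.8 mm, D_A = 11.46 mm, depth 1 mm), discretization
(N = 32 layers, aspect ratio gamma = 20), stiffness (K1 = 7.2, K2 = 0.0072,
K3 = 0.504 N/mm), physiological IOP p = 2 kPa, and the damage profile
(Dmax = 0.99, xi = 4).  The continuum grid defaults to 64 radial x 1280
azimuthal elements (gamma-consistent aspect).

Configs load from YAML or JSON; unknown keys are rejected with their path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .continuum import ContinuumSolverOptions
from .damage import DamageSpec
from .discrete import MaterialSpec, SolverOptions
from .errors import ConfigError
from .geometry import CorneaGeometry, Discretization

__all__ = ["CorneaConfig", "ContinuumGridSpec", "load_config", "default_config"]


@dataclass(frozen=True)
class ContinuumGridSpec:
    """Continuum grid sizes and solver tolerances."""

    n_R: int = 64
    n_Phi: Optional[int] = None  # None -> gamma * n_R
    tol: float = 1e-10
    max_iter: int = 50
    n_pressure_steps: int = 10
    n_damage_steps: Optional[int] = None

    def solver_options(self) -> ContinuumSolverOptions:
        return ContinuumSolverOptions(
            tol=self.tol,
            max_iter=self.max_iter,
            n_pressure_steps=self.n_pressure_steps,
            n_damage_steps=self.n_damage_steps,
        )


@dataclass(frozen=True)
class CorneaConfig:
    """Full parameter record for the corneal slice model."""

    geometry: CorneaGeometry = field(default_factory=CorneaGeometry)
    discretization: Discretization = field(default_factory=Discretization)
    material: MaterialSpec = field(default_factory=MaterialSpec)
    damage: DamageSpec = None
    continuum: ContinuumGridSpec = field(default_factory=ContinuumGridSpec)
    discrete_solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        if self.damage is None:
            object.__setattr__(
                self,
                "damage",
                DamageSpec(Dmax=0.99, xi=4, Y_max=self.geometry.Y_max),
            )

    def dimensionless_summary(self) -> dict:
        """The dimensionless groups governing the model."""
        g, m = self.geometry, self.material
        return {
            "gamma": self.discretization.gamma,
            "Phi_star_rad": g.Phi_star,
            "R_A_over_T": g.R_A / g.T,
            "D_over_T": g.D / g.T,
            "K2_over_K1": m.K2_ratio(),
            "K3_over_K1": m.K3_ratio(),
            "p_T_over_K1": m.p_dimensionless(g.T),
        }

    def to_dict(self) -> dict:
        g, m, d = self.geometry, self.material, self.damage
        return {
            "geometry": {
                "R_A_mm": g.R_A,
                "T_mm": g.T,
                "D_A_mm": g.D_A,
                "depth_mm": g.D,
                "N": self.discretization.N,
                "gamma": self.discretization.gamma,
            },
            "material": {
                "K1_N_per_mm": m.K1,
                "K2_N_per_mm": m.K2,
                "K3_N_per_mm": m.K3,
                "p_kPa": m.p,
            },
            "damage": {"Dmax": d.Dmax, "xi": d.xi},
            "continuum": {
                "n_R": self.continuum.n_R,
                "n_Phi": self.continuum.n_Phi,
                "tol": self.continuum.tol,
                "max_iter": self.continuum.max_iter,
                "n_pressure_steps": self.continuum.n_pressure_steps,
                "n_damage_steps": self.continuum.n_damage_steps,
            },
            "discrete_solver": {
                "tol": self.discrete_solver.tol,
                "max_iter": self.discrete_solver.max_iter,
                "n_pressure_steps": self.discrete_solver.n_pressure_steps,
            },
        }

    def hash(self) -> str:
        """Short stable hash of the full configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # -- convenience variants ------------------------------------------------
    def healthy(self) -> "CorneaConfig":
        """Same config with zero damage."""
        return dataclasses.replace(
            self, damage=DamageSpec(Dmax=0.0, xi=self.damage.xi, Y_max=self.geometry.Y_max)
        )

    def with_damage(self, Dmax: float, xi: int) -> "CorneaConfig":
        return dataclasses.replace(
            self, damage=DamageSpec(Dmax=Dmax, xi=xi, Y_max=self.geometry.Y_max)
        )


def default_config() -> CorneaConfig:
    return CorneaConfig()


_ALLOWED = {
    "geometry": {"R_A_mm", "T_mm", "D_A_mm", "depth_mm", "N", "gamma"},
    "material": {"K1_N_per_mm", "K2_N_per_mm", "K3_N_per_mm", "p_kPa"},
    "damage": {"Dmax", "xi"},
    "continuum": {
        "n_R",
        "n_Phi",
        "tol",
        "max_iter",
        "n_pressure_steps",
        "n_damage_steps",
    },
    "discrete_solver": {"tol", "max_iter", "n_pressure_steps"},
}


def _check_keys(data: dict):
    for section, content in data.items():
        if section not in _ALLOWED:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in content:
            if key not in _ALLOWED[section]:
                raise ConfigError(f"unknown key {section}.{key}")


def load_config(path_or_dict) -> CorneaConfig:
    """Load and validate a configuration from YAML/JSON file or a dict.

    Missing keys fall back to the baseline defaults; an empty file yields the
    full default configuration.
    """
    if isinstance(path_or_dict, (str, Path)):
        text = Path(path_or_dict).read_text()
        data = yaml.safe_load(text) or {}
    else:
        data = dict(path_or_dict or {})
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(data)

    geo = data.get("geometry", {})
    mat = data.get("material", {})
    dam = data.get("damage", {})
    cont = data.get("continuum", {})
    dsol = data.get("discrete_solver", {})

    try:
        geometry = CorneaGeometry(
            R_A=float(geo.get("R_A_mm", 7.8)),
            T=float(geo.get("T_mm", 0.62)),
            D_A=float(geo.get("D_A_mm", 11.46)),
            D=float(geo.get("depth_mm", 1.0)),
        )
        discretization = Discretization(
            N=int(geo.get("N", 32)), gamma=float(geo.get("gamma", 20.0))
        )
        material = MaterialSpec(
            K1=float(mat.get("K1_N_per_mm", 7.2)),
            K2=float(mat.get("K2_N_per_mm", 0.0072)),
            K3=float(mat.get("K3_N_per_mm", 0.504)),
            p=float(mat.get("p_kPa", 2.0)),
        )
        damage = DamageSpec(
            Dmax=float(dam.get("Dmax", 0.99)),
            xi=int(dam.get("xi", 4)),
            Y_max=geometry.Y_max,
        )
        continuum = ContinuumGridSpec(
            n_R=int(cont.get("n_R", 64)),
            n_Phi=cont.get("n_Phi"),
            tol=float(cont.get("tol", 1e-10)),
            max_iter=int(cont.get("max_iter", 50)),
            n_pressure_steps=int(cont.get("n_pressure_steps", 10)),
            n_damage_steps=cont.get("n_damage_steps"),
        )
        solver = SolverOptions(
            tol=float(dsol.get("tol", 1e-10)),
            max_iter=int(dsol.get("max_iter", 50)),
            n_pressure_steps=int(dsol.get("n_pressure_steps", 10)),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    return CorneaConfig(
        geometry=geometry,
        discretization=discretization,
        material=material,
        damage=damage,
        continuum=continuum,
        discrete_solver=solver,
    )
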