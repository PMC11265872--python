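"""Shared fixtures.

The expensive continuum solves (baseline 64x1280 healthy and damaged) are
session-scoped so that several acceptance tests reuse a single solve.
"""

import numpy as np
import pytest

from corneasim.config import CorneaConfig
from corneasim.continuum import ContinuumModel
from corneasim.damage import DamageSpec
from corneasim.discrete import MaterialSpec
from corneasim.geometry import CorneaGeometry, Discretization


@pytest.fixture(scope="session")
def baseline_geom():
    return CorneaGeometry()


@pytest.fixture(scope="session")
def baseline_material():
    return MaterialSpec()


@pytest.fixture(scope="session")
def baseline_config():
    return CorneaConfig()


@pytest.fixture(scope="session")
def healthy_continuum_baseline(baseline_geom, baseline_material):
    """Healthy continuum solution on the baseline 64x1280 grid."""
    model = ContinuumModel(baseline_geom, baseline_material, gamma=20.0, n_R=64)
    return model.solve()


@pytest.fixture(scope="session")
def damaged_continuum_baseline(baseline_geom, baseline_material):
    """Heavily damaged continuum solution (Dmax=0.99, xi=4) on the baseline grid."""
    dmg = DamageSpec(Dmax=0.99, xi=4, Y_max=baseline_geom.Y_max)
    model = ContinuumModel(baseline_geom, baseline_material, gamma=20.0, n_R=64, damage=dmg)
    return model.solve()


@pytest.fixture(scope="session")
def coarse_continuum(baseline_geom, baseline_material):
    """Factory for fast coarse-grid continuum solves used by property tests."""

    def run(n_R=8, damage=None, **kwargs):
        model = ContinuumModel(
            baseline_geom, baseline_material, gamma=20.0, n_R=n_R, damage=damage, **kwargs
        )
        return model.solve()

    return run
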