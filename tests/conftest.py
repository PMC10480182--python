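"""Shared fixtures.

The expensive objects (the converged ground truth and the full study
tables at the default desk-scale configuration) are session-scoped:
they are computed once and shared by the integration and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from stenoflow import (
    FluidProperties,
    SolverSettings,
    StudyConfig,
    build_geometry,
    generate_mesh,
)

BLOOD = FluidProperties(density=1060.0, dynamic_viscosity=0.0035)


@pytest.fixture(scope="session")
def blood():
    return BLOOD


@pytest.fixture(scope="session")
def reference_geometry():
    """50% diameter stenosis, D = 2 cm, 6D inlet run, 2D stenosis."""
    return build_geometry(0.02, 0.5)


@pytest.fixture()
def straight_duct_mesh():
    """Uniform square-celled straight duct (planar), for assembly oracles."""
    geom = build_geometry(0.02, 0.0, inlet_run=2, stenosis_length=2, outlet_run=4)
    # 8 cells per D axially, 8 across: square 2.5 mm cells
    return generate_mesh(geom, 64, 8, 1.0, "planar")


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def study(study_config):
    """The complete default study (ground truth + all three stages)."""
    from stenoflow import run_all

    return run_all(study_config)


@pytest.fixture(scope="session")
def ground_truth(study):
    return study["ground_truth"]


def laminar_settings(**kw):
    return SolverSettings(turbulence_enabled=False, **kw)


def make_uniform_inlet(mesh, u0, k0=0.0, eps0=1e-12, v0=0.0, mixing_length=1.0):
    from stenoflow import InletSpec

    nj = mesh.nj
    return InletSpec(
        "uniform_TI",
        np.full(nj, float(u0)),
        np.full(nj, float(v0)),
        np.full(nj, float(k0)),
        np.full(nj, float(eps0)),
        mixing_length,
    )
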