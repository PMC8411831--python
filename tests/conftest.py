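"""Shared fixtures: coarse solver plans and cached expensive pipelines."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from plasmonsense.dda import SolverSettings
from plasmonsense.geometry import (MoleculeSpec, NanorodGeometry,
                                   build_scene)
from plasmonsense.materials import DielectricTable, MaterialSet
from plasmonsense.sweep import SpectrumPlan


@pytest.fixture(autouse=True)
def _quiet_discretization_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore",
                                message=".*voxel_size above d/16.*")
        warnings.filterwarnings("ignore", message=".*\\|m\\| k d.*")
        yield


@pytest.fixture(scope="session")
def homogeneous_settings():
    """Solver settings for scenes in a uniform water host."""
    return SolverSettings(tolerance=1e-5, substrate_model="none")


@pytest.fixture(scope="session")
def coarse_plan():
    """Desk-scale spectrum plan: d/8 voxels, point-dipole molecule."""
    return SpectrumPlan(
        voxel_fraction=1.0 / 8.0,
        molecule_representation="point_dipole",
        n_wide=0,
        n_fine=5,
        fix_baseline=True,
        coarse_tolerance=1e-3,
        settings=SolverSettings(tolerance=3e-4, substrate_model="none",
                                single_precision=True),
    )


@pytest.fixture(scope="session")
def lossy_dielectric_materials():
    """A weakly lossy constant-index 'metal' table for benign DDA checks."""
    eps = 2.56 + 0.06j
    nk = np.sqrt(eps)
    table = DielectricTable(np.array([300.0, 1600.0]),
                            np.full(2, nk.real), np.full(2, nk.imag))
    return eps, MaterialSet(gold=table)


@pytest.fixture(scope="session")
def reference_scene():
    """The 20 x 80 nm reference rod with the streptavidin sphere."""
    return build_scene(NanorodGeometry(20.0, 4.0), molecule=MoleculeSpec(),
                       substrate_enabled=False)
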