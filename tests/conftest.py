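"""Shared fixtures: synthetic structures and precomputed SASD pipelines.

Everything is generated in-process from seeds; the expensive grid/search
steps are session-scoped so several test modules can share them.
"""

import numpy as np
import pytest

from xlwalk.evaluation import calpha_rmsd, compute_model_distances
from xlwalk.fixtures import FixtureSpec, make_fixture
from xlwalk.sasd_search import compute_sasd
from xlwalk.voxel_grid import build_grid, find_accessible_residues

PAIR = (("A", 1), ("A", 2))


@pytest.fixture(scope="session")
def free_pair_ca():
    """Two Cα-only lysines 10 Å apart with nothing between them."""
    fx = make_fixture(FixtureSpec("free_pair", separation=10.0,
                                  side_chains=False))
    grid = build_grid(fx.structure)
    access = find_accessible_residues(grid, fx.structure)
    result = compute_sasd(grid, access, fx.structure)
    return fx, grid, access, result


@pytest.fixture(scope="session")
def wall_case():
    """Cα-only lysines 20 Å apart with a finite carbon slab between them."""
    fx = make_fixture(FixtureSpec("wall", separation=20.0, wall_halfwidth=12.0))
    grid = build_grid(fx.structure)
    access = find_accessible_residues(grid, fx.structure)
    result = compute_sasd(grid, access, fx.structure)
    return fx, grid, access, result


@pytest.fixture(scope="session")
def wall_free_case():
    """The wall fixture's lysines with the slab removed."""
    from xlwalk.structures_io import StructureModel
    fx = make_fixture(FixtureSpec("wall", separation=20.0, wall_halfwidth=12.0))
    atoms = [a for a in fx.structure.atoms if a.residue_name != "OBS"]
    structure = StructureModel(atoms)
    grid = build_grid(structure)
    access = find_accessible_residues(grid, structure)
    result = compute_sasd(grid, access, structure)
    return structure, grid, access, result


@pytest.fixture(scope="session")
def buried_case():
    fx = make_fixture(FixtureSpec("buried", separation=10.0))
    grid = build_grid(fx.structure)
    access = find_accessible_residues(grid, fx.structure)
    result = compute_sasd(grid, access, fx.structure)
    return fx, grid, access, result


@pytest.fixture(scope="session")
def small_ensemble():
    """Ten perturbed models of the base assembly, with SASDs and RMSDs."""
    fx = make_fixture(FixtureSpec("perturbed_ensemble", n_models=10,
                                  max_sigma=12.0, seed=11))
    ref_dist = compute_model_distances(fx.structure)
    distances, rmsds = {}, {}
    for i, model in enumerate(fx.models):
        name = f"m{i:02d}"
        distances[name] = compute_model_distances(model)
        rmsds[name] = calpha_rmsd(model, fx.structure)
    return fx, ref_dist, distances, rmsds
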