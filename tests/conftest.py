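"""Shared fixtures: phantoms, meshes and assembled systems at several
sizes, session-scoped where construction is expensive."""

from __future__ import annotations

import numpy as np
import pytest

import skullvibe as sv
from skullvibe.phantom import VoxelPhantom


@pytest.fixture(scope="session")
def default_phantom() -> VoxelPhantom:
    return sv.generate_phantom(sv.PhantomConfig(), seed=1)


@pytest.fixture(scope="session")
def small_config() -> sv.PhantomConfig:
    """A reduced phantom (no mandible) cheap enough to mesh at 2x."""
    return sv.PhantomConfig(
        shape=(12, 12, 24),
        cranium_x=(1, 11), cranium_y=(8, 11), cranium_z=(2, 22),
        bulla_size=(2, 2, 3), bulla_y=(5, 7), bulla_z=(10, 13),
        left_bulla_x=(2, 4), right_bulla_x=(8, 10),
        pedicle_z=((10, 11), (12, 13)),
        mandible=False,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config) -> VoxelPhantom:
    return sv.generate_phantom(small_config, seed=1)


@pytest.fixture(scope="session")
def single_voxel() -> VoxelPhantom:
    return VoxelPhantom(np.ones((1, 1, 1), np.int8), [5.0, 5.0, 5.0], [0.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def tiny_block() -> VoxelPhantom:
    """2x2x2 all-bone block: 27 nodes, small enough for dense eigen."""
    return VoxelPhantom(np.ones((2, 2, 2), np.int8), [5.0, 5.0, 5.0], [0.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def tiny_system(tiny_block):
    mesh = sv.voxels_to_tetmesh(tiny_block)
    mats = sv.natural_preset()
    system = sv.assemble_system(mesh, mats, [])
    return mesh, mats, system


@pytest.fixture(scope="session")
def tiny_basis(tiny_system):
    _mesh, _mats, system = tiny_system
    # huge cutoff: retain the complete basis (reduction is then exact)
    return sv.compute_modal_basis(system, f_max=1e9, safety=1.5)


@pytest.fixture(scope="session")
def default_model():
    """Full default-phantom model chain with incident-wave loading
    (shared across the physics-trend tests; the modal basis dominates
    the cost and is cached inside the pipeline)."""
    cfg = sv.RunConfig(press=sv.PressConfig(mode="incident"))
    return cfg, sv.model_frfs(cfg)
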