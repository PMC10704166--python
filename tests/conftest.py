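"""Shared fixtures: small phantoms, slab volumes and terminal helpers."""

from __future__ import annotations

import pytest

from tdcs_currentflow.phantom import LabeledHeadVolume, PhantomSpec, generate_phantom
from tdcs_currentflow.testing import face_terminal_geometry, make_slab  # noqa: F401

__all__ = ["face_terminal_geometry", "make_slab"]


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarse phantom (4 mm voxels) for fast end-to-end tests."""
    return PhantomSpec(grid_shape=(48, 48, 48), voxel_size_mm=4.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec) -> LabeledHeadVolume:
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom() -> LabeledHeadVolume:
    """Production-resolution phantom (2 mm voxels, 96^3)."""
    return generate_phantom(PhantomSpec())
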