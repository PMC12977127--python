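"""Shared fixtures: small closed meshes and phantoms."""

import numpy as np
import pytest
import trimesh

from foliakit.mesh_core import build_adjacency
from foliakit.synthetic_data import PhantomSpec, make_folded_phantom
from foliakit.types import LabeledSurface


@pytest.fixture(scope="session")
def tetrahedron():
    """Regular tetrahedron with unit edge length, consistently oriented."""
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                 dtype=float) / np.sqrt(8)  # edge length 1
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return LabeledSurface(v, f, labels=np.ones(4, dtype=int))


@pytest.fixture(scope="session")
def unit_cube():
    mesh = trimesh.creation.box(extents=(1, 1, 1))
    return LabeledSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


@pytest.fixture(scope="session")
def icosphere_r10():
    """Sphere phantom, radius 10 mm, no folding (subdivision 4)."""
    return make_folded_phantom(PhantomSpec(
        base_radius=10.0, fold_amplitude=0.0, mesh_subdivisions=4,
        n_regions=2))


@pytest.fixture(scope="session")
def small_folded_phantom():
    """Folded 4-region phantom at subdivision 3 (642 vertices)."""
    return make_folded_phantom(PhantomSpec(mesh_subdivisions=3, n_regions=4))


@pytest.fixture(scope="session")
def medium_folded_phantom():
    """Folded 4-region phantom at subdivision 4 (2562 vertices)."""
    return make_folded_phantom(PhantomSpec(mesh_subdivisions=4, n_regions=4))


@pytest.fixture(scope="session")
def medium_adjacency(medium_folded_phantom):
    return build_adjacency(medium_folded_phantom)
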