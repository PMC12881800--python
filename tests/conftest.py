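"""Shared fixtures: one seeded phantom and its meshes, built once."""

from __future__ import annotations

import numpy as np
import pytest

import lungfem as lf


@pytest.fixture(scope="session")
def phantom7() -> lf.PhantomResult:
    """Default synthetic thorax, fixed seed."""
    return lf.generate_phantom(lf.PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def volume7(phantom7) -> lf.LabelVolume:
    return phantom7.volume


@pytest.fixture(scope="session")
def lobe_surfaces(phantom7) -> dict[int, lf.SurfaceMesh]:
    return {code: phantom7.surface(code) for code in range(1, 6)}


@pytest.fixture(scope="session")
def default_lobe_meshes(volume7) -> dict[int, lf.TetMesh]:
    """Per-lobe FEM meshes at the default whole-model element budget."""
    return lf.build_lobe_meshes(volume7)


@pytest.fixture(scope="session")
def small_cage(volume7) -> lf.TetMesh:
    """Parenchyma-only cage of the left lower lobe, ~300 elements."""
    return lf.build_tet_mesh(volume7, {2}, 300)


@pytest.fixture(scope="session")
def small_embedding(small_cage, phantom7) -> lf.EmbeddingMap:
    return lf.embed_surfaces(small_cage, phantom7.surface(2))


@pytest.fixture(scope="session")
def small_assembly(small_cage) -> lf.Assembly:
    return lf.assemble(small_cage, lf.default_materials())


@pytest.fixture(scope="session")
def mediastinum_point(lobe_surfaces) -> np.ndarray:
    return np.mean([s.centroid() for s in lobe_surfaces.values()], axis=0)


def regular_tet_nodes(edge: float = 1.0) -> np.ndarray:
    """Vertices of a regular tetrahedron with the given edge length."""
    nodes = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    return nodes * (edge / np.sqrt(8.0))


@pytest.fixture()
def unit_tet_mesh() -> lf.TetMesh:
    """Single regular tetrahedron, unit edge, parenchyma tissue."""
    nodes = regular_tet_nodes()
    tets = np.array([[0, 1, 2, 3]])
    a, b, c, d = nodes
    if np.dot(np.cross(b - a, c - a), d - a) < 0:
        tets = np.array([[0, 1, 3, 2]])
    return lf.TetMesh(nodes=nodes, tets=tets, tissue=np.array([1]), element_budget=1)


@pytest.fixture()
def cube_volume() -> lf.LabelVolume:
    """Fully occupied 8^3 unit-spacing grid (one 8 mm cube of tissue)."""
    voxels = np.ones((8, 8, 8), dtype=np.int16)
    return lf.LabelVolume(voxels=voxels, affine=np.eye(4), label_table={1: "LUL"})


@pytest.fixture(scope="session")
def bar_volume() -> lf.LabelVolume:
    """A 48x12x12 mm parenchyma bar for static bending checks."""
    voxels = np.zeros((26, 8, 8), dtype=np.int16)
    voxels[1:25, 1:7, 1:7] = 1
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    return lf.LabelVolume(voxels=voxels, affine=aff, label_table={1: "LUL"})
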