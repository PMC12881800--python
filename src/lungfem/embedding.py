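"""Barycentric embedding of detail surfaces in a coarse FEM cage.

Each surface vertex is written as a convex combination of the four
nodes of one tetrahedron, so deforming the cage drives the
high-resolution visual mesh for free. Vertices that fall outside every
element (marching-cubes surfaces protrude beyond a centroid-kept
lattice) are attached to the nearest candidate element with clamped,
renormalized weights; the affected fraction is reported rather than
hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .meshing import TetMesh
from .surface import SurfaceMesh

#: containment slack on barycentric weights
_INSIDE_TOL = 1e-6


@dataclass
class EmbeddingMap:
    """Per-vertex (element, barycentric weights) assignment.

    elements: (N,) element index per surface vertex; weights: (N, 4)
    barycentric weights summing to 1; node_indices: (N, 4) cached cage
    node ids of the assigned element; clamped: (N,) bool, True where
    the vertex lay outside and its weights were clamped.
    """

    elements: np.ndarray
    weights: np.ndarray
    node_indices: np.ndarray
    clamped: np.ndarray
    cage_node_count: int

    @property
    def clamped_fraction(self) -> float:
        return float(self.clamped.mean()) if len(self.clamped) else 0.0


def _barycentric(points: np.ndarray, a: np.ndarray, minv: np.ndarray) -> np.ndarray:
    """Weights of points w.r.t. tets given corner a and inverse edge matrix."""
    lam = np.einsum("...ij,...j->...i", minv, points - a)
    w0 = 1.0 - lam.sum(axis=-1, keepdims=True)
    return np.concatenate([w0, lam], axis=-1)


def embed_surfaces(cage: TetMesh, surface: SurfaceMesh, k_candidates: int = 32) -> EmbeddingMap:
    """Assign every surface vertex to a cage tetrahedron.

    Containing elements win; when several contain a vertex (it sits on
    a shared face or node) the lowest element index is chosen, keeping
    the assignment deterministic. Vertices inside no candidate element
    fall back to the nearest element centroid (ties again to the lowest
    index) with weights clamped to [0, 1] and renormalized.
    """
    pts = surface.vertices
    a = cage.nodes[cage.tets[:, 0]]
    edges = np.stack(
        [cage.nodes[cage.tets[:, i]] - a for i in (1, 2, 3)], axis=-1
    )  # (T, 3, 3) columns are edge vectors
    minv = np.linalg.inv(edges)

    k = min(k_candidates, cage.tet_count)
    tree = cKDTree(cage.centroids())
    dist, cand = tree.query(pts, k=k)
    if k == 1:
        dist = dist[:, None]
        cand = cand[:, None]

    w = _barycentric(pts[:, None, :], a[cand], minv[cand])  # (N, k, 4)
    inside = (w.min(axis=-1) >= -_INSIDE_TOL) & (w.max(axis=-1) <= 1.0 + _INSIDE_TOL)

    n = len(pts)
    chosen = np.empty(n, dtype=np.int64)
    weights = np.empty((n, 4))
    clamped = np.zeros(n, dtype=bool)

    # containing element with the lowest element index
    masked_ids = np.where(inside, cand, np.iinfo(np.int64).max)
    best_in = masked_ids.argmin(axis=1)
    has_inside = inside.any(axis=1)
    # nearest centroid fallback; KDTree returns distances sorted, so the
    # minimum is column 0 — among exact distance ties pick the lowest id
    tie = dist <= dist[:, :1]
    best_near = np.where(tie, cand, np.iinfo(np.int64).max).argmin(axis=1)

    sel = np.where(has_inside, best_in, best_near)
    rows = np.arange(n)
    chosen[:] = cand[rows, sel]
    weights[:] = w[rows, sel]
    outside = ~has_inside
    if outside.any():
        cw = np.clip(weights[outside], 0.0, None)
        weights[outside] = cw / cw.sum(axis=1, keepdims=True)
        clamped[outside] = True

    return EmbeddingMap(
        elements=chosen,
        weights=weights,
        node_indices=cage.tets[chosen],
        clamped=clamped,
        cage_node_count=len(cage.nodes),
    )


def apply_embedding(cage_nodes_deformed: np.ndarray, emap: EmbeddingMap) -> np.ndarray:
    """Surface vertex positions under a deformed cage.

    Linear in the node positions: v = sum_i w_i x_i over the assigned
    element's nodes.
    """
    nodes = np.asarray(cage_nodes_deformed, dtype=float)
    if nodes.shape != (emap.cage_node_count, 3):
        raise ValueError(
            f"cage node array shape {nodes.shape} does not match embedding "
            f"({emap.cage_node_count}, 3)"
        )
    return np.einsum("ni,nij->nj", emap.weights, nodes[emap.node_indices])
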