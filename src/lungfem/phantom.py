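"""Synthetic thoracic phantoms: five lung lobes, vascular/bronchial trees.

The phantom stands in for a CT segmentation so the meshing, simulation
and evaluation layers can be exercised without patient data. It is
deliberately schematic: each lung is a smoothly deformed ellipsoid cut
by fissure planes into 2 (left) + 3 (right) lobes, and the pulmonary
artery, vein and bronchial tree are recursive bifurcating cylinder
trees rasterized into the voxel grid. Geometry is fully determined by
the seed: identical configs give bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import LABEL_NAMES, LOBE_LABELS, Label
from .surface import SurfaceMesh, mask_to_surface
from .volume import LabelVolume


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic thorax.

    grid_shape / spacing define the voxel grid (mm); tree_depth is the
    number of bifurcation generations (a depth-d tree has 2**d terminal
    tips); radius_decay and length_decay are the child/parent ratios;
    branch_angle_deg is the mean half-angle between siblings and their
    parent; tumor_radius (mm) adds a sphere inside the right lower lobe
    when set.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lobe_count: int = 5
    tree_depth: int = 4
    radius_decay: float = 0.75
    length_decay: float = 0.75
    branch_angle_deg: float = 35.0
    root_radius: float = 4.0
    root_length: float = 18.0
    tumor_radius: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 32 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes, each >= 32 voxels, got {self.grid_shape}")
        if self.tree_depth < 1:
            raise ValueError("tree_depth must be >= 1")
        if not 0.0 < self.radius_decay < 1.0:
            raise ValueError("radius_decay must lie in (0, 1)")
        if not 0.0 < self.length_decay < 1.0:
            raise ValueError("length_decay must lie in (0, 1)")
        if self.lobe_count != 5:
            raise ValueError("phantom models the human lung: lobe_count must be 5")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def extent(self) -> np.ndarray:
        """Physical grid size in mm."""
        return np.asarray(self.grid_shape, dtype=float) * np.asarray(self.spacing, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff


@dataclass(frozen=True)
class TreeSegment:
    """One straight cylinder of a bifurcating tree."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float
    generation: int  # root = 0

    @property
    def is_tip(self) -> bool:
        return self._tip

    _tip: bool = field(default=False, repr=False)


@dataclass
class PhantomResult:
    """Output bundle of :func:`generate_phantom`."""

    volume: LabelVolume
    surfaces: list[SurfaceMesh]
    trees: dict[int, list[TreeSegment]]

    def surface(self, label: int) -> SurfaceMesh:
        for mesh in self.surfaces:
            if mesh.structure == int(label):
                return mesh
        raise KeyError(f"no surface for label {int(label)}")

    def tips(self, label: int) -> list[TreeSegment]:
        """Terminal branches of one tree (2**tree_depth of them)."""
        return [s for s in self.trees[int(label)] if s.is_tip]


def _check_tree_fits(config: PhantomConfig) -> None:
    """Fail loudly when the requested tree cannot live on this grid."""
    depth = config.tree_depth
    reach = config.root_length * sum(config.length_decay**i for i in range(depth + 1))
    limit = 0.48 * float(min(config.extent))
    if reach > limit:
        raise ValueError(
            f"grid too small for tree_depth={depth}: tree reach {reach:.1f} mm exceeds "
            f"{limit:.1f} mm available; enlarge the grid or reduce tree_depth"
        )
    tip_radius = config.root_radius * config.radius_decay**depth
    min_raster = 0.45 * float(max(config.spacing))
    if tip_radius < min_raster:
        raise ValueError(
            f"grid too coarse for tree_depth={depth}: terminal radius {tip_radius:.2f} mm "
            f"is below the rasterizable limit {min_raster:.2f} mm at this spacing"
        )


def _rotate_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _orthonormal(d: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to d (deterministic)."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    return u / np.linalg.norm(u)


def build_tree(
    config: PhantomConfig,
    rng: np.random.Generator,
    root_start: np.ndarray,
    root_direction: np.ndarray,
) -> list[TreeSegment]:
    """Recursive bifurcating cylinder tree.

    The first bifurcation is steered laterally (toward both lungs);
    deeper ones branch at ``branch_angle_deg`` with seeded jitter in
    angle and azimuth. Radii and lengths shrink geometrically. RNG
    consumption is independent of radius_decay, so two configs that
    differ only in radius_decay share identical centerlines.
    """
    segments: list[TreeSegment] = []
    theta0 = np.deg2rad(config.branch_angle_deg)

    def grow(start: np.ndarray, direction: np.ndarray, length: float, radius: float, gen: int) -> None:
        end = start + direction * length
        tip = gen == config.tree_depth
        segments.append(
            TreeSegment(start=tuple(start), end=tuple(end), radius=radius, generation=gen, _tip=tip)
        )
        if tip:
            return
        if gen == 0:
            # main bifurcation: one child per lung, tilted strongly lateral
            lateral = np.array([1.0, 0.0, 0.0])
            tilt = np.deg2rad(55.0 + rng.uniform(-5.0, 5.0))
            for sign in (-1.0, 1.0):
                child = np.cos(tilt) * direction + np.sin(tilt) * sign * lateral
                child /= np.linalg.norm(child)
                grow(end, child, length * config.length_decay, radius * config.radius_decay, gen + 1)
            return
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
        for k in (0, 1):
            angle = theta0 * (1.0 + rng.uniform(-0.15, 0.15))
            u = _orthonormal(direction)
            u = _rotate_about(direction, azimuth + k * np.pi) @ u
            child = np.cos(angle) * direction + np.sin(angle) * u
            child /= np.linalg.norm(child)
            grow(end, child, length * config.length_decay, radius * config.radius_decay, gen + 1)

    grow(
        np.asarray(root_start, dtype=float),
        np.asarray(root_direction, dtype=float) / np.linalg.norm(root_direction),
        config.root_length,
        config.root_radius,
        0,
    )
    return segments


def _rasterize_segment(voxels: np.ndarray, config: PhantomConfig, seg: TreeSegment, code: int) -> None:
    """Stamp one cylinder into the grid (distance-to-segment test)."""
    spacing = np.asarray(config.spacing, dtype=float)
    p0 = np.asarray(seg.start)
    p1 = np.asarray(seg.end)
    pad = seg.radius + spacing.max()
    lo = np.maximum(np.floor((np.minimum(p0, p1) - pad) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + pad) / spacing).astype(int) + 1, voxels.shape)
    if np.any(lo >= hi):
        return
    idx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij")
    centers = np.stack([idx[i] * spacing[i] for i in range(3)], axis=-1)
    d = p1 - p0
    dd = float(d @ d)
    if dd < 1e-12:
        dist = np.linalg.norm(centers - p0, axis=-1)
    else:
        t = np.clip(((centers - p0) @ d) / dd, 0.0, 1.0)
        dist = np.linalg.norm(centers - (p0 + t[..., None] * d), axis=-1)
    inside = dist <= seg.radius
    sub = voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[inside] = code


def _lung_mask(
    coords: list[np.ndarray], center: np.ndarray, radii: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Deformed-ellipsoid lung body on the voxel grid."""
    u = [(coords[i] - center[i]) / radii[i] for i in range(3)]
    q = u[0] ** 2 + u[1] ** 2 + u[2] ** 2
    # low-order boundary ripple so the lungs are not perfect quadrics
    k1, k2 = rng.integers(2, 4, size=2)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    ripple = 0.06 * (np.sin(k1 * np.pi * u[1] + ph1) + np.sin(k2 * np.pi * u[2] + ph2)) / 2.0
    return q <= (1.0 + ripple) ** 2


def generate_phantom(config: PhantomConfig) -> PhantomResult:
    """Build the synthetic thorax: label volume, surfaces and trees.

    Label codes follow :class:`~lungfem.labels.Label`. Lobes are kept
    pairwise disjoint by clearing a fissure band of one voxel half-width
    on each side of every fissure plane. Paint order (later wins):
    lobes, tumor, artery, vein, bronchus.
    """
    _check_tree_fits(config)
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.grid_shape)
    spacing = np.asarray(config.spacing, dtype=float)
    extent = config.extent
    voxels = np.zeros(shape, dtype=np.int16)
    coords = [
        np.arange(shape[i])[
            tuple(slice(None) if j == i else None for j in range(3))
        ].astype(float)
        * spacing[i]
        for i in range(3)
    ]
    coords = list(np.broadcast_arrays(*coords))

    gap = float(spacing.max())  # fissure half-width: >= 1 voxel clearance

    def plane_distance(normal: np.ndarray, point: np.ndarray) -> np.ndarray:
        n = normal / np.linalg.norm(normal)
        return sum((coords[i] - point[i]) * n[i] for i in range(3))

    # --- lungs ------------------------------------------------------------
    lung_radii = np.array([0.17, 0.27, 0.36]) * extent
    jitter = rng.uniform(-0.02, 0.02, size=(2, 3)) * extent
    left_center = np.array([0.30, 0.50, 0.52]) * extent + jitter[0]
    right_center = np.array([0.70, 0.50, 0.52]) * extent + jitter[1]
    left = _lung_mask(coords, left_center, lung_radii, rng)
    right = _lung_mask(coords, right_center, lung_radii * np.array([1.03, 1.0, 1.0]), rng)

    # left oblique fissure: upper lobe above, lower lobe below
    n_left = np.array([0.0, 0.45, 0.89]) + rng.uniform(-0.05, 0.05, size=3)
    d = plane_distance(n_left, left_center)
    voxels[left & (d > gap)] = Label.LUL
    voxels[left & (d < -gap)] = Label.LLL

    # right oblique fissure separates the lower lobe ...
    n_ro = np.array([0.0, 0.50, 0.87]) + rng.uniform(-0.05, 0.05, size=3)
    d_ro = plane_distance(n_ro, right_center)
    voxels[right & (d_ro < -gap)] = Label.RLL
    # ... and the horizontal fissure splits upper from middle
    n_rh = np.array([0.0, 0.92, 0.39]) + rng.uniform(-0.05, 0.05, size=3)
    d_rh = plane_distance(n_rh, right_center + np.array([0.0, 0.0, -0.04]) * extent)
    upper_part = right & (d_ro > gap)
    voxels[upper_part & (d_rh > gap)] = Label.RUL
    voxels[upper_part & (d_rh < -gap)] = Label.RML

    # --- tumor (inside the right lower lobe) ------------------------------
    if config.tumor_radius is not None:
        rll = voxels == Label.RLL
        if not rll.any():
            raise ValueError("cannot place tumor: right lower lobe is empty")
        idx = np.argwhere(rll)
        c_vox = idx.mean(axis=0)
        center = c_vox * spacing
        r2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
        voxels[(r2 <= config.tumor_radius**2) & rll] = Label.TUMOR

    # --- trees ------------------------------------------------------------
    mediastinum = np.array([0.5, 0.5, 0.62]) * extent
    trees: dict[int, list[TreeSegment]] = {}
    for code, y_off in ((int(Label.ARTERY), -0.06), (int(Label.VEIN), 0.06), (int(Label.BRONCHUS), 0.0)):
        start = mediastinum + np.array([0.0, y_off, 0.0]) * extent
        trees[code] = build_tree(config, rng, start, np.array([0.0, 0.0, -1.0]))
    for code in (int(Label.ARTERY), int(Label.VEIN), int(Label.BRONCHUS)):
        for seg in trees[code]:
            _rasterize_segment(voxels, config, seg, code)

    # --- package ----------------------------------------------------------
    present = [int(v) for v in np.unique(voxels) if v != 0]
    table = {code: LABEL_NAMES[code] for code in present}
    volume = LabelVolume(voxels=voxels, affine=config.affine, label_table=table)
    surfaces = [mask_to_surface(voxels == code, config.affine, structure=code) for code in present]
    return PhantomResult(volume=volume, surfaces=surfaces, trees=trees)


def lobe_centroids(volume: LabelVolume) -> dict[int, np.ndarray]:
    """World-mm centroid of each lobe present in the volume."""
    from .volume import apply_affine

    out: dict[int, np.ndarray] = {}
    for code in LOBE_LABELS:
        mask = volume.mask(code)
        if mask.any():
            out[int(code)] = apply_affine(volume.affine, np.argwhere(mask).mean(axis=0))[0]
    return out
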