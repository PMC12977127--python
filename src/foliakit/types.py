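"""Core in-memory containers shared across the toolkit.

Conventions
-----------
* Voxel indices are 0-based.
* The 4x4 affine maps *voxel centers* ``(i, j, k, 1)`` to world coordinates
  in millimetres (NIfTI convention).
* All distances and displacements are expressed in mm.
* Label id 0 is reserved for background / unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import AffineError, DimensionalityError

BACKGROUND = 0

__all__ = [
    "BACKGROUND",
    "LabelTable",
    "LabeledSurface",
    "Volume",
    "LabelVolume",
    "DisplacementField",
    "make_affine",
]


def make_affine(voxel_size, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Build a diagonal voxel-center-to-world affine.

    Parameters
    ----------
    voxel_size : float or length-3 sequence
        Voxel edge length(s) in mm.
    origin : length-3 sequence
        World coordinate of the center of voxel (0, 0, 0).
    """
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    aff[:3, 3] = origin
    return aff


@dataclass
class LabelTable:
    """Mapping between integer label ids, anatomical names and RGB colors.

    ``entries`` is a list of ``(id, name, (r, g, b))`` triples.  Id 0 is the
    background and must be present.  Two ids are given a special role when the
    table is used by the atlas pipelines: ``white_matter_id`` designates the
    central white matter core (corpus medullare) and ``wm_tract_id`` the
    white-matter-tract patch that closes the cortical sheet where the
    peduncles were cut.
    """

    entries: list
    white_matter_id: Optional[int] = None
    wm_tract_id: Optional[int] = None

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        names = [e[1] for e in self.entries]
        if any(i < 0 for i in ids):
            raise ValueError("label ids must be non-negative")
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")
        if len(set(names)) != len(names):
            raise ValueError("label names must be unique")
        if BACKGROUND not in ids:
            raise ValueError("label table must contain the background id 0")

    @property
    def ids(self) -> list:
        return [e[0] for e in self.entries]

    @property
    def names(self) -> list:
        return [e[1] for e in self.entries]

    def name_of(self, label_id: int) -> str:
        for i, n, _ in self.entries:
            if i == label_id:
                return n
        raise KeyError(label_id)

    def color_of(self, label_id: int):
        for i, _, c in self.entries:
            if i == label_id:
                return tuple(c)
        raise KeyError(label_id)

    def cortical_ids(self) -> list:
        """Ids that are neither background, white matter nor wm-tract."""
        skip = {BACKGROUND, self.white_matter_id, self.wm_tract_id}
        return [i for i in self.ids if i not in skip]

    @classmethod
    def from_names(cls, names: Sequence[str], start_id: int = 1, **kw) -> "LabelTable":
        """Build a table with sequential ids and deterministic colors."""
        rng = np.random.default_rng(0)
        entries = [(0, "background", (0, 0, 0))]
        for k, name in enumerate(names):
            color = tuple(int(c) for c in rng.integers(1, 255, 3))
            entries.append((start_id + k, name, color))
        return cls(entries, **kw)


@dataclass
class LabeledSurface:
    """Closed triangular mesh with optional per-vertex labels.

    Attributes
    ----------
    vertices : (N, 3) float array, world mm
    faces : (M, 3) int array of 0-based vertex indices
    labels : (N,) int array or None
    spherical : (N, 3) float array or None
        Unit-sphere coordinates aligned with ``vertices`` row-for-row, used
        as a fast geodesic-distance proxy during parcellation.
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: Optional[np.ndarray] = None
    spherical: Optional[np.ndarray] = None
    label_table: Optional[LabelTable] = None

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.labels is not None:
            self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.n_vertices,):
                raise ValueError("labels must be length N")
        if self.spherical is not None:
            self.spherical = np.ascontiguousarray(self.spherical, dtype=np.float64)
            if self.spherical.shape != self.vertices.shape:
                raise ValueError("spherical coordinates must be (N, 3)")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def validate(self) -> None:
        """Raise if face indices are out of range, faces are degenerate or
        spherical rows are not unit length."""
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValueError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ValueError("degenerate face with repeated vertex index")
        if self.spherical is not None:
            norms = np.linalg.norm(self.spherical, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("spherical coordinates must have unit norm")

    def with_labels(self, labels: np.ndarray) -> "LabeledSurface":
        return LabeledSurface(self.vertices, self.faces, labels,
                              self.spherical, self.label_table)

    def copy(self) -> "LabeledSurface":
        return LabeledSurface(
            self.vertices.copy(), self.faces.copy(),
            None if self.labels is None else self.labels.copy(),
            None if self.spherical is None else self.spherical.copy(),
            self.label_table)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise AffineError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise AffineError("affine is singular")
    return affine


@dataclass
class Volume:
    """A 3-D scalar grid with a voxel-center-to-world affine."""

    array: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D array, got {self.array.ndim}-D")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self):
        return self.array.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length per axis in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (n_voxels, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx)

    def sample(self, points_world: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate the grid at world points (nearest-edge extrapolation)."""
        vox = self.world_to_voxel(points_world)
        return map_coordinates(self.array.astype(float), vox.T, order=order,
                               mode="nearest")

    def copy(self) -> "Volume":
        return type(self)(self.array.copy(), self.affine.copy())


@dataclass
class LabelVolume(Volume):
    """Integer label grid.  0 is background; negative ids are transient
    sentinels used inside pipelines (never written to disk)."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.array.dtype, np.integer):
            raise TypeError("LabelVolume requires an integer array")

    def census(self) -> Mapping[int, int]:
        """Voxel count per label id present in the grid."""
        ids, counts = np.unique(self.array, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class DisplacementField:
    """Dense 3-D displacement field in world mm on a voxel grid.

    ``vectors[i, j, k]`` is the mm displacement of the point at the world
    position of voxel center ``(i, j, k)``.  A field represents the map
    ``x -> x + u(x)``; it is diffeomorphic when the Jacobian determinant of
    that map is positive everywhere.
    """

    vectors: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise DimensionalityError("vectors must be (X, Y, Z, 3)")
        self.affine = _check_affine(self.affine)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self):
        return self.vectors.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def zeros(cls, shape, affine) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (3,)), affine)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def sample(self, points_world: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the displacement at world points."""
        vox = self.world_to_voxel(points_world).T
        out = np.empty((vox.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(self.vectors[..., c], vox, order=1,
                                        mode="nearest")
        return out

    def apply_to_points(self, points_world: np.ndarray) -> np.ndarray:
        points_world = np.atleast_2d(np.asarray(points_world, dtype=float))
        return points_world + self.sample(points_world)

    def jacobian_determinant(self) -> np.ndarray:
        """Determinant of the Jacobian of ``x + u(x)`` at interior grid points.

        Central finite differences in world units; returned array has shape
        ``(X-2, Y-2, Z-2)``.
        """
        vs = self.voxel_size
        J = np.empty(tuple(s - 2 for s in self.shape) + (3, 3))
        interior = (slice(1, -1),) * 3
        for c in range(3):
            g = np.gradient(self.vectors[..., c], *vs, edge_order=1)
            for ax in range(3):
                J[..., c, ax] = g[ax][interior]
        J += np.eye(3)
        return np.linalg.det(J)

    def is_diffeomorphic(self) -> bool:
        return bool(np.all(self.jacobian_determinant() > 0))

    def max_magnitude(self) -> float:
        return float(np.max(np.linalg.norm(self.vectors, axis=-1)))

    def invert(self, n_iter: int = 50, tol_mm: float = 1e-3) -> "DisplacementField":
        """Numerically invert the map ``x + u(x)`` by fixed-point iteration.

        Solves ``v(x) = -u(x + v(x))`` on the field's own grid; converges for
        fields whose displacement gradient is a contraction (the case for the
        smooth deformations used here).
        """
        grid = Volume(np.zeros(self.shape), self.affine).voxel_centers()
        v = np.zeros_like(grid)
        for _ in range(n_iter):
            v_new = -self.sample(grid + v)
            if np.max(np.abs(v_new - v)) < tol_mm:
                v = v_new
                break
            v = v_new
        return DisplacementField(v.reshape(self.shape + (3,)), self.affine.copy())

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy(), self.affine.copy())
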