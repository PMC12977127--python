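"""Synthetic folded phantoms, smooth deformations and synthetic subjects.

Real cerebellar surface reconstructions are enormous (millions of vertices)
and not redistributable here, so every other module is exercised on closed
genus-0 "folded sphere" phantoms whose radial profile mimics folial folding,
with contiguous latitude-band region labels standing in for lobules.  All
generators are bit-reproducible from their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import trimesh
from scipy.ndimage import map_coordinates

from .errors import PhantomSpecError
from .types import (DisplacementField, LabelTable, LabeledSurface,
                    LabelVolume, Volume)
from .voxelize import winding_numbers

__all__ = [
    "PhantomSpec",
    "make_folded_phantom",
    "make_smooth_deformation",
    "make_subject",
    "phantom_label_table",
]


@dataclass
class PhantomSpec:
    """Parameters of a folded-sphere phantom.

    The surface is a subdivided icosphere of radius ``base_radius`` mm whose
    radius is modulated by ``1 + a * sin(k*theta) * sin(k*phi)`` in spherical
    angles; ``fold_count`` k controls the number of folds and
    ``fold_amplitude`` a their depth as a fraction of the radius.  Defaults
    (R = 25 mm, k = 6, a = 0.2, subdivision 5, about 10k vertices) are large
    enough to exercise folding while keeping tests at seconds scale.
    """

    base_radius: float = 25.0
    fold_count: int = 6
    fold_amplitude: float = 0.2
    mesh_subdivisions: int = 5
    n_regions: int = 8
    rng_seed: int = 0
    midline_strip: bool = False
    strip_half_width_rad: float = 0.15

    def __post_init__(self):
        if not (0 <= self.fold_amplitude < 0.5):
            raise PhantomSpecError("fold_amplitude must be in [0, 0.5)")
        if self.fold_count < 0:
            raise PhantomSpecError("fold_count must be >= 0")
        if self.n_regions < 1:
            raise PhantomSpecError("n_regions must be >= 1")


def phantom_label_table(spec: PhantomSpec) -> LabelTable:
    names = [f"band_{i}" for i in range(1, spec.n_regions + 1)]
    strip_id = None
    if spec.midline_strip:
        names.append("midline_strip")
        strip_id = spec.n_regions + 1
    table = LabelTable.from_names(names)
    table.white_matter_id = None
    table.wm_tract_id = None
    if strip_id is not None:
        # keep the id addressable for hierarchy definitions
        table.midline_strip_id = strip_id  # type: ignore[attr-defined]
    return table


def make_folded_phantom(spec: PhantomSpec,
                        validate: bool = True) -> LabeledSurface:
    """Closed, labeled, folded genus-0 phantom surface.

    Region labels are ``n_regions`` contiguous latitude bands of equal
    spherical area (ids 1..n).  The unit icosphere vertices are attached as
    the spherical coordinates, exactly as a real surface ships an aligned
    sphere representation.  With ``midline_strip`` a narrow meridian strip
    (id ``n_regions + 1``) is carved across the bands to emulate a midline
    vermis group.

    ``validate`` checks a sample of slightly-offset face centroids with the
    winding test and raises :class:`PhantomSpecError` on self-intersection.
    """
    ico = trimesh.creation.icosphere(subdivisions=spec.mesh_subdivisions,
                                     radius=1.0)
    unit = np.asarray(ico.vertices, dtype=np.float64)
    faces = np.asarray(ico.faces, dtype=np.int64)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)

    theta = np.arccos(np.clip(unit[:, 2], -1, 1))       # polar angle
    phi = np.arctan2(unit[:, 1], unit[:, 0])            # azimuth
    r = spec.base_radius * (1.0 + spec.fold_amplitude
                            * np.sin(spec.fold_count * theta)
                            * np.sin(spec.fold_count * phi))
    vertices = unit * r[:, np.newaxis]

    # equal-area latitude bands: uniform split of cos(theta)
    z = unit[:, 2]
    band = np.minimum(((z + 1.0) / 2.0 * spec.n_regions).astype(np.int64),
                      spec.n_regions - 1)
    labels = band + 1
    if spec.midline_strip:
        on_strip = np.abs(phi) < spec.strip_half_width_rad
        labels = labels.copy()
        labels[on_strip] = spec.n_regions + 1

    surface = LabeledSurface(vertices, faces, labels, spherical=unit,
                             label_table=phantom_label_table(spec))
    surface.validate()

    if validate and spec.fold_amplitude > 0:
        rng = np.random.default_rng(spec.rng_seed)
        sample = rng.choice(len(faces), size=min(200, len(faces)),
                            replace=False)
        tri = vertices[faces[sample]]
        centroids = tri.mean(axis=1)
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        probe = centroids - 1e-3 * spec.base_radius * normals
        w = winding_numbers(surface, probe)
        if np.any(np.abs(np.round(w)) > 1):
            raise PhantomSpecError(
                "fold amplitude causes a self-intersecting surface")
    return surface


def make_smooth_deformation(grid_shape,
                            affine: np.ndarray,
                            amplitude_mm: float,
                            wavelength_mm: float,
                            rng_seed: int = 0,
                            n_waves: int = 3) -> DisplacementField:
    """Band-limited random sinusoid mixture with guaranteed positive Jacobian.

    Each displacement component is a sum of ``n_waves`` random-direction,
    random-phase plane sinusoids of wavelength ``wavelength_mm``, scaled so
    the peak displacement magnitude is ``amplitude_mm`` and then, if needed,
    rescaled further so the maximum finite-difference displacement gradient
    stays below 0.9 (a sufficient condition for a positive Jacobian of
    ``x + u(x)``).  ``amplitude_mm = 0`` yields the identity field.
    """
    rng = np.random.default_rng(rng_seed)
    grid = Volume(np.zeros(tuple(grid_shape)), affine)
    pts = grid.voxel_centers()
    u = np.zeros((len(pts), 3))
    if amplitude_mm > 0:
        for c in range(3):
            for _ in range(n_waves):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                phase = rng.uniform(0, 2 * np.pi)
                amp = rng.uniform(0.5, 1.0)
                u[:, c] += amp * np.sin(2 * np.pi * (pts @ d) / wavelength_mm
                                        + phase)
        peak = np.max(np.linalg.norm(u, axis=1))
        if peak > 0:
            u *= amplitude_mm / peak
    vectors = u.reshape(tuple(grid_shape) + (3,))
    field = DisplacementField(vectors, affine)
    g = _max_gradient(field)
    if g >= 0.9:
        field = DisplacementField(vectors * (0.9 / g * 0.999), affine)
    return field


def _max_gradient(field: DisplacementField) -> float:
    """Max row-sum norm of the displacement gradient (world units)."""
    vs = field.voxel_size
    worst = 0.0
    for c in range(3):
        gs = np.gradient(field.vectors[..., c], *vs)
        row = np.abs(gs[0]) + np.abs(gs[1]) + np.abs(gs[2])
        worst = max(worst, float(row.max()))
    return worst


def _warp_volume(volume: Volume, field: DisplacementField,
                 order: int) -> np.ndarray:
    """Pull-back resampling: out(x) = volume(x + u(x)) on the volume's grid."""
    grid = Volume(np.zeros(volume.shape), volume.affine)
    pts = grid.voxel_centers() + field.sample(grid.voxel_centers())
    vox = volume.world_to_voxel(pts)
    out = map_coordinates(volume.array.astype(float), vox.T, order=order,
                          mode="nearest")
    return out.reshape(volume.shape)


def make_subject(atlas_label_volume: LabelVolume,
                 atlas_virtual_mri: Volume,
                 field: DisplacementField,
                 noise_sd: float = 0.0,
                 rng_seed: int = 0
                 ) -> Tuple[Volume, LabelVolume, DisplacementField]:
    """Synthesize a subject as a known diffeomorphic deformation of the atlas.

    The segmentation is resampled with nearest-neighbor and the intensity
    image with trilinear interpolation through ``x -> x + u(x)``; Gaussian
    noise of ``noise_sd`` is added to the intensities.  Returns
    ``(subject_mri, subject_segmentation, field)`` where the returned field
    is the pull-back ground truth: ``subject(x) = atlas(x + u(x))``, so the
    true atlas-to-subject point map is the inverse ``(id + u)^{-1}``.
    """
    rng = np.random.default_rng(rng_seed)
    seg = _warp_volume(atlas_label_volume, field, order=0)
    seg = np.round(seg).astype(atlas_label_volume.array.dtype)
    mri = _warp_volume(atlas_virtual_mri, field, order=1)
    if noise_sd > 0:
        mri = mri + rng.normal(0, noise_sd, mri.shape)
    return (Volume(mri, atlas_virtual_mri.affine.copy()),
            LabelVolume(seg, atlas_label_volume.affine.copy()),
            field.copy())
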