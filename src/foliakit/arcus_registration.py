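"""Two-stage diffeomorphic atlas-to-subject surface reconstruction (ARCUS).

The reconstruction warps a combined surface/volume atlas into an individual
subject's space in two sequential registrations: first the volumetric atlas
labels are registered to the subject's lobular segmentation (overall lobule
fit), then a virtual MRI rendered from the atlas — already carried through
the first transform — is registered to the masked subject image (local
fine-tuning).  The composed transform is finally applied to the atlas
surface vertices, yielding a lobule-labeled cortical sheet in subject space.

The builtin backend is a diffeomorphic demons registration: a smooth
stationary velocity field is updated with (optionally locally normalized)
intensity-difference forces over a coarse-to-fine pyramid, Gaussian
regularized, and exponentiated by scaling-and-squaring, which guarantees a
positive Jacobian.  Labels are registered as per-label one-hot channels
blurred by 1 mm with forces summed over channels.  An external-adapter hook
lets users substitute any registration tool that returns a displacement
field (e.g. a symmetric-normalization implementation).

Displacement fields follow the pull-back convention of image resampling:
``register(fixed, moving)`` returns ``u`` with ``moving(x + u(x)) ~
fixed(x)``.  Point sets therefore move with the *inverse* map, which is
computed by fixed-point inversion when vertices are carried to subject
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, uniform_filter

from .errors import DomainError, GridError, LabelLookupError, MetricError
from .types import DisplacementField, LabeledSurface, LabelVolume, Volume

__all__ = [
    "RegistrationBackendConfig",
    "make_virtual_mri",
    "register",
    "compose_fields",
    "warp_surface",
    "warp_volume",
    "arcus_reconstruct",
    "DEFAULT_INTENSITIES",
]

#: Default virtual-MRI intensity assignment (arbitrary units): cortex bright
#: mid-gray, white matter bright, background dark.
DEFAULT_INTENSITIES = {"cortex": 110.0, "white_matter": 250.0, "background": 0.0}


@dataclass
class RegistrationBackendConfig:
    """Configuration of the registration backend.

    ``smoothing_sigma_mm`` regularizes the velocity field (diffusion-like),
    ``update_sigma_mm`` the per-iteration force (fluid-like); both are in mm
    and apply at every pyramid level.  ``step_size`` caps the per-iteration
    update in voxels.  ``max_iterations`` is given per level,
    coarsest first.
    """

    backend: str = "builtin-demons"
    metric: str = "ssd"  # or "lncc" (local normalization, window 5 voxels)
    pyramid_levels: int = 3
    smoothing_sigma_mm: float = 2.0
    update_sigma_mm: float = 1.0
    step_size: float = 2.0
    max_iterations: Sequence[int] = (50, 50, 30)
    lncc_window_voxels: int = 5
    external_adapter: Optional[Callable[..., DisplacementField]] = None

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.smoothing_sigma_mm <= 0 or self.update_sigma_mm <= 0:
            raise ValueError("smoothing sigmas must be > 0")


def make_virtual_mri(label_volume: LabelVolume,
                     intensity_map: Dict[int, float],
                     blur_sigma_mm: float = 0.5) -> Volume:
    """Render an intensity image from a label volume.

    Each voxel receives its label's intensity from ``intensity_map``; the
    image is then blurred with a Gaussian of ``blur_sigma_mm`` and clipped
    back to the range of the map.  Every label present in the volume must be
    mapped.
    """
    present = set(int(v) for v in np.unique(label_volume.array))
    missing = sorted(present - set(int(k) for k in intensity_map))
    if missing:
        raise LabelLookupError(f"intensity_map lacks label id(s) {missing}")
    lut_ids = np.array(sorted(intensity_map))
    lut_vals = np.array([float(intensity_map[i]) for i in lut_ids])
    img = lut_vals[np.searchsorted(lut_ids, label_volume.array)]
    if blur_sigma_mm > 0:
        sigma_vox = blur_sigma_mm / label_volume.voxel_size
        img = gaussian_filter(img, sigma_vox)
        img = np.clip(img, lut_vals.min(), lut_vals.max())
    return Volume(img, label_volume.affine.copy())


# ---------------------------------------------------------------------------
# builtin diffeomorphic demons

def _as_channels(image) -> Tuple[List[np.ndarray], np.ndarray]:
    if isinstance(image, Volume):
        return [image.array.astype(np.float64)], image.affine
    chans = [v.array.astype(np.float64) for v in image]
    return chans, image[0].affine


def _local_normalize(img: np.ndarray, window: int) -> np.ndarray:
    mu = uniform_filter(img, window)
    var = uniform_filter(img * img, window) - mu * mu
    return (img - mu) / np.sqrt(np.maximum(var, 1e-8))


def _downsample(img: np.ndarray) -> np.ndarray:
    return gaussian_filter(img, 1.0)[::2, ::2, ::2]


def _upsample_vec(vec: np.ndarray, target_shape) -> np.ndarray:
    from scipy.ndimage import zoom
    factors = [t / s for t, s in zip(target_shape, vec.shape[:3])]
    out = np.empty(tuple(target_shape) + (3,))
    for c in range(3):
        out[..., c] = zoom(vec[..., c], factors, order=1)
    return out


def _warp_channels_vox(chans: List[np.ndarray], disp_vox: np.ndarray
                       ) -> List[np.ndarray]:
    shape = chans[0].shape
    grid = np.indices(shape, dtype=np.float64)
    coords = [grid[c] + disp_vox[..., c] for c in range(3)]
    return [map_coordinates(ch, coords, order=1, mode="nearest")
            for ch in chans]


def _exp_field_vox(vel: np.ndarray) -> np.ndarray:
    """Exponentiate a stationary velocity field by scaling and squaring
    (voxel units)."""
    mx = float(np.max(np.linalg.norm(vel, axis=-1)))
    n = max(0, int(np.ceil(np.log2(max(mx, 1e-9) / 0.5))))
    phi = vel / (2 ** n)
    for _ in range(n):
        warped = np.stack(_warp_channels_vox(
            [phi[..., c] for c in range(3)], phi), axis=-1)
        phi = phi + warped
    return phi


def _demons_level(fixed: List[np.ndarray], moving: List[np.ndarray],
                  vel: np.ndarray, iterations: int, voxel_size: np.ndarray,
                  config: RegistrationBackendConfig) -> np.ndarray:
    sigma_up = config.update_sigma_mm / voxel_size
    sigma_reg = config.smoothing_sigma_mm / voxel_size
    kappa2 = float(np.mean(voxel_size) ** 2)
    grads_f = [np.stack(np.gradient(f, *voxel_size), axis=-1) for f in fixed]
    for _ in range(iterations):
        phi = _exp_field_vox(vel)
        warped = _warp_channels_vox(moving, phi)
        num = np.zeros(vel.shape)
        den = np.zeros(vel.shape[:3])
        for f, m, gf in zip(fixed, warped, grads_f):
            gm = np.stack(np.gradient(m, *voxel_size), axis=-1)
            g = 0.5 * (gf + gm)
            diff = f - m
            num += diff[..., None] * g
            den += np.sum(g * g, axis=-1) + diff * diff / kappa2
        update_mm = num / np.maximum(den, 1e-12)[..., None]
        update_vox = update_mm / voxel_size
        nrm = np.linalg.norm(update_vox, axis=-1)
        cap = config.step_size
        scale = np.where(nrm > cap, cap / np.maximum(nrm, 1e-12), 1.0)
        update_vox *= scale[..., None]
        for c in range(3):
            update_vox[..., c] = gaussian_filter(update_vox[..., c], sigma_up)
        vel = vel + update_vox
        for c in range(3):
            vel[..., c] = gaussian_filter(vel[..., c], sigma_reg)
    return vel


def register(fixed, moving,
             config: Optional[RegistrationBackendConfig] = None
             ) -> DisplacementField:
    """Deformably register ``moving`` to ``fixed``.

    Inputs are :class:`~foliakit.types.Volume` instances (or sequences of
    them, treated as channels of one multi-channel image) on the same grid.
    Returns a displacement field ``u`` in world mm on the fixed grid such
    that resampling ``moving`` through ``x + u(x)`` approximates ``fixed``;
    the field is the exponential of a smooth velocity field and passes the
    positive-Jacobian check.
    """
    config = config or RegistrationBackendConfig()
    fixed_ch, aff_f = _as_channels(fixed)
    moving_ch, aff_m = _as_channels(moving)
    if fixed_ch[0].shape != moving_ch[0].shape or not np.allclose(aff_f, aff_m):
        raise GridError("builtin backend requires fixed and moving on the "
                        "same grid")
    if config.backend == "external-adapter":
        if config.external_adapter is None:
            raise ValueError("external-adapter backend needs "
                             "config.external_adapter")
        return config.external_adapter(fixed, moving, config)
    if config.backend != "builtin-demons":
        raise ValueError(f"unknown backend {config.backend!r}")

    for ch in fixed_ch + moving_ch:
        if np.ptp(ch) == 0 and config.metric == "lncc":
            raise MetricError("constant image: local normalized correlation "
                              "is undefined; use metric='ssd'")

    voxel_size = np.linalg.norm(aff_f[:3, :3], axis=0)

    # build pyramids, coarsest last in the lists below
    pyr_f = [fixed_ch]
    pyr_m = [moving_ch]
    pyr_vs = [voxel_size]
    for _ in range(config.pyramid_levels - 1):
        if min(pyr_f[-1][0].shape) < 8:
            break
        pyr_f.append([_downsample(c) for c in pyr_f[-1]])
        pyr_m.append([_downsample(c) for c in pyr_m[-1]])
        pyr_vs.append(pyr_vs[-1] * 2)
    n_levels = len(pyr_f)
    iters = list(config.max_iterations)
    while len(iters) < n_levels:
        iters = [iters[0]] + iters

    vel = None
    for level in range(n_levels - 1, -1, -1):
        f_ch, m_ch, vs = pyr_f[level], pyr_m[level], pyr_vs[level]
        if config.metric == "lncc":
            w = config.lncc_window_voxels
            f_ch = [_local_normalize(c, w) for c in f_ch]
            m_ch = [_local_normalize(c, w) for c in m_ch]
        shape = f_ch[0].shape
        if vel is None:
            vel_vox = np.zeros(shape + (3,))
        else:
            vel_vox = _upsample_vec(vel, shape) * 2.0  # finer voxels: mm same
        it = iters[n_levels - 1 - level] if len(iters) >= n_levels else iters[-1]
        vel = _demons_level(f_ch, m_ch, vel_vox, it, vs, config)

    disp_vox = _exp_field_vox(vel)
    disp_mm = disp_vox @ aff_f[:3, :3].T  # voxel steps to world mm
    return DisplacementField(disp_mm, aff_f.copy())


# ---------------------------------------------------------------------------
# field algebra and application

def compose_fields(first: DisplacementField,
                   second: DisplacementField) -> DisplacementField:
    """Compose two displacement fields: applying the result equals applying
    ``first`` then ``second``.

    ``composed(x) = first(x) + second(x + first(x))`` on the grid of
    ``first``, with trilinear interpolation of ``second``.
    """
    grid = Volume(np.zeros(first.shape), first.affine).voxel_centers()
    u1 = first.sample(grid)
    u2 = second.sample(grid + u1)
    return DisplacementField((u1 + u2).reshape(first.shape + (3,)),
                             first.affine.copy())


def warp_surface(surface: LabeledSurface,
                 field_chain: Union[DisplacementField, Sequence[DisplacementField]],
                 max_outside_fraction: float = 0.01) -> LabeledSurface:
    """Displace surface vertices through a chain of fields, in order.

    Faces, labels and spherical coordinates are unchanged.  Vertices outside
    a field's grid are extrapolated from the nearest edge; if more than
    ``max_outside_fraction`` of vertices fall outside, a :class:`DomainError`
    is raised.
    """
    if isinstance(field_chain, DisplacementField):
        field_chain = [field_chain]
    verts = surface.vertices.copy()
    for f in field_chain:
        vox = f.world_to_voxel(verts)
        outside = np.any((vox < 0) | (vox > np.array(f.shape) - 1), axis=1)
        if outside.mean() > max_outside_fraction:
            raise DomainError(
                f"{outside.sum()} of {len(verts)} vertices outside the "
                "displacement field domain")
        verts = verts + f.sample(verts)
    return LabeledSurface(verts, surface.faces.copy(),
                          None if surface.labels is None else surface.labels.copy(),
                          None if surface.spherical is None else surface.spherical.copy(),
                          surface.label_table)


def warp_volume(volume: Volume, field: DisplacementField,
                order: int = 1) -> Volume:
    """Pull-back resampling of a volume through ``x + u(x)`` on its own grid
    (order 0 for label volumes)."""
    grid = Volume(np.zeros(volume.shape), volume.affine)
    pts = grid.voxel_centers()
    pts = pts + field.sample(pts)
    vox = volume.world_to_voxel(pts)
    out = map_coordinates(volume.array.astype(float), vox.T, order=order,
                          mode="nearest").reshape(volume.shape)
    if order == 0:
        return LabelVolume(np.round(out).astype(volume.array.dtype),
                           volume.affine.copy())
    return Volume(out, volume.affine.copy())


# ---------------------------------------------------------------------------
# the two-stage reconstruction

def _one_hot_channels(vol: LabelVolume, label_ids: Sequence[int],
                      blur_mm: float = 1.0) -> List[Volume]:
    sigma = blur_mm / vol.voxel_size
    out = []
    for lab in label_ids:
        m = (vol.array == lab).astype(np.float64)
        out.append(Volume(gaussian_filter(m, sigma), vol.affine))
    return out


def arcus_reconstruct(atlas_label_volume: LabelVolume,
                      atlas_surface: LabeledSurface,
                      atlas_virtual_mri: Volume,
                      subject_segmentation: LabelVolume,
                      subject_mri: Volume,
                      subject_mask: Optional[np.ndarray] = None,
                      config: Optional[RegistrationBackendConfig] = None,
                      return_fields: bool = False):
    """Reconstruct the cortical surface in subject space.

    Stage 1 registers the atlas label volume (blurred one-hot channels) to
    the subject segmentation; stage 2 carries the atlas virtual MRI through
    the stage-1 transform and registers it to the subject MRI restricted to
    ``subject_mask`` (multiplicative masking).  Both stage fields are
    image-resampling (pull-back) maps, so the vertex chain applies their
    numerical inverses in order; the output surface has the same face list,
    labels and spherical coordinates as the atlas surface.

    Returns the warped surface, or ``(surface, (stage1, stage2))`` with the
    pull-back fields when ``return_fields`` is set.
    """
    config = config or RegistrationBackendConfig()
    atlas_ids = set(int(v) for v in np.unique(atlas_label_volume.array)) - {0}
    subj_ids = set(int(v) for v in np.unique(subject_segmentation.array)) - {0}
    if not subj_ids <= atlas_ids:
        raise LabelLookupError(
            f"subject segmentation labels {sorted(subj_ids - atlas_ids)} "
            "missing from the atlas label volume")
    label_ids = sorted(atlas_ids)

    fixed1 = _one_hot_channels(subject_segmentation, label_ids)
    moving1 = _one_hot_channels(atlas_label_volume, label_ids)
    stage1 = register(fixed1, moving1, config)

    mri1 = warp_volume(atlas_virtual_mri, stage1, order=1)
    subj = subject_mri.array.astype(np.float64)
    if subject_mask is not None:
        subj = subj * subject_mask
        mri1 = Volume(mri1.array * subject_mask, mri1.affine)
    stage2 = register(Volume(subj, subject_mri.affine), mri1, config)

    # pull-back fields map subject -> atlas; vertices travel atlas -> subject
    inv1 = stage1.invert()
    inv2 = stage2.invert()
    out = warp_surface(atlas_surface, [inv1, inv2])
    if return_fields:
        return out, (stage1, stage2)
    return out
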