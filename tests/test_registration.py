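"""Virtual MRI synthesis, diffeomorphic demons registration, field algebra
and the two-stage atlas-to-subject surface reconstruction."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt, gaussian_filter1d

from foliakit.arcus_registration import (RegistrationBackendConfig,
                                         arcus_reconstruct, compose_fields,
                                         make_virtual_mri, register,
                                         warp_surface, warp_volume)
from foliakit.errors import DomainError, GridError, LabelLookupError
from foliakit.evaluation import dice
from foliakit.label_pipeline import PipelineConfig, run_atlas_volume_pipeline
from foliakit.synthetic_data import (PhantomSpec, make_folded_phantom,
                                     make_smooth_deformation, make_subject)
from foliakit.types import (DisplacementField, LabelVolume, Volume,
                            make_affine)


# ------------------------------------------------------------- virtual MRI

def test_virtual_mri_single_label_constant():
    vol = LabelVolume(np.full((8, 8, 8), 3, dtype=np.int32), make_affine(1.0))
    img = make_virtual_mri(vol, {3: 110.0}, blur_sigma_mm=0)
    assert np.all(img.array == 110.0)


def test_virtual_mri_two_labels_no_blur():
    arr = np.zeros((8, 8, 8), dtype=np.int32)
    arr[4:] = 7
    img = make_virtual_mri(LabelVolume(arr, make_affine(1.0)),
                           {0: 0.0, 7: 200.0}, blur_sigma_mm=0)
    assert set(np.unique(img.array)) == {0.0, 200.0}


def test_virtual_mri_blur_matches_1d_gaussian_oracle():
    """A two-label slab blurred in 3-D equals the 1-D convolution of the step
    profile along the slab normal, with midpoint intensity at the interface."""
    arr = np.zeros((40, 16, 16), dtype=np.int32)
    arr[20:] = 1
    vol = LabelVolume(arr, make_affine(1.0))
    img = make_virtual_mri(vol, {0: 0.0, 1: 100.0}, blur_sigma_mm=2.0)
    profile = img.array[:, 8, 8]
    oracle = gaussian_filter1d(np.where(np.arange(40) >= 20, 100.0, 0.0), 2.0)
    np.testing.assert_allclose(profile[4:-4], oracle[4:-4], atol=1e-6)
    mid = 0.5 * (profile[19] + profile[20])
    assert mid == pytest.approx(50.0, abs=1e-6)


def test_virtual_mri_unmapped_label_rejected():
    vol = LabelVolume(np.full((4, 4, 4), 9, dtype=np.int32), make_affine(1.0))
    with pytest.raises(LabelLookupError, match="9"):
        make_virtual_mri(vol, {0: 0.0})


# ------------------------------------------------------------- registration

def _blob(center, shape=(32, 32, 32), width=50.0):
    x, y, z = np.indices(shape)
    return 100.0 * np.exp(-((x - center[0]) ** 2 + (y - center[1]) ** 2
                            + (z - center[2]) ** 2) / width)


def test_register_identity_returns_zero_field():
    f = Volume(_blob((16, 16, 16)), make_affine(1.0))
    u = register(f, f, RegistrationBackendConfig(max_iterations=(10, 10, 5)))
    assert u.max_magnitude() < 0.1


def test_register_recovers_translation():
    aff = make_affine(1.0)
    fixed = Volume(_blob((16, 16, 16)), aff)
    moving = Volume(_blob((13, 16, 16)), aff)
    u = register(fixed, moving, RegistrationBackendConfig())
    core = fixed.array > 30
    mean_u = u.vectors[core].mean(axis=0)
    np.testing.assert_allclose(mean_u, [-3.0, 0.0, 0.0], atol=0.5)
    assert u.is_diffeomorphic()


def test_register_agrees_with_independent_demons_backend():
    """Cross-check against SimpleITK's diffeomorphic demons on the same
    translation-recovery problem."""
    import SimpleITK as sitk
    aff = make_affine(1.0)
    fixed = Volume(_blob((16, 16, 16)), aff)
    moving = Volume(_blob((13, 16, 16)), aff)
    ours = register(fixed, moving, RegistrationBackendConfig())
    dem = sitk.DiffeomorphicDemonsRegistrationFilter()
    dem.SetNumberOfIterations(80)
    dem.SetStandardDeviations(2.0)
    out = dem.Execute(sitk.GetImageFromArray(fixed.array),
                      sitk.GetImageFromArray(moving.array))
    # sitk arrays index [z][y][x] which maps back to our (i, j, k); the
    # physical (x, y, z) vector components therefore reverse to (i, j, k)
    ref = sitk.GetArrayFromImage(out)[..., ::-1]
    core = fixed.array > 30
    ref_mean = ref[core].mean(axis=0)
    our_mean = ours.vectors[core].mean(axis=0)
    np.testing.assert_allclose(our_mean, ref_mean, atol=0.5)


def _boundary_distance(mask_a, mask_b):
    """Mean distance from the boundary of A to the boundary of B."""
    from scipy.ndimage import binary_erosion
    ba = mask_a & ~binary_erosion(mask_a)
    bb = mask_b & ~binary_erosion(mask_b)
    dt = distance_transform_edt(~bb)
    return dt[ba].mean()


def test_register_reduces_label_boundary_distance():
    """A sinusoidal warp of 2-voxel amplitude: registration cuts the mean
    label boundary distance by at least 60%."""
    s = make_folded_phantom(PhantomSpec(mesh_subdivisions=3, n_regions=2))
    vol, _ = run_atlas_volume_pipeline(s, PipelineConfig(voxel_size=2.0))
    field = make_smooth_deformation(vol.shape, vol.affine, amplitude_mm=4.0,
                                    wavelength_mm=40.0, rng_seed=2)
    warped = warp_volume(vol, field, order=0)
    from foliakit.arcus_registration import _one_hot_channels
    ids = sorted(int(v) for v in np.unique(vol.array) if v != 0)
    u = register(_one_hot_channels(warped, ids), _one_hot_channels(vol, ids),
                 RegistrationBackendConfig())
    recovered = warp_volume(vol, u, order=0)
    before = np.mean([_boundary_distance(vol.array == i, warped.array == i)
                      for i in ids])
    after = np.mean([_boundary_distance(recovered.array == i, warped.array == i)
                     for i in ids])
    assert after <= 0.4 * before


def test_register_grid_mismatch_rejected():
    a = Volume(np.zeros((8, 8, 8)), make_affine(1.0))
    b = Volume(np.zeros((9, 9, 9)), make_affine(1.0))
    with pytest.raises(GridError):
        register(a, b)


def test_constant_image_lncc_rejected():
    from foliakit.errors import MetricError
    a = Volume(np.ones((8, 8, 8)), make_affine(1.0))
    with pytest.raises(MetricError, match="ssd"):
        register(a, a, RegistrationBackendConfig(metric="lncc"))


# ------------------------------------------------------------ field algebra

def test_compose_identity_is_neutral():
    rng = np.random.default_rng(0)
    aff = make_affine(1.0)
    f = DisplacementField(rng.normal(0, 0.5, (10, 10, 10, 3)), aff)
    ident = DisplacementField.zeros((10, 10, 10), aff)
    got = compose_fields(ident, f)
    np.testing.assert_allclose(got.vectors, f.vectors, atol=1e-9)


def test_compose_translations_add():
    aff = make_affine(1.0)
    t1 = DisplacementField(np.full((8, 8, 8, 3), (1.0, 0.0, 2.0)), aff)
    t2 = DisplacementField(np.full((8, 8, 8, 3), (0.5, -1.0, 0.0)), aff)
    got = compose_fields(t1, t2)
    np.testing.assert_allclose(got.vectors,
                               np.full((8, 8, 8, 3), (1.5, -1.0, 2.0)),
                               atol=1e-9)


def test_compose_matches_sequential_application():
    aff = make_affine(1.0)
    f1 = make_smooth_deformation((16, 16, 16), aff, 1.5, 12.0, rng_seed=1)
    f2 = make_smooth_deformation((16, 16, 16), aff, 1.5, 12.0, rng_seed=2)
    comp = compose_fields(f1, f2)
    rng = np.random.default_rng(3)
    pts = rng.uniform(3, 12, (50, 3))
    seq = f2.apply_to_points(f1.apply_to_points(pts))
    direct = comp.apply_to_points(pts)
    assert np.max(np.linalg.norm(seq - direct, axis=1)) < 0.25


# ------------------------------------------------------------- warp surface

def test_warp_surface_identity_and_translation(small_folded_phantom):
    s = small_folded_phantom
    aff = make_affine(2.0, s.vertices.min(axis=0) - 4)
    shape = tuple(int(np.ceil(p / 2)) + 5 for p in
                  s.vertices.max(axis=0) - s.vertices.min(axis=0))
    ident = DisplacementField.zeros(shape, aff)
    out = warp_surface(s, ident)
    np.testing.assert_allclose(out.vertices, s.vertices, atol=1e-12)
    shift = DisplacementField(np.full(shape + (3,), (2.0, -1.0, 0.5)), aff)
    out = warp_surface(s, shift)
    np.testing.assert_allclose(out.vertices - s.vertices,
                               np.broadcast_to((2.0, -1.0, 0.5),
                                               s.vertices.shape), atol=1e-9)
    np.testing.assert_array_equal(out.faces, s.faces)
    np.testing.assert_array_equal(out.labels, s.labels)


def test_warp_surface_matches_analytic_warp(small_folded_phantom):
    """For f(v) = v + A sin(2 pi v / L), interpolated displacements match the
    analytic map within the trilinear error bound h^2 * max|f''|."""
    s = small_folded_phantom
    A, L, h = 1.5, 30.0, 1.0
    lo = s.vertices.min(axis=0) - 3
    shape = tuple(int(np.ceil((s.vertices.max(axis=0) - lo)[i] / h)) + 6
                  for i in range(3))
    aff = make_affine(h, lo)
    grid = Volume(np.zeros(shape), aff).voxel_centers()
    vec = A * np.sin(2 * np.pi * grid / L)
    field = DisplacementField(vec.reshape(shape + (3,)), aff)
    out = warp_surface(s, field)
    expect = s.vertices + A * np.sin(2 * np.pi * s.vertices / L)
    bound = 3 * h ** 2 * A * (2 * np.pi / L) ** 2  # per-axis curvature bound
    assert np.max(np.abs(out.vertices - expect)) < bound


def test_warp_surface_outside_domain_rejected(small_folded_phantom):
    tiny = DisplacementField.zeros((4, 4, 4), make_affine(1.0, (500, 500, 500)))
    with pytest.raises(DomainError):
        warp_surface(small_folded_phantom, tiny)


# ----------------------------------------------------------- reconstruction

@pytest.fixture(scope="module")
def atlas_setup():
    s = make_folded_phantom(PhantomSpec(mesh_subdivisions=4, n_regions=4))
    cfg = PipelineConfig(voxel_size=2.0, white_matter_label=100)
    vol, surf = run_atlas_volume_pipeline(s, cfg)
    intens = {0: 0.0, 100: 250.0}
    for lab in np.unique(vol.array):
        intens.setdefault(int(lab), 110.0 + 10.0 * int(lab))
    vmri = make_virtual_mri(vol, intens, blur_sigma_mm=1.0)
    return vol, surf, vmri


def test_reconstruct_identity_subject(atlas_setup):
    """Subject identical to the atlas: vertex RMS displacement < 1 voxel."""
    vol, surf, vmri = atlas_setup
    out = arcus_reconstruct(vol, surf, vmri, vol, vmri,
                            subject_mask=vol.array > 0)
    rms = np.sqrt(np.mean(np.sum((out.vertices - surf.vertices) ** 2, axis=1)))
    assert rms < 2.0  # 1 voxel at 2 mm
    np.testing.assert_array_equal(out.faces, surf.faces)
    np.testing.assert_array_equal(out.labels, surf.labels)


def test_reconstruct_recovers_known_deformation(atlas_setup):
    """Subject = atlas warped by a known diffeomorphism: vertices recovered
    within 2 voxel widths RMS and every per-label Dice improves."""
    vol, surf, vmri = atlas_setup
    field = make_smooth_deformation(vol.shape, vol.affine, amplitude_mm=6.0,
                                    wavelength_mm=40.0, rng_seed=5)
    mri, seg, gt = make_subject(vol, vmri, field, noise_sd=5.0, rng_seed=5)
    out, (u1, u2) = arcus_reconstruct(vol, surf, vmri, seg, mri,
                                      subject_mask=seg.array > 0,
                                      return_fields=True)
    gt_verts = warp_surface(surf, gt.invert()).vertices
    rms = np.sqrt(np.mean(np.sum((out.vertices - gt_verts) ** 2, axis=1)))
    assert rms < 2 * 2.0  # 2 voxel widths at 2 mm
    warped_labels = warp_volume(vol, u1, order=0)
    for lab in (1, 2, 3, 4, 100):
        before = dice(vol.array == lab, seg.array == lab)
        after = dice(warped_labels.array == lab, seg.array == lab)
        assert after > before
    assert u1.is_diffeomorphic() and u2.is_diffeomorphic()


def test_reconstruct_label_mismatch_rejected(atlas_setup):
    vol, surf, vmri = atlas_setup
    bad = LabelVolume(np.full(vol.shape, 77, dtype=np.int32), vol.affine)
    with pytest.raises(LabelLookupError, match="77"):
        arcus_reconstruct(vol, surf, vmri, bad, vmri)
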