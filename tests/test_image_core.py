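import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chronact.image_core import (
    Channel,
    DisplacementField,
    LabelVolume,
    ScalarVolume,
    connected_components,
    jacobian_determinant,
    read_volume,
    resample_labels_nn,
    shell_masks,
    write_volume,
)

from conftest import affine_iso


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_read_zero_scalar_roundtrip(tmp_path, unit_affine):
    vol = ScalarVolume(np.zeros((4, 4, 4)), unit_affine, channel=Channel.FLAIR)
    path = tmp_path / "zero.nii.gz"
    write_volume(vol, path)
    back = read_volume(path, kind="scalar")
    assert back.shape == (4, 4, 4)
    assert np.all(back.data == 0)
    assert np.allclose(back.spacing, 1.0)


def test_random_scalar_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    vol = ScalarVolume(rng.normal(size=(5, 6, 7)), affine_iso(2.0))
    path = tmp_path / "rand.nii"
    write_volume(vol, path)
    back = read_volume(path, kind="scalar")
    np.testing.assert_allclose(back.data, vol.data, rtol=1e-12)
    np.testing.assert_allclose(back.affine, vol.affine)


def test_label_roundtrip_label_set(tmp_path, unit_affine):
    labels = np.zeros((4, 4, 4), dtype=np.int16)
    labels[0, 0, 0] = 1
    labels[3, 3, 3] = 2
    write_volume(LabelVolume(labels, unit_affine), tmp_path / "lab.nii.gz")
    back = read_volume(tmp_path / "lab.nii.gz", kind="label")
    # oracle: brute-force unique positive values
    expected = set(int(v) for v in np.unique(labels) if v > 0)
    assert back.label_set == expected == {1, 2}


def test_field_roundtrip(tmp_path, unit_affine):
    rng = np.random.default_rng(1)
    fld = DisplacementField(rng.normal(size=(4, 4, 4, 3)), unit_affine)
    write_volume(fld, tmp_path / "field.nii.gz")
    back = read_volume(tmp_path / "field.nii.gz", kind="field")
    np.testing.assert_allclose(back.vectors, fld.vectors)


def test_read_noninteger_labels_raises(tmp_path, unit_affine):
    vol = ScalarVolume(np.full((3, 3, 3), 0.5), unit_affine)
    write_volume(vol, tmp_path / "bad.nii.gz")
    with pytest.raises(TypeError):
        read_volume(tmp_path / "bad.nii.gz", kind="label")


def test_read_missing_file_raises():
    with pytest.raises(Exception):
        read_volume("/nonexistent/nope.nii.gz")


def test_invariant_validation(unit_affine):
    with pytest.raises(ValueError):
        ScalarVolume(np.full((3, 3, 3), np.nan), unit_affine)
    with pytest.raises(ValueError):
        LabelVolume(np.full((3, 3, 3), -1, dtype=np.int32), unit_affine)
    singular = np.zeros((4, 4))
    with pytest.raises(ValueError):
        ScalarVolume(np.zeros((3, 3, 3)), singular)


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

def test_two_blocks():
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[0:2, 0:2, 0:2] = True
    mask[5:7, 5:7, 5:7] = True
    out = connected_components(mask)
    assert out.label_set == {1, 2}
    assert (out.labels == 1).sum() == 8
    assert (out.labels == 2).sum() == 8


def test_single_corner_voxel():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = True
    out = connected_components(mask)
    assert out.label_set == {1}
    assert (out.labels > 0).sum() == 1


def test_empty_mask_is_not_an_error():
    out = connected_components(np.zeros((3, 3, 3), dtype=bool))
    assert out.label_set == set()


def _bfs_components(mask):
    """Flood-fill oracle with 26-connectivity."""
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_components_match_bfs_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((10, 10, 10)) < 0.2
    out = connected_components(mask)
    got = {
        frozenset(map(tuple, np.argwhere(out.labels == k)))
        for k in out.label_set
    }
    assert got == _bfs_components(mask)


def test_components_sorted_by_decreasing_size():
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask[0, 0, 0] = True  # size 1
    mask[5:8, 5:8, 5:8] = True  # size 27
    out = connected_components(mask)
    assert (out.labels == 1).sum() == 27
    assert (out.labels == 2).sum() == 1


# ---------------------------------------------------------------------------
# nearest-neighbour label resampling
# ---------------------------------------------------------------------------

def test_resample_identity(cube_labels):
    target = ScalarVolume(np.zeros(cube_labels.shape), cube_labels.affine)
    out = resample_labels_nn(cube_labels, target)
    np.testing.assert_array_equal(out.labels, cube_labels.labels)
    # idempotence on identical lattices
    out2 = resample_labels_nn(out, target)
    np.testing.assert_array_equal(out2.labels, out.labels)


def test_resample_2x_upsampling():
    labels = np.zeros((3, 3, 3), dtype=np.int32)
    labels[1, 1, 1] = 7
    src = LabelVolume(labels, affine_iso(2.0))
    target = ScalarVolume(np.zeros((6, 6, 6)), affine_iso(1.0))
    out = resample_labels_nn(src, target)
    assert (out.labels == 7).sum() == 8
    # source centre voxel sits at world (2,2,2); the 8 nearest 1 mm centres
    # are indices {2,3} per axis (ties resolve to the lower index)
    assert (out.labels[2:4, 2:4, 2:4] == 7).all()


def _nearest_centre_oracle(src, target_shape, target_affine):
    src_idx = np.array(
        [(i, j, k) for i in range(src.shape[0])
         for j in range(src.shape[1]) for k in range(src.shape[2])]
    )
    src_world = src_idx @ src.affine[:3, :3].T + src.affine[:3, 3]
    out = np.zeros(target_shape, dtype=np.int32)
    for i in range(target_shape[0]):
        for j in range(target_shape[1]):
            for k in range(target_shape[2]):
                w = target_affine[:3, :3] @ (i, j, k) + target_affine[:3, 3]
                d = np.linalg.norm(src_world - w, axis=1)
                nearest = src_idx[int(np.argmin(d))]
                out[i, j, k] = src.labels[tuple(nearest)]
    return out


def test_resample_matches_nearest_centre_oracle():
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int32)
    # rotation * positive scaling + translation (no shear)
    rot = Rotation.from_euler("xyz", [20, -10, 35], degrees=True).as_matrix()
    src_aff = np.eye(4)
    src_aff[:3, :3] = rot @ np.diag([1.0, 1.3, 0.8])
    src_aff[:3, 3] = [2.0, -1.0, 0.5]
    src = LabelVolume(labels, src_aff)
    # build the target inside the source hull so every nearest centre exists:
    # 5^3 grid spanning source index box [0.3, 4.7] under a rotated lattice
    inner = np.eye(4)
    # tie-free steps/offsets: no target centre lands exactly between sources
    inner[:3, :3] = Rotation.from_euler("y", 15, degrees=True).as_matrix() @ np.diag(
        [1.03, 1.07, 0.97]
    )
    inner[:3, 3] = [0.37, 0.41, 0.43]
    tgt_aff = src_aff @ inner
    target = ScalarVolume(np.zeros((4, 4, 4)), tgt_aff)
    out = resample_labels_nn(src, target)
    np.testing.assert_array_equal(
        out.labels, _nearest_centre_oracle(src, (4, 4, 4), tgt_aff)
    )


def test_resample_never_grows_label_set(cube_labels):
    target = ScalarVolume(np.zeros((20, 20, 20)), affine_iso(0.5))
    out = resample_labels_nn(cube_labels, target)
    assert out.label_set <= cube_labels.label_set


# ---------------------------------------------------------------------------
# Jacobian determinant
# ---------------------------------------------------------------------------

def test_zero_field_jacobian_is_one(unit_affine):
    fld = DisplacementField(np.zeros((5, 5, 5, 3)), unit_affine)
    jac = jacobian_determinant(fld)
    np.testing.assert_allclose(jac.data, 1.0, atol=1e-15)


def test_uniform_scaling_jacobian():
    s = 1.1
    shape = (6, 6, 6)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    u = (s - 1.0) * idx.astype(float)
    jac = jacobian_determinant(DisplacementField(u, affine_iso(1.0)))
    np.testing.assert_allclose(jac.data[1:-1, 1:-1, 1:-1], s**3, atol=1e-12)
    assert np.isclose(s**3, 1.331)


@pytest.mark.parametrize("seed", [0, 1])
def test_affine_field_jacobian_equals_det(seed):
    rng = np.random.default_rng(seed)
    A = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
    spacing = np.array([1.0, 1.2, 0.8])
    shape = (7, 6, 5)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    world = idx * spacing
    u = world @ (A - np.eye(3)).T
    jac = jacobian_determinant(DisplacementField(u, affine_iso(1.0) * np.diag([*spacing, 1])))
    np.testing.assert_allclose(
        jac.data[1:-1, 1:-1, 1:-1], np.linalg.det(A), atol=1e-10
    )


def _gradient_oracle(u, spacing):
    """Entry-by-entry finite differences + per-voxel 3x3 determinants."""
    shape = u.shape[:3]
    J = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                g = np.zeros((3, 3))
                for axis in range(3):
                    idx = [i, j, k]
                    h = spacing[axis]
                    n = shape[axis]
                    pos = idx[axis]
                    lo, hi = list(idx), list(idx)
                    if 0 < pos < n - 1:
                        lo[axis] -= 1
                        hi[axis] += 1
                        denom = 2 * h
                    elif pos == 0:
                        hi[axis] += 1
                        denom = h
                    else:
                        lo[axis] -= 1
                        denom = h
                    for comp in range(3):
                        g[axis, comp] = (
                            u[tuple(hi) + (comp,)] - u[tuple(lo) + (comp,)]
                        ) / denom
                J[i, j, k] = np.linalg.det(np.eye(3) + g)
    return J


def test_jacobian_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    u = 0.3 * rng.normal(size=(5, 5, 5, 3))
    spacing = (1.0, 1.5, 2.0)
    aff = np.diag([*spacing, 1.0])
    jac = jacobian_determinant(DisplacementField(u, aff))
    np.testing.assert_allclose(jac.data, _gradient_oracle(u, spacing), atol=1e-12)


def test_jacobian_requires_three_voxels(unit_affine):
    with pytest.raises(ValueError):
        jacobian_determinant(DisplacementField(np.zeros((2, 5, 5, 3)), unit_affine))


def test_jacobian_integrates_to_volume_ratio():
    """Integral of J over a dilated ball ~ deformed/original volume."""
    from chronact.synthetic_cohort import (
        LesionTruth,
        SimulationConfig,
        radial_expansion_field,
    )

    cfg = SimulationConfig()
    lesion = LesionTruth(
        lesion_id=1,
        center=np.array([20.0, 20.0, 20.0]),
        semi_axes=np.array([5.0, 5.0, 5.0]),
        volume_mm3=float(4 / 3 * np.pi * 125),
        true_sel=True,
        true_prl=False,
        growth_rate_annual=1.04,
        growth_total=1.2,
        rim_coverage=0.0,
    )
    shape = (40, 40, 40)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    grid = idx.astype(float)
    u = radial_expansion_field(grid, lesion, 1.2, cfg)
    jac = jacobian_determinant(DisplacementField(u, affine_iso(1.0)))
    inside = np.linalg.norm(grid - lesion.center, axis=-1) <= 5.0
    ratio = jac.data[inside].mean()  # == integral J / original volume
    assert abs(ratio - 1.2**3) / 1.2**3 < 0.02


# ---------------------------------------------------------------------------
# shell masks
# ---------------------------------------------------------------------------

def test_cube_shell_arithmetic(cube_labels):
    masks = shell_masks(cube_labels, 1, core_erosion=1, ring_dilation=2)
    assert masks.core.sum() == 27  # 3^3
    assert masks.shell.sum() == 125 - 27
    assert not masks.core_empty
    # pairwise disjoint
    assert not (masks.core & masks.shell).any()
    assert not (masks.core & masks.ring).any()
    assert not (masks.shell & masks.ring).any()


def test_single_voxel_lesion_core_empty(unit_affine):
    labels = np.zeros((5, 5, 5), dtype=np.int32)
    labels[2, 2, 2] = 1
    masks = shell_masks(LabelVolume(labels, unit_affine), 1)
    assert masks.core_empty
    assert masks.shell.sum() == 1


def test_missing_lesion_raises(cube_labels):
    with pytest.raises(ValueError):
        shell_masks(cube_labels, 99)


def _morph_oracle(mask, op):
    """One 6-connected erosion/dilation by explicit neighbour checks."""
    out = np.zeros_like(mask)
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            for k in range(mask.shape[2]):
                neigh = []
                for a, b, c in offs:
                    p = (i + a, j + b, k + c)
                    inside = all(0 <= p[d] < mask.shape[d] for d in range(3))
                    neigh.append(mask[p] if inside else False)
                if op == "erode":
                    out[i, j, k] = mask[i, j, k] and all(neigh)
                else:
                    out[i, j, k] = mask[i, j, k] or any(neigh)
    return out


def test_shell_masks_match_morphology_oracle(unit_affine):
    rng = np.random.default_rng(11)
    blob = np.zeros((10, 10, 10), dtype=bool)
    blob[3:8, 3:8, 3:8] = rng.random((5, 5, 5)) < 0.7
    labels = np.where(blob, 1, 0).astype(np.int32)
    masks = shell_masks(LabelVolume(labels, unit_affine), 1, 1, 1)
    core_o = _morph_oracle(blob, "erode")
    ring_o = _morph_oracle(blob, "dilate") & ~blob
    np.testing.assert_array_equal(masks.core, core_o)
    np.testing.assert_array_equal(masks.shell, blob & ~core_o)
    np.testing.assert_array_equal(masks.ring, ring_o)
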