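"""Volume data model, NIfTI I/O, labelling, morphology and Jacobians.

Conventions
-----------
* Voxel indices are 0-based; world coordinates come from the 4x4 affine
  (sform preferred over qform on read).
* Displacement fields are stored on the baseline lattice as millimetre
  3-vectors in a 4-D array with the vector axis last, so the Jacobian
  determinant ``det(I + grad(u))`` is > 1 where tissue expands.
* Gradients use per-axis spacing in mm: central differences at interior
  voxels, one-sided differences on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Literal, Union

import nibabel as nib
import numpy as np
from scipy import ndimage


class Channel(str, Enum):
    FLAIR = "FLAIR"
    T1 = "T1"
    SWI = "SWI"
    OTHER = "OTHER"


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class ScalarVolume:
    """A 3-D intensity grid with voxel spacing and a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    channel: Channel = Channel.OTHER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"scalar volume must be 3-D, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scalar volume contains non-finite values")
        self.affine = _check_affine(self.affine)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer-labelled lesion grid: 0 = background, k > 0 = lesion id."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise TypeError("label volume contains non-integer values")
            labels = np.round(labels).astype(np.int32)
        if labels.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {labels.ndim}-D")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def label_set(self) -> set:
        ids = np.unique(self.labels)
        return set(int(k) for k in ids if k > 0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class DisplacementField:
    """Per-voxel displacement 3-vectors (mm) on the baseline lattice."""

    vectors: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"field must be (X, Y, Z, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple:
        return self.vectors.shape[:3]


Volume = Union[ScalarVolume, LabelVolume, DisplacementField]


def read_volume(
    path: Union[str, Path],
    kind: Literal["scalar", "label", "field"] = "scalar",
    channel: Channel = Channel.OTHER,
) -> Volume:
    """Read a NIfTI-1 file as a scalar volume, label volume or field.

    The affine is taken from the header (nibabel resolves sform/qform
    preference). Field files must hold a 3-component vector per voxel as a
    4-D array with the last axis of length 3.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    if kind == "scalar":
        return ScalarVolume(data=data, affine=affine, channel=channel)
    if kind == "label":
        if not np.issubdtype(data.dtype, np.integer) and not np.allclose(
            data, np.round(data)
        ):
            raise TypeError(f"{path}: label file holds non-integer data")
        return LabelVolume(labels=np.round(data).astype(np.int32), affine=affine)
    if kind == "field":
        if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector dialect
            data = data[:, :, :, 0, :]
        return DisplacementField(vectors=data, affine=affine)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(volume: Volume, path: Union[str, Path]) -> None:
    """Write any volume type to NIfTI-1 (deterministic round-trip)."""
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.int32)
    elif isinstance(volume, DisplacementField):
        data = volume.vectors.astype(np.float64)
    else:
        data = volume.data.astype(np.float64)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_qform(volume.affine, code=1)
    img.header.set_sform(volume.affine, code=1)
    nib.save(img, str(path))


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def connected_components(
    mask: np.ndarray, affine: np.ndarray | None = None
) -> LabelVolume:
    """Label 26-connected components 1..K in decreasing size order."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if affine is None:
        affine = np.eye(4)
    raw, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        return LabelVolume(labels=np.zeros(mask.shape, dtype=np.int32), affine=affine)
    sizes = ndimage.sum_labels(mask, raw, index=np.arange(1, n + 1))
    # stable order: ties broken by first-encountered (raw) label
    order = np.argsort(-sizes, kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1)
    return LabelVolume(labels=remap[raw], affine=affine)


def resample_labels_nn(labels: LabelVolume, target: Volume) -> LabelVolume:
    """Resample labels onto the target lattice by nearest neighbour.

    Each target voxel centre is mapped to continuous source index space and
    rounded per axis. For affines composed of rotation, positive scaling and
    translation (no shear) this is exactly the nearest source voxel centre
    in world coordinates. Targets falling outside the source grid become
    background, so the label set can shrink but never grow.
    """
    src_affine = labels.affine
    tgt_affine = target.affine
    try:
        to_src = np.linalg.inv(src_affine) @ tgt_affine
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in ctor
        raise ValueError("singular affine") from exc

    if np.allclose(src_affine, tgt_affine) and labels.shape == target.shape:
        return LabelVolume(labels=labels.labels.copy(), affine=tgt_affine)

    shape = target.shape[:3] if isinstance(target, DisplacementField) else target.shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    src_idx = idx @ to_src[:3, :3].T + to_src[:3, 3]
    # half-down rounding: exact ties resolve to the lower index, matching an
    # argmin-over-centres oracle (numpy's round-half-even would not)
    src_idx = np.ceil(src_idx - 0.5).astype(np.int64)
    inside = np.all(src_idx >= 0, axis=1) & np.all(
        src_idx < np.array(labels.shape), axis=1
    )
    out = np.zeros(len(idx), dtype=np.int32)
    si = src_idx[inside]
    out[inside] = labels.labels[si[:, 0], si[:, 1], si[:, 2]]
    return LabelVolume(labels=out.reshape(shape), affine=tgt_affine)


def jacobian_determinant(
    field: DisplacementField, smooth_sigma: float = 0.0
) -> ScalarVolume:
    """Jacobian determinant J(x) = det(I + grad u(x)) of a displacement field.

    grad u is taken in world (mm) units using the per-axis spacing;
    ``smooth_sigma`` (mm) optionally Gaussian-smooths the field components
    before differentiation (default: none).
    """
    if min(field.shape) < 3:
        raise ValueError("field must span >= 3 voxels along every axis")
    u = field.vectors
    spacing = field.spacing
    if smooth_sigma > 0:
        sig_vox = smooth_sigma / spacing
        u = np.stack(
            [ndimage.gaussian_filter(u[..., c], sigma=sig_vox) for c in range(3)],
            axis=-1,
        )
    # g[a][b] = d u_b / d x_a, plus identity on the diagonal
    g = [[None] * 3 for _ in range(3)]
    for b in range(3):
        gx, gy, gz = np.gradient(u[..., b], spacing[0], spacing[1], spacing[2])
        g[0][b], g[1][b], g[2][b] = gx, gy, gz
        g[b][b] += 1.0
    det = (
        g[0][0] * (g[1][1] * g[2][2] - g[1][2] * g[2][1])
        - g[0][1] * (g[1][0] * g[2][2] - g[1][2] * g[2][0])
        + g[0][2] * (g[1][0] * g[2][1] - g[1][1] * g[2][0])
    )
    return ScalarVolume(data=det, affine=field.affine, channel=Channel.OTHER)


@dataclass
class ShellMasks:
    """Core / boundary-shell / perilesional-ring decomposition of a lesion."""

    core: np.ndarray
    shell: np.ndarray
    ring: np.ndarray
    core_empty: bool = field(default=False)


def shell_masks(
    labels: LabelVolume,
    lesion_id: int,
    core_erosion: int = 1,
    ring_dilation: int = 2,
) -> ShellMasks:
    """Split one lesion into an eroded core, a boundary shell and an outer ring.

    Morphology uses a 6-connected (face) structuring element, one iteration
    per voxel of erosion/dilation. The ring excludes voxels belonging to any
    lesion. A lesion too small to survive the erosion yields shell = whole
    lesion with ``core_empty`` set (signalled, not fatal).
    """
    lesion = labels.labels == lesion_id
    if not lesion.any():
        raise ValueError(f"lesion id {lesion_id} not present")
    core = ndimage.binary_erosion(lesion, structure=_STRUCT_6, iterations=core_erosion)
    core_empty = not core.any()
    shell = lesion & ~core
    dilated = ndimage.binary_dilation(
        lesion, structure=_STRUCT_6, iterations=ring_dilation
    )
    ring = dilated & ~lesion & (labels.labels == 0)
    return ShellMasks(core=core, shell=shell, ring=ring, core_empty=core_empty)
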