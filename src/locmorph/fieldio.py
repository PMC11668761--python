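"""NIfTI I/O and geometry for deformation-field cohorts.

A deformation (displacement) field stores, for every voxel of a common atlas
grid, a 3-vector in millimetres describing how that location moves between
the atlas and a subject.  Cohorts of such fields, restricted to a brain mask
and vectorized in a fixed feature order, are the raw data for the localized
PCA model.

Conventions
-----------
* Vector fields are stored on disk as 5-D NIfTI-1 images of shape
  ``(X, Y, Z, 1, 3)`` (the ANTs warp dialect); 4-D ``(X, Y, Z, 3)`` images
  are accepted on read and normalized.
* Feature order: masked voxels are enumerated with the x index varying
  fastest (Fortran order over ``(X, Y, Z)``); the three displacement
  components of one voxel are contiguous, so feature ``3*v + a`` is axis
  ``a`` of the ``v``-th masked voxel.  The three features of a voxel share
  one location row.
* Voxel indices are 0-based; world position is ``index * spacing`` unless a
  non-trivial affine is supplied, in which case the affine applies.
* Displacements are in mm.  Warping uses backward trilinear interpolation
  with zero padding outside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage

from .exceptions import FormatError, ShapeError, ValidationError

__all__ = [
    "VectorField",
    "BrainMask",
    "LabelVolume",
    "Cohort",
    "load_vector_field",
    "save_vector_field",
    "load_mask",
    "save_mask",
    "load_label_volume",
    "save_label_volume",
    "assemble_cohort",
    "bounding_box_diagonal",
    "magnitude_map",
    "region_attribution",
    "warp_image",
    "vector_to_field",
]


def _spacing_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VectorField:
    """A 3-D displacement field on a regular grid.

    Attributes
    ----------
    data : ndarray, shape (X, Y, Z, 3)
        Displacement in mm along each world axis.
    spacing : tuple of float
        Voxel size in mm along each axis.
    affine : ndarray (4, 4), optional
        Grid-to-world transform.  ``None`` means ``index * spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ShapeError(
                f"vector field data must have shape (X, Y, Z, 3), got {self.data.shape}"
            )
        if any(d < 1 for d in self.dims):
            raise ValidationError(f"all spatial dims must be >= 1, got {self.dims}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("vector field contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class BrainMask:
    """Boolean mask selecting the voxels that enter the analysis."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ShapeError(f"mask must be 3-D, got shape {self.voxels.shape}")
        if not self.voxels.any():
            raise ValidationError("mask has no true voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class LabelVolume:
    """Integer region labels on the atlas grid; label 0 is background."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    names: dict[int, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ShapeError(f"label volume must be 3-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int32)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    def name_of(self, label: int) -> str:
        return self.names.get(int(label), f"region_{int(label)}")


@dataclass
class Cohort:
    """Vectorized masked deformation fields for n subjects.

    ``X`` has one row per subject and ``p = 3 * mask.n_voxels`` columns;
    ``locations`` gives the mm position of each feature's voxel centre (the
    three features of one voxel share a row value).
    """

    X: np.ndarray
    locations: np.ndarray
    mask: BrainMask
    subject_ids: list[str]
    voxel_index: np.ndarray  # (n_voxels, 3) int voxel triples in feature order

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_index(self) -> list[tuple[tuple[int, int, int], int]]:
        """Feature -> (voxel index triple, axis) in documented order."""
        out = []
        for v in self.voxel_index:
            for axis in range(3):
                out.append(((int(v[0]), int(v[1]), int(v[2])), axis))
        return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_vector_field(path: str | Path) -> VectorField:
    """Read a displacement field from a 5-D (X,Y,Z,1,3) or 4-D (X,Y,Z,3) NIfTI."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1 and data.shape[4] == 3:
        data = data[:, :, :, 0, :]
    elif data.ndim == 4 and data.shape[3] == 3:
        pass
    else:
        raise FormatError(
            f"{path}: expected a 3-component vector image "
            f"(X,Y,Z,1,3) or (X,Y,Z,3), got shape {tuple(data.shape)}"
        )
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: vector field contains non-finite values")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine)
    if np.allclose(affine, _spacing_affine(spacing)):
        affine = None
    return VectorField(data=np.asarray(data, dtype=float), spacing=spacing, affine=affine)


def save_vector_field(field: VectorField, path: str | Path) -> None:
    """Write a displacement field as a 5-D (X,Y,Z,1,3) NIfTI-1 image."""
    data = field.data[:, :, :, np.newaxis, :]
    affine = field.affine if field.affine is not None else _spacing_affine(field.spacing)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(field.spacing + (1.0, 1.0))
    img.header.set_intent("vector")
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"failed to write vector field to {path}: {exc}") from exc


def load_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3-D, got shape {tuple(data.shape)}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BrainMask(voxels=data > 0, spacing=spacing)


def save_mask(mask: BrainMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _spacing_affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_label_volume(path: str | Path, names_tsv: str | Path | None = None) -> LabelVolume:
    """Read an integer label volume; region names from a 2-column TSV sidecar."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: label volume must be 3-D, got shape {tuple(data.shape)}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    names: dict[int, str] = {}
    if names_tsv is not None:
        for line in Path(names_tsv).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{names_tsv}: expected 'label_id<TAB>name', got {line!r}")
            names[int(parts[0])] = parts[1]
    return LabelVolume(labels=np.rint(data).astype(np.int32), spacing=spacing, names=names)


def save_label_volume(atlas: LabelVolume, path: str | Path,
                      names_tsv: str | Path | None = None) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), _spacing_affine(atlas.spacing))
    img.header.set_zooms(atlas.spacing)
    nib.save(img, str(path))
    if names_tsv is not None:
        lines = [f"{lid}\t{name}" for lid, name in sorted(atlas.names.items())]
        Path(names_tsv).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Cohort assembly and geometry
# ---------------------------------------------------------------------------

def _masked_voxel_index(mask: BrainMask) -> np.ndarray:
    """Voxel triples of true mask voxels, x index varying fastest."""
    flat = np.flatnonzero(mask.voxels.ravel(order="F"))
    i, j, k = np.unravel_index(flat, mask.dims, order="F")
    return np.column_stack([i, j, k])


def assemble_cohort(
    fields: Sequence[VectorField],
    mask: BrainMask,
    ids: Sequence[str] | None = None,
) -> Cohort:
    """Vectorize a list of fields over the mask into an n x p data matrix.

    Row ``i`` of ``X`` is subject ``i``'s field restricted to masked voxels in
    the documented feature order (x fastest, 3 components per voxel
    contiguous).
    """
    fields = list(fields)
    if len(fields) < 2:
        raise ValidationError(f"need at least 2 subjects, got {len(fields)}")
    if ids is None:
        ids = [f"sub{i:04d}" for i in range(len(fields))]
    ids = [str(s) for s in ids]
    if len(ids) != len(fields):
        raise ValidationError(
            f"{len(fields)} fields but {len(ids)} subject ids"
        )
    for sid, f in zip(ids, fields):
        if f.dims != mask.dims:
            raise ShapeError(
                f"subject {sid}: field dims {f.dims} != mask dims {mask.dims}"
            )
        if not np.allclose(f.spacing, mask.spacing):
            raise ShapeError(
                f"subject {sid}: field spacing {f.spacing} != mask spacing {mask.spacing}"
            )
    vox = _masked_voxel_index(mask)
    n_vox = vox.shape[0]
    p = 3 * n_vox
    X = np.empty((len(fields), p))
    for r, f in enumerate(fields):
        X[r] = f.data[vox[:, 0], vox[:, 1], vox[:, 2], :].ravel()
    affine = next((f.affine for f in fields if f.affine is not None), None)
    if affine is not None:
        homog = np.column_stack([vox, np.ones(n_vox)])
        vox_mm = (homog @ affine.T)[:, :3]
    else:
        vox_mm = vox * np.asarray(mask.spacing)
    locations = np.repeat(vox_mm, 3, axis=0)
    return Cohort(X=X, locations=locations, mask=mask, subject_ids=ids, voxel_index=vox)


def vector_to_field(vec: np.ndarray, cohort: Cohort) -> VectorField:
    """Reshape a length-p feature vector back onto the atlas grid (zeros outside mask)."""
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != cohort.p:
        raise ShapeError(f"vector length {vec.size} != cohort p {cohort.p}")
    data = np.zeros(cohort.mask.dims + (3,))
    vox = cohort.voxel_index
    data[vox[:, 0], vox[:, 1], vox[:, 2], :] = vec.reshape(-1, 3)
    return VectorField(data=data, spacing=cohort.mask.spacing)


def bounding_box_diagonal(mask: BrainMask) -> float:
    """Diagonal (mm) of the axis-aligned box spanned by true-voxel centres.

    Centre-to-centre convention: a single-voxel mask has diagonal 0.
    """
    idx = np.argwhere(mask.voxels)
    if idx.size == 0:
        raise ValidationError("mask has no true voxels")
    span = (idx.max(axis=0) - idx.min(axis=0)) * np.asarray(mask.spacing)
    return float(np.linalg.norm(span))


def magnitude_map(field: VectorField) -> np.ndarray:
    """Per-voxel Euclidean norm (mm) of the displacement vectors."""
    return np.linalg.norm(field.data, axis=-1)


def region_attribution(
    mag: np.ndarray,
    atlas: LabelVolume,
    stat: str = "mean",
) -> list[tuple[str, float]]:
    """Rank atlas regions by a summary of a magnitude map.

    Returns one ``(region name, value)`` entry per nonzero label present in
    the atlas, sorted descending by the statistic; ties are broken by
    ascending label id.
    """
    mag = np.asarray(mag, dtype=float)
    if mag.shape != atlas.dims:
        raise ShapeError(f"magnitude dims {mag.shape} != atlas dims {atlas.dims}")
    if stat not in ("mean", "max"):
        raise ValidationError(f"stat must be 'mean' or 'max', got {stat!r}")
    labels = np.unique(atlas.labels)
    labels = labels[labels != 0]
    rows = []
    for lid in labels:
        sel = mag[atlas.labels == lid]
        value = float(sel.mean()) if stat == "mean" else float(sel.max())
        rows.append((int(lid), value))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return [(atlas.name_of(lid), value) for lid, value in rows]


def warp_image(image: np.ndarray, field: VectorField) -> np.ndarray:
    """Backward-warp a scalar volume by a displacement field.

    Output voxel ``v`` takes the trilinearly interpolated input value at
    world position ``v * spacing + displacement(v)``; samples outside the
    grid are 0.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != field.dims:
        raise ShapeError(f"image dims {image.shape} != field dims {field.dims}")
    spacing = np.asarray(field.spacing)
    grids = np.meshgrid(*[np.arange(d) for d in field.dims], indexing="ij")
    # pad by one zero voxel so samples just past the boundary blend with 0
    # (plain mode="constant" would snap the whole sample to 0 instead)
    coords = [
        (grids[a] * spacing[a] + field.data[..., a]) / spacing[a] + 1.0
        for a in range(3)
    ]
    padded = np.pad(image, 1, mode="constant")
    return ndimage.map_coordinates(padded, coords, order=1, mode="constant", cval=0.0)
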