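"""NIfTI volume I/O and 2-D time-by-voxel matrix bookkeeping.

Naturalistic fMRI decomposition works on a 2-D real matrix whose rows are
time points and whose columns are in-mask voxels.  This module owns the
conversion between that matrix view and 4-D NIfTI volumes: masked
extraction, per-voxel z-normalization, temporal concatenation across
subjects, and back-projection of spatial vectors (e.g. network maps) into
brain space.

Voxel ordering convention
-------------------------
Columns follow ascending *Fortran-order* linear voxel index within the
mask (first axis fastest-varying).  The convention is arbitrary but fixed:
every function here uses it, and the round trip extract -> back-project is
exact for in-mask voxels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "DegenerateInputError",
    "VolumeSpace",
    "BrainMask",
    "FMRIMatrix",
    "load_masked_timeseries",
    "normalize_timeseries",
    "concatenate_group",
    "map_to_volume",
    "save_matrix_tsv",
    "load_matrix_tsv",
    "save_map_nifti",
]


class GeometryError(ValueError):
    """Shapes, masks or affines of two objects do not agree."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but empty/degenerate (e.g. empty mask)."""


@dataclass(frozen=True)
class VolumeSpace:
    """3-D voxel grid plus the affine mapping voxel indices to world mm."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise GeometryError(f"shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels_total(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class BrainMask:
    """In-mask voxel set: ordered Fortran-style linear indices into a grid."""

    space: VolumeSpace
    voxel_index: np.ndarray  # strictly increasing ints, length V

    def __post_init__(self) -> None:
        idx = np.asarray(self.voxel_index, dtype=np.int64)
        if idx.ndim != 1 or idx.size < 1:
            raise DegenerateInputError("mask contains no voxels")
        if np.any(np.diff(idx) <= 0):
            raise GeometryError("voxel_index must be strictly increasing (unique)")
        if idx[0] < 0 or idx[-1] >= self.space.n_voxels_total:
            raise GeometryError("voxel_index out of grid bounds")
        object.__setattr__(self, "voxel_index", idx)

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_index.size)

    @classmethod
    def from_array(cls, mask_array: np.ndarray, affine: np.ndarray | None = None) -> "BrainMask":
        """Build a mask from a 3-D array; nonzero entries are in-mask."""
        mask_array = np.asarray(mask_array)
        if mask_array.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got ndim={mask_array.ndim}")
        if affine is None:
            affine = np.eye(4)
        flat = np.flatnonzero(mask_array.ravel(order="F") != 0)
        if flat.size == 0:
            raise DegenerateInputError("mask has zero nonzero voxels")
        space = VolumeSpace(shape=mask_array.shape, affine=affine)
        return cls(space=space, voxel_index=flat)

    @classmethod
    def from_nifti(cls, path: str | Path) -> "BrainMask":
        img = nib.load(str(path))
        return cls.from_array(np.asanyarray(img.dataobj), affine=img.affine)

    def to_array(self) -> np.ndarray:
        """Binary 3-D array with ones at in-mask voxels."""
        flat = np.zeros(self.space.n_voxels_total, dtype=np.uint8)
        flat[self.voxel_index] = 1
        return flat.reshape(self.space.shape, order="F")


@dataclass
class FMRIMatrix:
    """A T x V time-by-voxel matrix tied to a mask.

    ``row_offsets`` records per-subject starting rows after group
    concatenation so that the stack can be undone.
    """

    values: np.ndarray  # T x V, float
    mask: BrainMask
    subject_id: str = "subject"
    session_id: str = "A"
    normalized: bool = False
    row_offsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError(f"values must be 2-D, got ndim={self.values.ndim}")
        if self.values.shape[1] != self.mask.n_voxels:
            raise GeometryError(
                f"matrix has {self.values.shape[1]} columns but mask has "
                f"{self.mask.n_voxels} voxels"
            )

    @property
    def n_timepoints(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.values.shape[1])


def load_masked_timeseries(volume_4d_path: str | Path, mask_path: str | Path) -> FMRIMatrix:
    """Extract the in-mask time series of a 4-D NIfTI volume.

    Returns a T x V matrix whose column order follows the mask's voxel
    index order; ``normalized`` is False.
    """
    img = nib.load(str(volume_4d_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise GeometryError(f"expected 4-D volume, got ndim={data.ndim}")
    mask = BrainMask.from_nifti(mask_path)
    if tuple(data.shape[:3]) != mask.space.shape:
        raise GeometryError(
            f"volume grid {data.shape[:3]} does not match mask grid {mask.space.shape}"
        )
    t = data.shape[3]
    flat = data.reshape(-1, t, order="F")  # (X*Y*Z) x T in Fortran order
    values = flat[mask.voxel_index].T.astype(float)  # T x V
    return FMRIMatrix(values=values, mask=mask, subject_id=Path(volume_4d_path).stem)


def normalize_timeseries(m: FMRIMatrix) -> FMRIMatrix:
    """Z-normalize every voxel's time series to zero mean, unit variance.

    Constant (zero-variance) columns cannot be normalized; they are set to
    all-zero and logged — real brain masks routinely contain flat voxels.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    x = m.values - m.values.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=0)
    flat_cols = sd <= 0
    n_flat = int(flat_cols.sum())
    if n_flat:
        logger.warning("normalize_timeseries: %d constant voxel(s) set to zero", n_flat)
    sd_safe = np.where(flat_cols, 1.0, sd)
    x = x / sd_safe
    x[:, flat_cols] = 0.0
    return replace(m, values=x, normalized=True)


def concatenate_group(subjects: list[FMRIMatrix]) -> FMRIMatrix:
    """Stack subjects' time series along time into one group matrix.

    All subjects must share the identical mask and be normalized.  The
    result records each subject's (start, stop) row range so individual
    blocks can be recovered.
    """
    if not subjects:
        raise DegenerateInputError("no subjects to concatenate")
    ref = subjects[0]
    offsets: dict[str, tuple[int, int]] = {}
    row = 0
    for s in subjects:
        if not np.array_equal(s.mask.voxel_index, ref.mask.voxel_index) or (
            s.mask.space.shape != ref.mask.space.shape
        ):
            raise GeometryError(f"subject {s.subject_id!r} mask differs from group mask")
        if not s.normalized:
            raise ValueError(f"subject {s.subject_id!r} is not normalized")
        offsets[s.subject_id] = (row, row + s.n_timepoints)
        row += s.n_timepoints
    values = np.vstack([s.values for s in subjects])
    return FMRIMatrix(
        values=values,
        mask=ref.mask,
        subject_id="group",
        session_id=ref.session_id,
        normalized=True,
        row_offsets=offsets,
    )


def map_to_volume(spatial_vector: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Back-project a length-V spatial vector to a 3-D volume.

    Out-of-mask voxels are zero; in-mask voxel ``j`` receives element ``j``.
    """
    vec = np.asarray(spatial_vector, dtype=float).ravel()
    if vec.size != mask.n_voxels:
        raise GeometryError(f"vector length {vec.size} != mask voxel count {mask.n_voxels}")
    flat = np.zeros(mask.space.n_voxels_total, dtype=float)
    flat[mask.voxel_index] = vec
    return flat.reshape(mask.space.shape, order="F")


def save_map_nifti(spatial_vector: np.ndarray, mask: BrainMask, path: str | Path) -> None:
    """Write a spatial vector as a NIfTI volume in the mask's space."""
    vol = map_to_volume(spatial_vector, mask)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), mask.space.affine), str(path))


# --- plain-text interchange for synthetic runs -------------------------------

def save_matrix_tsv(m: FMRIMatrix, path: str | Path) -> None:
    """Dump a matrix as TSV with a one-line JSON sidecar (``<path>.json``)."""
    path = Path(path)
    np.savetxt(path, m.values, delimiter="\t", fmt="%.10g")
    meta = {
        "T": m.n_timepoints,
        "V": m.n_voxels,
        "subject_id": m.subject_id,
        "session_id": m.session_id,
        "normalized": m.normalized,
        "shape": list(m.mask.space.shape),
        "voxel_index": m.mask.voxel_index.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_matrix_tsv(path: str | Path) -> FMRIMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    mask = BrainMask(
        space=VolumeSpace(shape=tuple(meta["shape"]), affine=np.eye(4)),
        voxel_index=np.asarray(meta["voxel_index"], dtype=np.int64),
    )
    return FMRIMatrix(
        values=values,
        mask=mask,
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        normalized=bool(meta["normalized"]),
    )
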