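"""Volumetric mask I/O and the package-wide coordinate conventions.

Every 3D array in airtree is indexed ``(z, y, x)`` with

* axis 0 — z, superior → inferior (slice 0 is the most superior),
* axis 1 — y, anterior → posterior,
* axis 2 — x, patient-right → patient-left.

A voxel is a point sample at its centre; its physical position in mm is
``index * spacing`` along each axis, and its volume is the product of the
spacings.  NIfTI volumes of any orientation are normalised to this
convention on load (equivalent to nibabel axis codes ``('I', 'P', 'L')``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import orientations as _ornt
from scipy import ndimage

from .errors import (
    EmptyMaskError,
    GridMismatchError,
    InvalidLabelError,
    MissingColumnError,
    Not3DError,
    NonBinaryError,
)

AXIS_CONVENTION = "zyx:IPL"
_TARGET_AXCODES = ("I", "P", "L")

#: structuring element for 26-connectivity in 3D
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """Shape and spacing of a regular voxel grid.

    Parameters
    ----------
    shape
        ``(nz, ny, nx)`` array shape.
    spacing
        ``(sz, sy, sx)`` voxel spacing in mm.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    convention: str = AXIS_CONVENTION

    def __post_init__(self):
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("grid shape and spacing must be triples")
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def coords_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return np.arange(self.shape[axis]) * self.spacing[axis]


@dataclasses.dataclass
class BinaryMask:
    """A boolean occupancy volume on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    voxels: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise GridMismatchError(
                f"voxel array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.grid.voxel_volume_mm3

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0


def same_grid(*masks, rtol: float = 1e-5) -> VoxelGrid:
    """Assert that all masks/volumes share one grid and return it.

    Spacings are compared with a small relative tolerance because NIfTI
    affines are stored in float32.
    """
    ref = masks[0].grid
    for m in masks[1:]:
        if m.grid.shape != ref.shape or not np.allclose(
            m.grid.spacing, ref.spacing, rtol=rtol, atol=0
        ):
            raise GridMismatchError(
                f"masks do not share a grid: {m.grid} vs {ref}"
            )
    return ref


def canonical_affine(grid: VoxelGrid) -> np.ndarray:
    """RAS affine encoding the package ``(z, y, x) = (I, P, L)`` convention."""
    sz, sy, sx = grid.spacing
    aff = np.zeros((4, 4))
    aff[0, 2] = -sx  # x index increases toward patient-left => RAS x decreases
    aff[1, 1] = -sy  # y index increases toward posterior => RAS y decreases
    aff[2, 0] = -sz  # z index increases toward inferior => RAS z decreases
    aff[3, 3] = 1.0
    return aff


def _load_canonical(path) -> tuple[np.ndarray, VoxelGrid, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise Not3DError(f"{path}: not a 3D mask (got {data.ndim}D, shape {data.shape})")
    src_ornt = _ornt.io_orientation(img.affine)
    transform = _ornt.ornt_transform(src_ornt, _ornt.axcodes2ornt(_TARGET_AXCODES))
    data = _ornt.apply_orientation(data, transform)
    zooms = nib.affines.voxel_sizes(img.affine)[:3]
    spacing = [0.0, 0.0, 0.0]
    for in_axis in range(3):
        out_axis = int(transform[in_axis, 0])
        spacing[out_axis] = float(zooms[in_axis])
    grid = VoxelGrid(shape=data.shape, spacing=tuple(spacing))
    meta = {
        "source_path": str(path),
        "source_affine": img.affine.tolist(),
        "source_axcodes": "".join(_ornt.ornt2axcodes(src_ornt)),
    }
    return data, grid, meta


def read_mask(path, binary_tol: float = 0.2) -> BinaryMask:
    """Read a NIfTI binary mask, normalising orientation.

    Values must be near 0 or 1 (within ``binary_tol``); the mask is then
    thresholded at 0.5.  Raises :class:`Not3DError` for non-3D volumes and
    :class:`NonBinaryError` for volumes with intermediate values.
    """
    data, grid, meta = _load_canonical(path)
    data = np.asarray(data, dtype=np.float64)
    off = np.minimum(np.abs(data), np.abs(data - 1.0))
    worst = float(off.max()) if data.size else 0.0
    if worst > binary_tol:
        raise NonBinaryError(
            f"{path}: volume is not binary (value {worst:.3g} away from 0/1)"
        )
    return BinaryMask(grid=grid, voxels=data > 0.5, meta=meta)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit NIfTI in the canonical orientation."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), canonical_affine(mask.grid))
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def read_labels(path):
    """Read an integer label volume (codes 0..4); see :func:`write_labels`."""
    from .decomposition import LABEL_NAMES, SegmentLabelVolume

    data, grid, meta = _load_canonical(path)
    labels = np.rint(np.asarray(data, dtype=np.float64)).astype(np.int16)
    if labels.min() < 0 or labels.max() >= len(LABEL_NAMES):
        raise InvalidLabelError(
            f"{path}: label codes outside 0..{len(LABEL_NAMES) - 1}"
        )
    return SegmentLabelVolume(grid=grid, labels=labels)


def write_labels(labels, path) -> None:
    """Write a :class:`~airtree.decomposition.SegmentLabelVolume` to NIfTI.

    Codes: 0 background, 1 trachea, 2 medium, 3 small, 4 terminal.
    Round-tripping through :func:`read_labels` is bit-exact.
    """
    from .decomposition import LABEL_NAMES

    arr = np.asarray(labels.labels)
    if arr.min() < 0 or arr.max() >= len(LABEL_NAMES):
        raise InvalidLabelError(
            f"label codes outside 0..{len(LABEL_NAMES) - 1}: "
            f"range [{arr.min()}, {arr.max()}]"
        )
    img = nib.Nifti1Image(arr.astype(np.int16), canonical_affine(labels.grid))
    img.header.set_zooms(labels.grid.spacing)
    nib.save(img, str(path))


def largest_component(mask: BinaryMask) -> tuple[np.ndarray, int]:
    """Largest 26-connected component of a mask.

    Returns the component as a boolean array plus the number of foreground
    voxels discarded (those in smaller components).
    """
    if mask.count == 0:
        raise EmptyMaskError("mask has no foreground voxels")
    lab, n = ndimage.label(mask.voxels, structure=STRUCT_26)
    if n == 1:
        return mask.voxels.copy(), 0
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    comp = lab == keep
    return comp, int(mask.count - comp.sum())


REQUIRED_COHORT_COLUMNS = ("id", "time", "event")


def read_cohort(path):
    """Read a survival cohort CSV into a :class:`~airtree.survival.Cohort`.

    Requires columns ``id``, ``time`` (years, > 0) and ``event`` (0/1);
    any further columns are treated as covariates.  Rows with missing or
    invalid required fields are dropped and counted.
    """
    from .survival import Cohort

    df = pd.read_csv(path)
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"{path}: cohort table lacks column '{col}'")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    ok = (
        df["id"].notna()
        & df["time"].notna()
        & (df["time"] > 0)
        & df["event"].isin([0, 1])
    )
    n_rejected = int((~ok).sum())
    clean = df.loc[ok].reset_index(drop=True)
    clean["event"] = clean["event"].astype(int)
    return Cohort(frame=clean, n_rejected=n_rejected)
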