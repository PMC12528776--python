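"""Projection-and-distance airway branch decomposition.

Pipeline: locate the trachea and carina on the largest 26-connected
airway component; split the lung mask into left/right; project the
bronchial (non-trachea) airway along z; compute per-lung max-normalised
radial distance maps in the axial plane and a normalised vertical depth
below the carina; threshold the distances into medium / small / terminal
classes; back-project the 2D classes onto every voxel of each axial
column; optionally promote voxels by the vertical-depth constraint.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, NoCarinaError
from .grid import BinaryMask, VoxelGrid, largest_component, same_grid

logger = logging.getLogger(__name__)

BACKGROUND, TRACHEA, MEDIUM, SMALL, TERMINAL = 0, 1, 2, 3, 4
LABEL_NAMES = {
    BACKGROUND: "background",
    TRACHEA: "trachea",
    MEDIUM: "medium",
    SMALL: "small",
    TERMINAL: "terminal",
}

_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity within a slice


@dataclasses.dataclass(frozen=True)
class DecompositionConfig:
    """Tunable parameters of the decomposition.

    ``t_terminal`` / ``t_small`` are the normalised-distance cuts for the
    terminal and small classes; ``carina_persistence`` is the number of
    consecutive split slices required to accept a carina; ``threshold_mode``
    applies the cuts to the normalised distance itself or to its empirical
    quantile rank within each lung; ``revision`` enables the vertical-max
    promotion constraint.
    """

    t_terminal: float = 0.55
    t_small: float = 0.25
    carina_persistence: int = 3
    threshold_mode: str = "normalised"  # or "rank"
    revision: str = "vertical-max"  # or "off"
    min_trachea_area_mm2: float = 10.0

    def __post_init__(self):
        if not (0.0 < self.t_small < self.t_terminal < 1.0):
            raise ValueError(
                f"need 0 < t_small < t_terminal < 1, got "
                f"({self.t_small}, {self.t_terminal})"
            )
        if self.carina_persistence < 1:
            raise ValueError("carina_persistence must be >= 1")
        if self.threshold_mode not in ("normalised", "rank"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.revision not in ("vertical-max", "off"):
            raise ValueError(f"unknown revision mode {self.revision!r}")


@dataclasses.dataclass
class SegmentLabelVolume:
    """Per-voxel label in {background, trachea, medium, small, terminal}."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid")

    def class_counts(self) -> dict[str, int]:
        out = {}
        for code, name in LABEL_NAMES.items():
            if code == BACKGROUND:
                continue
            out[name] = int((self.labels == code).sum())
        return out

    def class_volumes_ml(self) -> dict[str, float]:
        vv = self.grid.voxel_volume_mm3 / 1000.0
        return {k: v * vv for k, v in self.class_counts().items()}


@dataclasses.dataclass
class TracheaResult:
    trachea: np.ndarray  # bool volume
    component: np.ndarray  # largest airway component, bool volume
    carina_slice: int  # first stable-split slice index
    carina_mm: np.ndarray  # (z, y, x) mm of the last single-section centroid
    discarded_voxels: int


@dataclasses.dataclass
class LungSplit:
    left: np.ndarray
    right: np.ndarray
    mode: str  # "components" or "plane"


@dataclasses.dataclass
class DistanceFields:
    """2D projections plus the normalised distance and depth fields."""

    p_z: np.ndarray  # (ny, nx) bool, bronchial axial projection
    p_y: np.ndarray  # (nz, nx) bool, bronchial frontal projection
    side: np.ndarray  # (ny, nx) int8: 0 none, 1 left, 2 right
    d: np.ndarray  # (ny, nx) float, max-normalised radial distance (NaN off-airway)
    centers_mm: dict  # {"left": (y, x) mm or None, "right": ...}
    max_dist_mm: dict  # {"left": float, "right": float}
    carina_mm: np.ndarray
    height_mm: float
    h: np.ndarray  # (nz,) normalised vertical depth below the carina per slice


def project(mask: np.ndarray, axis: str) -> np.ndarray:
    """Binary max projection: ``axis='z'`` -> (ny, nx), ``axis='y'`` -> (nz, nx)."""
    ax = {"z": 0, "y": 1}[axis]
    return np.asarray(mask, dtype=bool).any(axis=ax)


def locate_trachea(
    airway: BinaryMask, config: DecompositionConfig = DecompositionConfig()
) -> TracheaResult:
    """Find the trachea and carina by slicewise split persistence.

    Scanning the largest component from the most superior slice downward,
    the carina slice is the first whose in-plane cross-section splits into
    >= 2 pieces and stays split for ``carina_persistence`` consecutive
    slices; the trachea is everything strictly above it.
    """
    comp, discarded = largest_component(airway)
    zs = np.flatnonzero(comp.any(axis=(1, 2)))
    z_top = int(zs[0])
    sz, sy, sx = airway.grid.spacing
    top_area = comp[z_top].sum() * sy * sx
    if top_area < config.min_trachea_area_mm2:
        raise NoCarinaError(
            f"topmost cross-section area {top_area:.1f} mm2 below the "
            f"minimum {config.min_trachea_area_mm2} mm2"
        )

    def n_sections(z: int) -> int:
        if not comp[z].any():
            return 0
        return ndimage.label(comp[z], structure=_STRUCT_2D)[1]

    counts = {z: n_sections(z) for z in range(z_top, int(zs[-1]) + 1)}
    carina_slice = None
    for z in range(z_top, int(zs[-1]) + 1):
        window = [counts.get(z + k, 0) for k in range(config.carina_persistence)]
        if all(c >= 2 for c in window):
            carina_slice = z
            break
    if carina_slice is None:
        raise NoCarinaError("airway component never splits below the trachea")

    # centroid of the last single-section cross-section above the split
    z_single = None
    for z in range(carina_slice - 1, z_top - 1, -1):
        if counts.get(z, 0) == 1:
            z_single = z
            break
    if z_single is None:
        raise NoCarinaError("no single-section slice above the split")
    jy, ix = np.argwhere(comp[z_single]).mean(axis=0)
    carina_mm = np.array([z_single * sz, jy * sy, ix * sx])

    trachea = np.zeros_like(comp)
    trachea[:carina_slice] = comp[:carina_slice]
    return TracheaResult(
        trachea=trachea,
        component=comp,
        carina_slice=carina_slice,
        carina_mm=carina_mm,
        discarded_voxels=discarded,
    )


def split_lungs(
    lung: BinaryMask, carina_mm: np.ndarray, large_fraction: float = 0.2
) -> LungSplit:
    """Split the lung mask into left and right halves.

    If the mask has exactly two 26-connected components each holding at
    least ``large_fraction`` of the lung volume they are assigned by
    centroid x (x increases toward patient-left); otherwise the mask is
    cut by the sagittal plane through the carina x coordinate.
    """
    if lung.count == 0:
        raise EmptyMaskError("lung mask is empty")
    lab, n = ndimage.label(lung.voxels, structure=np.ones((3, 3, 3), dtype=bool))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    big = [i + 1 for i, s in enumerate(sizes) if s >= large_fraction * lung.count]
    if len(big) == 2:
        cent = ndimage.center_of_mass(lung.voxels, lab, index=big)
        order = np.argsort([c[2] for c in cent])  # ascending x: right first
        right = lab == big[order[0]]
        left = lab == big[order[1]]
        return LungSplit(left=left, right=right, mode="components")
    sx = lung.grid.spacing[2]
    x_mm = np.arange(lung.grid.shape[2]) * sx
    left_cols = x_mm >= carina_mm[2]
    left = lung.voxels & left_cols[None, None, :]
    right = lung.voxels & ~left_cols[None, None, :]
    return LungSplit(left=left, right=right, mode="plane")


def compute_distance_fields(
    airway: BinaryMask,
    trachea: TracheaResult,
    lungs: LungSplit,
    config: DecompositionConfig = DecompositionConfig(),
) -> DistanceFields:
    """Per-lung max-normalised axial distance maps and vertical depth."""
    grid = airway.grid
    sz, sy, sx = grid.spacing
    bronchial = trachea.component & ~trachea.trachea
    if not bronchial.any():
        raise EmptyMaskError("no bronchial voxels below the carina")
    p_z = project(bronchial, "z")
    p_y = project(bronchial, "y")

    left_proj = project(lungs.left, "z")
    right_proj = project(lungs.right, "z")
    side = np.zeros(p_z.shape, dtype=np.int8)
    jj, ii = np.nonzero(p_z)
    x_mm = ii * sx
    for k, (j, i) in enumerate(zip(jj, ii)):
        in_l, in_r = left_proj[j, i], right_proj[j, i]
        if in_l and not in_r:
            side[j, i] = 1
        elif in_r and not in_l:
            side[j, i] = 2
        else:
            side[j, i] = 1 if x_mm[k] >= trachea.carina_mm[2] else 2

    d = np.full(p_z.shape, np.nan)
    centers: dict[str, tuple | None] = {"left": None, "right": None}
    max_dist: dict[str, float] = {"left": 0.0, "right": 0.0}
    for name, code in (("left", 1), ("right", 2)):
        jjs, iis = np.nonzero(side == code)
        if len(jjs) == 0:
            warnings.warn(f"{name} lung contains no airway pixels", stacklevel=2)
            continue
        y_mm = jjs * sy
        x_mm_s = iis * sx
        cy, cx = float(y_mm.mean()), float(x_mm_s.mean())
        centers[name] = (cy, cx)
        dist = np.hypot(y_mm - cy, x_mm_s - cx)
        m = float(dist.max())
        max_dist[name] = m
        d[jjs, iis] = dist / m if m > 0 else 0.0

    z_mm = np.arange(grid.shape[0]) * sz
    depth = z_mm - trachea.carina_mm[0]
    voxel_z = np.flatnonzero(bronchial.any(axis=(1, 2)))
    height = float(depth[voxel_z].max())
    if height <= 0:
        height = sz  # degenerate: all bronchial voxels at the carina slice
    h = np.clip(depth / height, 0.0, 1.0)
    return DistanceFields(
        p_z=p_z,
        p_y=p_y,
        side=side,
        d=d,
        centers_mm=centers,
        max_dist_mm=max_dist,
        carina_mm=trachea.carina_mm,
        height_mm=height,
        h=h,
    )


def _classify_value(values: np.ndarray, config: DecompositionConfig) -> np.ndarray:
    out = np.full(values.shape, MEDIUM, dtype=np.int16)
    out[values >= config.t_small] = SMALL
    out[values >= config.t_terminal] = TERMINAL
    return out


def _rank_percentile(values: np.ndarray) -> np.ndarray:
    """Empirical quantile rank in [0, 1]: (rank - 1) / (n - 1), average ties."""
    from scipy.stats import rankdata

    n = len(values)
    if n <= 1:
        return np.zeros(n)
    return (rankdata(values, method="average") - 1.0) / (n - 1.0)


def classify_preliminary(
    fields: DistanceFields, config: DecompositionConfig = DecompositionConfig()
) -> np.ndarray:
    """Per-pixel class over P_Z (int16 2D array, BACKGROUND off-airway).

    Cut points are closed on the left: ``D >= t_terminal`` is terminal,
    ``t_small <= D < t_terminal`` small, ``D < t_small`` medium.
    """
    classes = np.zeros(fields.p_z.shape, dtype=np.int16)
    for code in (1, 2):
        jjs, iis = np.nonzero(fields.side == code)
        if len(jjs) == 0:
            continue
        v = fields.d[jjs, iis]
        if config.threshold_mode == "rank":
            v = _rank_percentile(v)
        classes[jjs, iis] = _classify_value(v, config)
    return classes


def back_project(
    classes2d: np.ndarray, trachea: TracheaResult, grid: VoxelGrid
) -> SegmentLabelVolume:
    """Lift the 2D axial classes onto every voxel of each column."""
    labels = np.zeros(grid.shape, dtype=np.int16)
    bronchial = trachea.component & ~trachea.trachea
    labels[bronchial] = np.broadcast_to(classes2d[None, :, :], grid.shape)[bronchial]
    labels[trachea.trachea] = TRACHEA
    return SegmentLabelVolume(grid=grid, labels=labels)


def revise_labels(
    preliminary: SegmentLabelVolume,
    fields: DistanceFields,
    config: DecompositionConfig = DecompositionConfig(),
) -> SegmentLabelVolume:
    """Vertical-depth promotion constraint.

    In ``vertical-max`` mode each bronchial voxel is rescored with
    ``S = max(D of its axial column, H of its slice)`` and reclassified by
    the same cuts; only promotions toward more distal classes can occur.
    In ``off`` mode the labels pass through unchanged.
    """
    if config.revision == "off":
        return SegmentLabelVolume(grid=preliminary.grid, labels=preliminary.labels.copy())
    labels = preliminary.labels.copy()
    bronchial = labels >= MEDIUM
    kk, jj, ii = np.nonzero(bronchial)
    s = np.maximum(fields.d[jj, ii], fields.h[kk])
    revised = _classify_value(s, config)
    labels[kk, jj, ii] = np.maximum(labels[kk, jj, ii], revised)
    return SegmentLabelVolume(grid=preliminary.grid, labels=labels)


@dataclasses.dataclass
class DecompositionResult:
    labels: SegmentLabelVolume
    fields: DistanceFields
    trachea: TracheaResult
    lungs: LungSplit
    report: dict


def decompose(
    airway: BinaryMask,
    lung: BinaryMask,
    config: DecompositionConfig = DecompositionConfig(),
) -> DecompositionResult:
    """Full decomposition of an airway mask into labelled segments."""
    same_grid(airway, lung)
    trachea = locate_trachea(airway, config)
    lungs = split_lungs(lung, trachea.carina_mm)
    fields = compute_distance_fields(airway, trachea, lungs, config)
    classes2d = classify_preliminary(fields, config)
    preliminary = back_project(classes2d, trachea, airway.grid)
    final = revise_labels(preliminary, fields, config)
    report = {
        "carina_slice": int(trachea.carina_slice),
        "carina_mm": [float(v) for v in trachea.carina_mm],
        "centers_mm": {
            k: (list(map(float, v)) if v is not None else None)
            for k, v in fields.centers_mm.items()
        },
        "tree_height_mm": float(fields.height_mm),
        "lung_split_mode": lungs.mode,
        "discarded_voxels": int(trachea.discarded_voxels),
        "class_counts": final.class_counts(),
        "class_volumes_ml": final.class_volumes_ml(),
    }
    logger.info("decompose: %s", report)
    return DecompositionResult(
        labels=final, fields=fields, trachea=trachea, lungs=lungs, report=report
    )
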