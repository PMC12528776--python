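"""Synthetic airway-tree phantoms with ground-truth generation labels.

The phantom is a dichotomous tree of tapering capsules (cylinders with
hemispherical caps) embedded in a two-lobe lung mask.  Every branch
carries its generation index (trachea = 0, main bronchi = 1, ...), which
is rasterised into a ground-truth label volume so the decomposition and
morphometry layers can be validated without any real imaging data.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import PhantomGeometryError
from .grid import BinaryMask, VoxelGrid


@dataclasses.dataclass(frozen=True)
class TreeSpec:
    """Parameters of a dichotomous tapering airway tree.

    Lengths and radii shrink geometrically with generation; children tilt
    away from the parent direction by ``half_angle_deg`` about an azimuth
    axis that changes each generation, with a mild downward bias so distal
    generations keep descending (as bronchi do).
    """

    n_generations: int = 5
    trachea_length_mm: float = 28.0
    trachea_radius_mm: float = 4.5
    length_ratio: float = 0.78
    radius_ratio: float = 0.75
    half_angle_deg: float = 35.0
    azimuth_rule: str = "alternating"  # or "rotating"
    descent_bias: float = 0.25
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self):
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (0 < self.length_ratio <= 1 and 0 < self.radius_ratio <= 1):
            raise ValueError("length/radius ratios must lie in (0, 1]")
        if not (0 < self.half_angle_deg < 90):
            raise ValueError("branching half-angle must lie in (0, 90) degrees")
        if not (0 <= self.jitter < 1):
            raise ValueError("jitter fraction must lie in [0, 1)")
        if self.azimuth_rule not in ("alternating", "rotating"):
            raise ValueError(f"unknown azimuth rule {self.azimuth_rule!r}")


@dataclasses.dataclass
class Branch:
    """One edge of the phantom tree, in mm (z, y, x) coordinates."""

    id: int
    parent: int  # -1 for the trachea
    generation: int
    p0: np.ndarray
    p1: np.ndarray
    radius_mm: float

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def direction(self) -> np.ndarray:
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)


@dataclasses.dataclass
class AirwayTreePhantom:
    """Centerline tree with radii and generations plus its target grid."""

    spec: TreeSpec
    grid: VoxelGrid
    branches: list[Branch]

    @property
    def n_generations(self) -> int:
        return max(b.generation for b in self.branches)

    def children_of(self, branch_id: int) -> list[Branch]:
        return [b for b in self.branches if b.parent == branch_id]

    @property
    def root(self) -> Branch:
        roots = [b for b in self.branches if b.parent == -1]
        assert len(roots) == 1
        return roots[0]


def default_grid(size: int = 128, spacing: float = 1.0) -> VoxelGrid:
    return VoxelGrid(shape=(size, size, size), spacing=(spacing,) * 3)


def _perp_axis(direction: np.ndarray, generation: int, rule: str) -> np.ndarray:
    """Unit vector perpendicular to ``direction`` selecting the split plane."""
    # alternating: odd generations split in the x (coronal) sense, even in y;
    # rotating: reference axis rotates 90 deg per generation in the xy plane.
    if rule == "alternating":
        ref = np.array([0.0, 0.0, 1.0]) if generation % 2 == 1 else np.array([0.0, 1.0, 0.0])
    else:
        ang = np.pi / 2 * generation
        ref = np.array([0.0, np.sin(ang), np.cos(ang)])
    perp = ref - np.dot(ref, direction) * direction
    n = np.linalg.norm(perp)
    if n < 1e-9:  # direction parallel to ref; fall back to the other axis
        ref = np.array([0.0, 1.0, 0.0]) if abs(ref[2]) > 0.5 else np.array([0.0, 0.0, 1.0])
        perp = ref - np.dot(ref, direction) * direction
        n = np.linalg.norm(perp)
    return perp / n


def generate_tree(spec: TreeSpec, grid: VoxelGrid | None = None) -> AirwayTreePhantom:
    """Grow a deterministic dichotomous tree inside ``grid``.

    Raises :class:`PhantomGeometryError` naming the first branch whose
    capsule would leave the grid.
    """
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(spec.seed)
    ez, ey, ex = np.eye(3)
    extent = np.array(grid.extent_mm)
    # integer voxel centre: half-voxel-symmetric tubes defeat 3D thinning.
    # The trachea starts at z = 0 so its superior cap is clipped by the grid,
    # like a real scan cut at the top of the field of view.
    root_start = np.array([
        0.0,
        ((grid.shape[1] - 1) // 2) * grid.spacing[1],
        ((grid.shape[2] - 1) // 2) * grid.spacing[2],
    ])

    min_spacing = min(grid.spacing)
    clamped = False
    branches: list[Branch] = []

    def check_bounds(b: Branch) -> None:
        for p in (b.p0, b.p1):
            lo = (p - b.radius_mm).copy()
            hi = p + b.radius_mm
            if b.generation == 0 and p is b.p0:
                lo[0] = max(lo[0], 0.0)  # superior trachea cap may be clipped
            if np.any(lo < -0.5 * min_spacing) or np.any(hi > extent - 0.5 * min_spacing):
                raise PhantomGeometryError(
                    f"branch {b.id} (generation {b.generation}) leaves the grid: "
                    f"endpoint {p.round(2).tolist()} mm, radius {b.radius_mm:.2f} mm, "
                    f"grid extent {extent.tolist()} mm"
                )

    def jittered(value: float) -> float:
        if spec.jitter == 0:
            return value
        return value * (1.0 + rng.uniform(-spec.jitter, spec.jitter))

    # trachea straight down
    trachea = Branch(
        id=0, parent=-1, generation=0,
        p0=root_start,
        p1=root_start + ez * jittered(spec.trachea_length_mm),
        radius_mm=max(spec.trachea_radius_mm, min_spacing),
    )
    check_bounds(trachea)
    branches.append(trachea)

    frontier = [trachea]
    next_id = 1
    theta0 = np.deg2rad(spec.half_angle_deg)
    for gen in range(1, spec.n_generations + 1):
        length = spec.trachea_length_mm * spec.length_ratio**gen
        radius = spec.trachea_radius_mm * spec.radius_ratio**gen
        if radius < min_spacing:
            radius = min_spacing
            clamped = True
        new_frontier = []
        for parent in frontier:
            d = parent.direction
            u = _perp_axis(d, gen, spec.azimuth_rule)
            for sign in (+1.0, -1.0):
                theta = jittered(theta0) if spec.jitter else theta0
                child_dir = np.cos(theta) * d + sign * np.sin(theta) * u
                # downward bias keeps distal generations descending
                child_dir = child_dir + spec.descent_bias * ez
                child_dir /= np.linalg.norm(child_dir)
                child = Branch(
                    id=next_id, parent=parent.id, generation=gen,
                    p0=parent.p1.copy(),
                    p1=parent.p1 + child_dir * jittered(length),
                    radius_mm=radius,
                )
                check_bounds(child)
                branches.append(child)
                new_frontier.append(child)
                next_id += 1
        frontier = new_frontier

    if clamped:
        warnings.warn(
            "phantom radii fell below one voxel spacing and were clamped",
            stacklevel=2,
        )
    return AirwayTreePhantom(spec=spec, grid=grid, branches=branches)


def _segment_distance_field(grid, p0, p1, radius, pad_mm):
    """Distances from voxel centres in the capsule bounding box to segment.

    Returns (zslice, yslice, xslice, dist) restricted to the bounding box.
    """
    lo = np.minimum(p0, p1) - radius - pad_mm
    hi = np.maximum(p0, p1) + radius + pad_mm
    idx_lo = np.maximum(np.floor(lo / np.array(grid.spacing)).astype(int), 0)
    idx_hi = np.minimum(
        np.ceil(hi / np.array(grid.spacing)).astype(int) + 1, np.array(grid.shape)
    )
    if np.any(idx_hi <= idx_lo):
        return None
    slices = tuple(slice(int(a), int(b)) for a, b in zip(idx_lo, idx_hi))
    axes = [
        np.arange(s.start, s.stop) * grid.spacing[i] for i, s in enumerate(slices)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = p1 - p0
    L2 = float(np.dot(d, d))
    if L2 == 0:
        dist = np.sqrt((zz - p0[0]) ** 2 + (yy - p0[1]) ** 2 + (xx - p0[2]) ** 2)
        return slices, dist
    t = ((zz - p0[0]) * d[0] + (yy - p0[1]) * d[1] + (xx - p0[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    cz = p0[0] + t * d[0]
    cy = p0[1] + t * d[1]
    cx = p0[2] + t * d[2]
    dist = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    return slices, dist


def rasterize_tree(
    phantom: AirwayTreePhantom, grid: VoxelGrid | None = None
) -> tuple[BinaryMask, np.ndarray]:
    """Paint the tree into a binary mask plus generation ground truth.

    Each branch is a capsule of its radius.  The ground-truth volume holds
    ``generation + 1`` (0 = background); a voxel covered by several
    capsules takes the generation of the nearest centerline segment, ties
    broken toward the higher generation.
    """
    if grid is None:
        grid = phantom.grid
    min_spacing = min(grid.spacing)
    best = np.full(grid.shape, np.inf, dtype=np.float32)
    truth = np.zeros(grid.shape, dtype=np.int16)
    clamped = False
    for b in sorted(phantom.branches, key=lambda b: b.generation):
        r = b.radius_mm
        if r < min_spacing:
            r = min_spacing
            clamped = True
        out = _segment_distance_field(grid, b.p0, b.p1, r, pad_mm=min_spacing)
        if out is None:
            continue
        slices, dist = out
        covered = dist <= r
        # iterating in ascending generation, '<=' lets higher generations win ties
        win = covered & (dist <= best[slices])
        best[slices][win] = dist[win].astype(np.float32)
        sub = truth[slices]
        sub[win] = b.generation + 1
        truth[slices] = sub
    if clamped:
        warnings.warn("branch radii below one voxel spacing were clamped during "
                      "rasterisation", stacklevel=2)
    mask = BinaryMask(grid=grid, voxels=truth > 0)
    return mask, truth


def rasterize_tube(
    points_mm: np.ndarray, radius_mm: float, grid: VoxelGrid
) -> BinaryMask:
    """Rasterise a polyline tube (chain of capsules) — curved-branch helper."""
    points_mm = np.asarray(points_mm, dtype=float)
    min_spacing = min(grid.spacing)
    r = max(radius_mm, min_spacing)
    vox = np.zeros(grid.shape, dtype=bool)
    for p0, p1 in zip(points_mm[:-1], points_mm[1:]):
        out = _segment_distance_field(grid, p0, p1, r, pad_mm=min_spacing)
        if out is None:
            continue
        slices, dist = out
        vox[slices] |= dist <= r
    return BinaryMask(grid=grid, voxels=vox)


def _sample_branch_points(branch: Branch, step_mm: float = 1.0) -> np.ndarray:
    n = max(int(np.ceil(branch.length_mm / step_mm)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return branch.p0[None, :] * (1 - t) + branch.p1[None, :] * t


def generate_lung_mask(
    grid: VoxelGrid, phantom: AirwayTreePhantom, margin_mm: float = 8.0,
    gap_half_mm: float = 3.0,
) -> BinaryMask:
    """Two-lobe lung mask covering all bronchial (generation >= 1) voxels.

    Built as two lateral ellipsoids (split by a mediastinal gap at the
    trachea's x position) unioned with the bronchial capsules inflated by
    ``margin_mm``, which guarantees the clearance constraint; the trachea
    itself may lie in the gap.
    """
    bronchial = [b for b in phantom.branches if b.generation >= 1]
    if not bronchial:
        raise PhantomGeometryError("phantom has no bronchial branches (generation >= 1)")
    cx = phantom.root.p0[2]
    r_max = max(b.radius_mm for b in bronchial)

    pts = np.concatenate([_sample_branch_points(b) for b in bronchial], axis=0)
    sides = {"right": pts[pts[:, 2] <= cx], "left": pts[pts[:, 2] >= cx]}

    zz = grid.coords_mm(0)[:, None, None]
    yy = grid.coords_mm(1)[None, :, None]
    xx = grid.coords_mm(2)[None, None, :]
    vox = np.zeros(grid.shape, dtype=bool)
    for name, sp in sides.items():
        if len(sp) == 0:
            continue
        lo, hi = sp.min(axis=0), sp.max(axis=0)
        centre = (lo + hi) / 2
        semi = (hi - lo) / 2 + margin_mm + r_max + 2.0
        semi = np.maximum(semi, margin_mm + r_max + 2.0)
        ell = (
            ((zz - centre[0]) / semi[0]) ** 2
            + ((yy - centre[1]) / semi[1]) ** 2
            + ((xx - centre[2]) / semi[2]) ** 2
        ) <= 1.0
        if name == "right":
            ell &= xx[0, 0, :] < cx - gap_half_mm
        else:
            ell &= xx[0, 0, :] > cx + gap_half_mm
        vox |= ell

    # inflated bronchial capsules guarantee coverage with >= margin clearance
    min_spacing = min(grid.spacing)
    for b in bronchial:
        out = _segment_distance_field(
            grid, b.p0, b.p1, b.radius_mm + margin_mm, pad_mm=min_spacing
        )
        if out is None:
            continue
        slices, dist = out
        vox[slices] |= dist <= max(b.radius_mm, min_spacing) + margin_mm
    return BinaryMask(grid=grid, voxels=vox)


def add_honeycomb_clutter(
    lung: BinaryMask,
    airway: BinaryMask,
    n_cysts: int = 30,
    cyst_radius_mm: float = 3.0,
    seed: int = 0,
) -> BinaryMask:
    """Spherical cysts in the peripheral lung rind, disjoint from the airway.

    Returns the clutter alone; union it into the airway mask to build a
    corrupted segmentation for robustness probes.
    """
    from scipy import ndimage

    grid = lung.grid
    out = np.zeros(grid.shape, dtype=bool)
    if n_cysts == 0:
        return BinaryMask(grid=grid, voxels=out)
    rng = np.random.default_rng(seed)
    min_spacing = min(grid.spacing)
    rind_depth = max(int(round(2 * cyst_radius_mm / min_spacing)), 2)
    interior = ndimage.binary_erosion(lung.voxels, iterations=rind_depth)
    rind = lung.voxels & ~interior
    # distance to the airway (mm); candidate centres must keep clear of it
    dist_to_airway = ndimage.distance_transform_edt(
        ~airway.voxels, sampling=grid.spacing
    )
    clearance = cyst_radius_mm + 2.0 * min_spacing
    candidates = np.argwhere(rind & (dist_to_airway > clearance))
    if len(candidates) == 0:
        warnings.warn("no room for honeycomb clutter in the lung rind", stacklevel=2)
        return BinaryMask(grid=grid, voxels=out)
    picks = candidates[rng.choice(len(candidates), size=min(n_cysts, len(candidates)),
                                  replace=False)]
    for centre_idx in picks:
        centre = centre_idx * np.array(grid.spacing)
        out_field = _segment_distance_field(
            grid, centre, centre, cyst_radius_mm, pad_mm=min_spacing
        )
        if out_field is None:
            continue
        slices, dist = out_field
        out[slices] |= dist <= cyst_radius_mm
    out &= ~airway.voxels
    return BinaryMask(grid=grid, voxels=out)


def generation_voxel_counts(truth: np.ndarray) -> dict[int, int]:
    """Voxel count per ground-truth generation (key = generation index)."""
    vals, counts = np.unique(truth[truth > 0], return_counts=True)
    return {int(v) - 1: int(c) for v, c in zip(vals, counts)}
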