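"""Skeleton-based branch graph and morphometric metrics.

The airway mask is thinned to a one-voxel skeleton, condensed into a
branch graph rooted at the most superior endpoint (the trachea top), and
each branch is measured: arc length, tortuosity (arc / chord), angle to
its parent and sibling angle.  Branches are also classed medium / small /
terminal by their generation percentage along root-to-leaf paths (cuts at
40% and 70%).
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import EmptyMaskError
from .grid import STRUCT_26, BinaryMask, VoxelGrid, largest_component

#: generation-percentage cuts (closed on the left)
GEN_PCT_TERMINAL = 70.0
GEN_PCT_SMALL = 40.0

#: centerline samples used for direction vectors at branch ends
DIRECTION_POINTS = 5

_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


@dataclasses.dataclass
class BranchRecord:
    """One branch: ordered centerline (mm) plus derived metrics."""

    id: int
    parent: int  # -1 for the root branch
    generation: int
    points_mm: np.ndarray  # (n, 3) proximal -> distal
    children: list[int] = dataclasses.field(default_factory=list)
    length_mm: float = np.nan
    tortuosity: float = np.nan
    angle_to_parent_deg: float = np.nan
    sibling_angle_deg: float = np.nan
    gen_percent: float = np.nan
    cls: str = ""


@dataclasses.dataclass
class AirwayGraph:
    """Rooted branch decomposition of a skeleton."""

    grid: VoxelGrid
    branches: dict[int, BranchRecord]
    root: int

    @property
    def max_generation(self) -> int:
        return max(b.generation for b in self.branches.values())

    def leaves(self) -> list[int]:
        return [i for i, b in self.branches.items() if not b.children]


def skeletonize_airway(airway: BinaryMask) -> np.ndarray:
    """One-voxel-wide 26-connected skeleton of the largest component."""
    comp, _ = largest_component(airway)
    return skeletonize(comp).astype(bool)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    counts = ndimage.convolve(
        skel.astype(np.uint8), STRUCT_26.astype(np.uint8), mode="constant"
    )
    return np.where(skel, counts - 1, 0)


def build_graph(skeleton: np.ndarray, grid: VoxelGrid, prune_mm: float = 2.0) -> AirwayGraph:
    """Condense a voxel skeleton into a rooted branch graph.

    Junction voxels (>= 3 skeleton neighbours) are clustered into nodes;
    paths of degree-2 voxels between nodes become branches.  The root is
    the most superior endpoint.  Cycles are broken by dropping the longest
    edge of each cycle (minimum-spanning selection); leaf branches shorter
    than ``prune_mm`` are pruned as thinning spurs.
    """
    if not skeleton.any():
        raise EmptyMaskError("skeleton is empty")
    spacing = np.array(grid.spacing)
    deg = _neighbor_counts(skeleton)
    junction = skeleton & (deg >= 3)
    endpoint = skeleton & (deg <= 1)

    node_id = np.full(skeleton.shape, -1, dtype=np.int32)
    jlab, njunc = ndimage.label(junction, structure=STRUCT_26)
    node_id[junction] = jlab[junction] - 1
    next_node = njunc
    ep_coords = np.argwhere(endpoint)
    for c in ep_coords:
        node_id[tuple(c)] = next_node
        next_node += 1
    node_voxels: dict[int, list] = {}
    for c in np.argwhere(node_id >= 0):
        node_voxels.setdefault(int(node_id[tuple(c)]), []).append(tuple(c))

    skel_set = set(map(tuple, np.argwhere(skeleton)))

    def neighbors(v):
        for off in _OFFSETS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in skel_set:
                yield w

    visited_mid = set()
    raw_edges = []  # (node_a, node_b, voxel path)
    seen_pairs = set()
    for nid, voxels in node_voxels.items():
        for start in voxels:
            for nb in neighbors(start):
                if node_id[nb] >= 0:
                    other = int(node_id[nb])
                    if other != nid:
                        key = (min(nid, other), max(nid, other), start, nb)
                        rkey = (min(nid, other), max(nid, other), nb, start)
                        if rkey in seen_pairs or key in seen_pairs:
                            continue
                        seen_pairs.add(key)
                        raw_edges.append((nid, other, [start, nb]))
                    continue
                if nb in visited_mid:
                    continue
                path = [start, nb]
                visited_mid.add(nb)
                prev, cur = start, nb
                while True:
                    cand = [w for w in neighbors(cur) if w != prev]
                    # stop at the first node voxel reached (not the start
                    # cluster, unless the path loops back to it)
                    hits = [
                        w for w in cand
                        if node_id[w] >= 0
                        and (int(node_id[w]) != nid or len(path) > 3)
                    ]
                    if hits:
                        step = hits[0]
                        path.append(step)
                        raw_edges.append((nid, int(node_id[step]), path))
                        break
                    mids = [w for w in cand if node_id[w] < 0 and w not in visited_mid]
                    if not mids:
                        break  # dead end; drop the fragment
                    step = mids[0]
                    visited_mid.add(step)
                    path.append(step)
                    prev, cur = cur, step
    # graph over nodes, possibly with parallel edges/cycles
    g = nx.Graph()
    for nid in node_voxels:
        g.add_node(nid)
    for a, b, path in raw_edges:
        length = _polyline_length(np.array(path) * spacing)
        if g.has_edge(a, b):
            if length >= g.edges[a, b]["length"]:
                continue  # keep the shorter parallel edge
        g.add_edge(a, b, length=length, path=path)
    if g.number_of_edges() >= g.number_of_nodes():
        warnings.warn("skeleton contains cycles; breaking at longest edges",
                      stacklevel=2)
        g = nx.minimum_spanning_tree(g, weight="length")

    # root: node containing the most superior endpoint voxel
    if len(ep_coords):
        top = ep_coords[np.argmin(ep_coords[:, 0])]
        root_node = int(node_id[tuple(top)])
    else:
        root_node = 0

    branches: dict[int, BranchRecord] = {}
    next_branch = 0
    stack = [(root_node, -1, 0)]  # (node, parent branch id, generation)
    seen_nodes = {root_node}
    while stack:
        node, parent_branch, gen = stack.pop()
        for _, other, data in g.edges(node, data=True):
            if other in seen_nodes:
                continue
            seen_nodes.add(other)
            path = data["path"]
            if tuple(path[0]) not in {tuple(v) for v in node_voxels[node]}:
                path = path[::-1]
            rec = BranchRecord(
                id=next_branch,
                parent=parent_branch,
                generation=gen,
                points_mm=np.asarray(path, dtype=float) * spacing,
            )
            branches[rec.id] = rec
            if parent_branch >= 0:
                branches[parent_branch].children.append(rec.id)
            stack.append((other, rec.id, gen + 1))
            next_branch += 1

    graph = AirwayGraph(grid=grid, branches=branches, root=0)
    _prune_spurs(graph, prune_mm)
    compute_branch_metrics(graph)
    return graph


def _polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _prune_spurs(graph: AirwayGraph, prune_mm: float) -> None:
    """Remove leaf branches shorter than ``prune_mm`` (thinning artifacts)."""
    changed = True
    while changed:
        changed = False
        for bid in list(graph.branches):
            b = graph.branches.get(bid)
            if b is None or b.children or b.parent < 0:
                continue
            parent = graph.branches[b.parent]
            # only prune a spur if its parent keeps >= 1 other child
            if _polyline_length(b.points_mm) < prune_mm and len(parent.children) >= 2:
                parent.children.remove(bid)
                del graph.branches[bid]
                changed = True
    # merge pass-through chains created by pruning (node left with one child)
    merged = True
    while merged:
        merged = False
        for bid in list(graph.branches):
            b = graph.branches.get(bid)
            if b is None or len(b.children) != 1:
                continue
            child = graph.branches[b.children[0]]
            b.points_mm = np.vstack([b.points_mm, child.points_mm[1:]])
            b.children = child.children
            for gc in b.children:
                graph.branches[gc].parent = bid
            del graph.branches[child.id]
            merged = True
    _reindex_generations(graph)


def _reindex_generations(graph: AirwayGraph) -> None:
    roots = [b for b in graph.branches.values() if b.parent < 0]
    stack = [(r.id, 0) for r in roots]
    while stack:
        bid, gen = stack.pop()
        graph.branches[bid].generation = gen
        for c in graph.branches[bid].children:
            stack.append((c, gen + 1))


def _smooth(points: np.ndarray, window: int = 5) -> np.ndarray:
    if len(points) <= 2 or window <= 1:
        return points
    out = ndimage.uniform_filter1d(points, size=window, axis=0, mode="nearest")
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def _direction(points: np.ndarray, k: int = DIRECTION_POINTS, end: str = "start") -> np.ndarray:
    if len(points) < 2:
        return np.zeros(3)
    if len(points) < k:
        warnings.warn("branch shorter than the direction window; using all points",
                      stacklevel=2)
        k = len(points)
    seg = points[:k] if end == "start" else points[-k:]
    d = seg[-1] - seg[0]
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.zeros(3)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def compute_branch_metrics(graph: AirwayGraph) -> None:
    """Fill length, tortuosity, angles and generation-percentage classes."""
    # max generation reachable through each branch (root-to-leaf path maximum)
    subtree_max: dict[int, int] = {}

    def walk(bid: int) -> int:
        b = graph.branches[bid]
        m = b.generation if not b.children else max(walk(c) for c in b.children)
        subtree_max[bid] = m
        return m

    for b in graph.branches.values():
        if b.parent < 0:
            walk(b.id)

    for b in graph.branches.values():
        sm = _smooth(b.points_mm)
        arc = _polyline_length(sm)
        chord = float(np.linalg.norm(sm[-1] - sm[0]))
        b.length_mm = _polyline_length(b.points_mm)
        b.tortuosity = arc / chord if chord > 0 else np.nan
        if b.parent >= 0:
            pdir = _direction(_smooth(graph.branches[b.parent].points_mm), end="end")
            b.angle_to_parent_deg = _angle_deg(pdir, _direction(sm, end="start"))
            siblings = [c for c in graph.branches[b.parent].children if c != b.id]
            if siblings:
                sdir = _direction(_smooth(graph.branches[siblings[0]].points_mm),
                                  end="start")
                b.sibling_angle_deg = _angle_deg(_direction(sm, end="start"), sdir)
        denom = max(subtree_max[b.id], 1)
        b.gen_percent = 100.0 * b.generation / denom
        if b.gen_percent >= GEN_PCT_TERMINAL:
            b.cls = "terminal"
        elif b.gen_percent >= GEN_PCT_SMALL:
            b.cls = "small"
        else:
            b.cls = "medium"


def generation_percent_classes(graph: AirwayGraph) -> dict[int, str]:
    """Branch id -> class under the 70/40 generation-percentage cuts."""
    return {bid: b.cls for bid, b in graph.branches.items()}


def analyze_airway(airway: BinaryMask, prune_mm: float = 2.0) -> AirwayGraph:
    """Mask -> skeleton -> measured branch graph."""
    skel = skeletonize_airway(airway)
    return build_graph(skel, airway.grid, prune_mm=prune_mm)


def branch_table(graph: AirwayGraph):
    """Branch metrics as a pandas DataFrame (one row per branch)."""
    import pandas as pd

    rows = []
    for b in sorted(graph.branches.values(), key=lambda b: b.id):
        rows.append(
            {
                "id": b.id,
                "parent": b.parent,
                "generation": b.generation,
                "class": b.cls,
                "gen_percent": b.gen_percent,
                "length_mm": b.length_mm,
                "tortuosity": b.tortuosity,
                "angle_to_parent_deg": b.angle_to_parent_deg,
                "sibling_angle_deg": b.sibling_angle_deg,
            }
        )
    return pd.DataFrame(rows)
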