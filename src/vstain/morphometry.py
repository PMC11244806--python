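"""Morphometry of tubular networks: segmentation, skeleton graphs, radii,
branch lengths, and profiles along the lobule (CV-PV) axis.

The pipeline quantifies predicted or experimental bile-canaliculi channels:
an intensity volume is thresholded (Otsu by default), reduced to a medial
skeleton, converted to a graph whose branches are maximal paths between
junctions/endpoints, and annotated with local radii from the Euclidean
distance transform of the mask.  All lengths are reported in µm using the
(possibly anisotropic) voxel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .training import otsu_threshold

_NEIGHBOR_OFFSETS = [off for off in product((-1, 0, 1), repeat=3) if any(off)]


@dataclass
class Branch:
    path: np.ndarray          # (n, 3) voxel coordinates along the branch
    length_um: float          # arc length with anisotropic voxel size
    endpoints: tuple          # the two node voxels


@dataclass
class NetworkGraph:
    """Skeleton graph: junction/endpoint nodes and polyline branches."""

    nodes: list[tuple[int, int, int]]
    branches: list[Branch]
    skeleton_coords: np.ndarray            # (n, 3) all skeleton voxels
    radii_um: np.ndarray                   # per skeleton voxel, µm
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def n_junctions(self) -> int:
        return sum(1 for n in self.nodes if self._degree(n) > 2)

    def _degree(self, node) -> int:
        return sum(1 for b in self.branches if node in b.endpoints)


# --------------------------------------------------------------- operations
def segment_network(channel: np.ndarray, method: str = "otsu",
                    threshold: float | None = None,
                    largest_component: bool = False) -> np.ndarray:
    """Binary mask of the network, by Otsu or a fixed threshold.

    Otsu makes the segmentation invariant to affine intensity rescaling.
    An all-background result is allowed (with a warning).
    """
    channel = np.asarray(channel)
    if method == "otsu":
        if channel.max() <= channel.min():
            warnings.warn("constant channel: empty segmentation mask")
            return np.zeros(channel.shape, dtype=bool)
        thr = otsu_threshold(channel)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask = channel > thr
    if not mask.any():
        warnings.warn("segmentation produced an empty mask")
        return mask
    if largest_component:
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _branch_arc_length(path: np.ndarray, voxel_size) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.diff(path.astype(float), axis=0) * np.asarray(voxel_size)
    return float(np.linalg.norm(steps, axis=1).sum())


def skeletonize_network(mask: np.ndarray,
                        voxel_size=(1.0, 1.0, 1.0)) -> NetworkGraph:
    """Medial-axis skeleton reduced to a branch graph.

    Skeleton voxels with exactly two 26-neighbours are chain interior points;
    all others are nodes (endpoints or junctions).  Branches are maximal
    chains between nodes; an isolated cycle is reported as one closed branch.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3D mask")
    if not mask.any():
        return NetworkGraph([], [], np.empty((0, 3), int), np.empty(0), tuple(voxel_size))
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    voxel_set = set(map(tuple, coords))
    neigh = {
        v: [tuple(np.add(v, off)) for off in _NEIGHBOR_OFFSETS
            if tuple(np.add(v, off)) in voxel_set]
        for v in voxel_set
    }
    nodes = [v for v, nb in neigh.items() if len(nb) != 2]
    node_set = set(nodes)

    branches: list[Branch] = []
    visited_edges = set()

    def walk(start, first):
        """Follow a chain from a node through degree-2 voxels to the next node."""
        path = [start, first]
        prev, cur = start, first
        while cur not in node_set:
            nxt = [n for n in neigh[cur] if n != prev]
            if not nxt:
                break  # dead end inside a chain (shouldn't happen, degree-2 rule)
            # prefer continuing away from where we came from
            prev, cur = cur, nxt[0]
            path.append(cur)
        return path

    for node in nodes:
        for first in neigh[node]:
            edge_key = frozenset((node, first))
            if edge_key in visited_edges:
                continue
            path = walk(node, first)
            for a, b in zip(path[:-1], path[1:]):
                visited_edges.add(frozenset((a, b)))
            arr = np.asarray(path)
            branches.append(Branch(arr, _branch_arc_length(arr, voxel_size),
                                   (path[0], path[-1])))

    # isolated cycles: chains never touching a node
    covered = set()
    for b in branches:
        covered.update(map(tuple, b.path))
    remaining = voxel_set - covered
    while remaining:
        start = next(iter(remaining))
        cycle = [start]
        prev, cur = None, start
        while True:
            nxt = [n for n in neigh[cur] if n != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            if cur == start:
                cycle.append(cur)
                break
            cycle.append(cur)
        arr = np.asarray(cycle)
        branches.append(Branch(arr, _branch_arc_length(arr, voxel_size),
                               (cycle[0], cycle[-1])))
        remaining -= set(map(tuple, cycle))

    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    radii = edt[tuple(coords.T)]
    return NetworkGraph([tuple(n) for n in nodes], branches, coords, radii,
                        tuple(voxel_size))


def prune_spurs(graph: NetworkGraph, min_length_um: float = 2.0) -> NetworkGraph:
    """Drop terminal branches (one endpoint of degree 1) shorter than the cutoff."""
    endpoint_count: dict[tuple, int] = {}
    for b in graph.branches:
        for e in b.endpoints:
            endpoint_count[e] = endpoint_count.get(e, 0) + 1
    kept = [b for b in graph.branches
            if b.length_um >= min_length_um
            or (endpoint_count[b.endpoints[0]] > 1 and endpoint_count[b.endpoints[1]] > 1)]
    return NetworkGraph(graph.nodes, kept, graph.skeleton_coords, graph.radii_um,
                        graph.voxel_size)


def radius_stats(mask: np.ndarray, graph: NetworkGraph) -> dict:
    """Radius distribution sampled on the skeleton and its mean (µm).

    The local radius is the Euclidean distance transform of the mask at each
    skeleton voxel, i.e. the distance to the nearest background voxel.
    """
    if graph.skeleton_coords.shape[0] == 0:
        raise ValueError("empty network graph")
    radii = graph.radii_um
    hist, edges = np.histogram(radii, bins=32)
    return {
        "radii_um": radii,
        "mean_radius_um": float(radii.mean()),
        "histogram": (hist, edges),
    }


def branch_length_stats(graph: NetworkGraph, prune_below_um: float = 0.0) -> dict:
    """Mean branch arc length (µm), optionally after spur pruning."""
    if graph.n_branches == 0:
        raise ValueError("empty network graph")
    g = prune_spurs(graph, prune_below_um) if prune_below_um > 0 else graph
    if g.n_branches == 0:
        raise ValueError("all branches pruned")
    lengths = np.array([b.length_um for b in g.branches])
    return {"lengths_um": lengths, "mean_branch_length_um": float(lengths.mean()),
            "n_branches": int(len(lengths))}


# ------------------------------------------------------------- axis profiles
@dataclass
class AxisProfile:
    """Binned mean/sd of a quantity along the normalized CV-PV coordinate."""

    bin_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray       # NaN for bins with < 2 samples
    counts: np.ndarray


def profile_along_axis(quantity_samples: np.ndarray, positions_um: np.ndarray,
                       axis_origin_um, axis_direction, axis_length_um: float,
                       n_bins: int = 10) -> AxisProfile:
    """Project samples onto the lobule axis, normalize to [0, 1], and bin.

    ``positions_um`` are (n, 3) sample coordinates in µm; the axis is a unit
    direction from an origin with a finite length (e.g. the CV-to-PV span).
    Empty bins report NaN mean and zero count; a single-sample bin has no sd.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    q = np.asarray(quantity_samples, dtype=float)
    pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
    if len(q) != len(pos):
        raise ValueError("samples and positions differ in length")
    direction = np.asarray(axis_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = (pos - np.asarray(axis_origin_um, dtype=float)) @ direction / axis_length_um
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b] > 0:
            mean[b] = q[sel].mean()
        if counts[b] > 1:
            sd[b] = q[sel].std(ddof=1)
    return AxisProfile(centers, mean, sd, counts)


def quantify_network(channel: np.ndarray, voxel_size=(1.0, 1.0, 1.0),
                     prune_below_um: float = 2.0) -> dict:
    """One-call morphometry: segment, skeletonize, radii and branch lengths."""
    mask = segment_network(channel)
    if not mask.any():
        raise ValueError("no network segmented from the channel")
    graph = skeletonize_network(mask, voxel_size)
    out = {"mask": mask, "graph": graph}
    out.update(radius_stats(mask, graph))
    out.update(branch_length_stats(graph, prune_below_um))
    return out
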