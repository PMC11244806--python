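"""Synthetic 3D liver-phantom volumes with known geometry.

The phantom emulates the channel set of the imaging experiments at desk scale:

* ``membrane``  — bright shells on the borders of a space-filling cell
  tessellation (the cortical actin mesh a small-molecule stain reveals);
* ``bc``        — a connected network of thin tubes running along cell–cell
  interfaces (bile canaliculi);
* ``sinusoid``  — thicker smooth tubes crossing the volume roughly along the
  lobule axis (sinusoidal capillaries);
* ``kupffer``   — sparse star-shaped blobs (Kupffer-cell macrophages).

All geometry is recorded as ground truth so downstream modules (training,
inference, metrics, morphometry) can be validated against known structure.
Arrays are indexed ``(z, y, x)``, 0-based, with z the depth from the imaged
surface; every operation is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi, QhullError

import networkx as nx

CHANNEL_NAMES = ("membrane", "bc", "sinusoid", "kupffer")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and corruption parameters of a synthetic liver volume.

    Lengths are in µm.  The defaults describe a desk-scale tissue block of
    192 µm per side at 1 µm isotropic voxels; hepatocyte-scale cells
    (~22 µm), thin bile-canaliculi tubes, sinusoids of a few µm radius, and
    an antibody-penetration knee at 80 µm depth.
    """

    shape: tuple[int, int, int] = (192, 192, 192)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_cells: int = 220
    cell_diameter: float = 22.0
    bc_radius: float = 1.5
    sinusoid_radius: float = 4.0
    kupffer_count: int = 10
    attenuation_depth: float = 80.0
    attenuation_width: float = 10.0
    noise_gaussian_sd: float = 0.02
    noise_poisson_scale: float = 50.0
    seed: int = 0
    n_sinusoids: int = 5
    bc_extra_edge_fraction: float = 0.3
    #: optional (start, end) radius in µm, linear along the lobule axis;
    #: overrides ``bc_radius`` when set (used to emulate zonated geometry)
    bc_radius_axis_range: tuple[float, float] | None = None

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive voxel counts (z, y, x)")
        for name in ("cell_diameter", "bc_radius", "sinusoid_radius",
                     "attenuation_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be > 0")
        z_extent = self.shape[0] * self.voxel_size[0]
        if self.attenuation_depth > z_extent:
            raise ValueError(
                f"attenuation_depth {self.attenuation_depth} µm exceeds the z extent "
                f"{z_extent} µm")
        if self.n_cells < 1 or self.kupffer_count < 0:
            raise ValueError("n_cells must be >= 1 and kupffer_count >= 0")


@dataclass
class PhantomTruth:
    """Ground-truth geometry of a generated phantom (voxel coordinates)."""

    cell_label_map: np.ndarray
    bc_centerlines: list[tuple[np.ndarray, np.ndarray]]  # (points Nx3, radii N, µm)
    sinusoid_centerlines: list[tuple[np.ndarray, np.ndarray]]
    kupffer_centroids: np.ndarray
    lobule_axis: dict  # {"origin": µm point, "direction": unit vector, "length": µm}

    def __post_init__(self):
        d = np.asarray(self.lobule_axis["direction"], dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise ValueError("lobule_axis direction must be a unit vector")


@dataclass
class PhantomVolume:
    channels: dict[str, np.ndarray]
    truth: PhantomTruth
    config: PhantomConfig

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]


# ------------------------------------------------------------------ geometry
def _poisson_disc_seeds(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Blue-noise cell centers by dart throwing with a minimum-distance rule."""
    shape = np.asarray(cfg.shape, dtype=float)
    vs = np.asarray(cfg.voxel_size, dtype=float)
    if any(shape * vs < cfg.cell_diameter):
        raise ValueError(
            f"volume extent {tuple(shape * vs)} µm too small to host one cell of "
            f"diameter {cfg.cell_diameter} µm")
    min_dist_vox = cfg.cell_diameter / vs  # per-axis, anisotropy-aware
    seeds: list[np.ndarray] = []
    attempts = 0
    max_attempts = cfg.n_cells * 60
    while len(seeds) < cfg.n_cells and attempts < max_attempts:
        attempts += 1
        cand = rng.uniform(0, shape)
        if all(np.linalg.norm((cand - s) / min_dist_vox) >= 0.85 for s in seeds):
            seeds.append(cand)
    return np.array(seeds)


def _label_map_from_seeds(shape, seeds, voxel_size) -> np.ndarray:
    """Nearest-seed (Voronoi) labels via the Euclidean feature transform."""
    marker = np.ones(shape, dtype=bool)
    idx = np.round(seeds).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    marker[tuple(idx.T)] = False
    indices = ndimage.distance_transform_edt(
        marker, sampling=voxel_size, return_distances=False, return_indices=True)
    seed_label = np.full(shape, -1, dtype=np.int32)
    seed_label[tuple(idx.T)] = np.arange(len(seeds), dtype=np.int32)
    return seed_label[tuple(indices)] + 1  # labels are 1-based


def _membrane_from_labels(labels: np.ndarray) -> np.ndarray:
    """Bright shells where the cell label changes between neighbours."""
    border = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        diff = labels[tuple(sl_a)] != labels[tuple(sl_b)]
        border[tuple(sl_a)] |= diff
        border[tuple(sl_b)] |= diff
    membrane = ndimage.gaussian_filter(border.astype(np.float32), sigma=0.7)
    peak = membrane.max()
    return membrane / peak if peak > 0 else membrane


def rasterize_tube(shape, points: np.ndarray, radii: np.ndarray,
                   voxel_size=(1.0, 1.0, 1.0), out: np.ndarray | None = None
                   ) -> np.ndarray:
    """Rasterize a polyline tube with per-point radius (µm) into a boolean mask."""
    mask = out if out is not None else np.zeros(shape, dtype=bool)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(points),))
    vs = np.asarray(voxel_size, dtype=float)
    if len(points) == 1:
        points = np.vstack([points, points])
        radii = np.hstack([radii, radii])
    for (p0, p1), (r0, r1) in zip(zip(points[:-1], points[1:]),
                                  zip(radii[:-1], radii[1:])):
        rmax_vox = max(r0, r1) / vs.min()
        lo = np.maximum(np.floor(np.minimum(p0, p1) - rmax_vox - 1), 0).astype(int)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + rmax_vox + 2),
                        np.asarray(shape)).astype(int)
        if np.any(hi <= lo):
            continue
        grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                            indexing="ij", sparse=False)
        pts = np.stack(grids, axis=-1).astype(float)
        seg = (p1 - p0) * vs
        rel = (pts - p0) * vs
        seg_len2 = float(seg @ seg)
        if seg_len2 < 1e-12:
            t = np.zeros(pts.shape[:-1])
        else:
            t = np.clip(rel @ seg / seg_len2, 0.0, 1.0)
        closest = t[..., None] * seg
        dist = np.linalg.norm(rel - closest, axis=-1)
        radius = r0 + t * (r1 - r0)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= dist <= radius
    return mask


def _bc_network_edges(cfg: PhantomConfig, seeds: np.ndarray,
                      rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Connected tube network along cell interfaces.

    Edges of the Voronoi ridge polygons are the triple lines where three cells
    meet; a random spanning tree of the largest connected component plus a
    fraction of loop-closing extras gives an interconnected network, mirroring
    the qualitative topology of the canalicular mesh.
    """
    shape = np.asarray(cfg.shape, dtype=float)
    margin = cfg.bc_radius / min(cfg.voxel_size) + 1.0
    try:
        if len(seeds) < 5:
            raise QhullError("too few seeds for a 3D tessellation")
        vor = Voronoi(seeds)
        graph = nx.Graph()
        for ridge in vor.ridge_vertices:
            if -1 in ridge:
                continue
            cycle = list(ridge) + [ridge[0]]
            for a, b in zip(cycle[:-1], cycle[1:]):
                pa, pb = vor.vertices[a], vor.vertices[b]
                if (np.all(pa >= margin) and np.all(pa <= shape - 1 - margin)
                        and np.all(pb >= margin) and np.all(pb <= shape - 1 - margin)):
                    graph.add_edge(a, b, length=float(np.linalg.norm(pa - pb)))
        if graph.number_of_edges() == 0:
            raise QhullError("no interior tessellation edges")
        component = max(nx.connected_components(graph), key=len)
        sub = graph.subgraph(component).copy()
        for _, _, data in sub.edges(data=True):
            data["w"] = rng.random()
        tree = nx.minimum_spanning_tree(sub, weight="w")
        kept = set(frozenset(e) for e in tree.edges())
        extras = [e for e in sub.edges() if frozenset(e) not in kept]
        rng.shuffle(extras)
        kept_edges = list(tree.edges()) + extras[: int(len(extras) * cfg.bc_extra_edge_fraction)]
        return [(vor.vertices[a].copy(), vor.vertices[b].copy()) for a, b in kept_edges]
    except QhullError:
        # degenerate seed sets: fall back to a chain through interface midpoints
        order = rng.permutation(len(seeds))
        mids = [(seeds[order[i]] + seeds[order[i + 1]]) / 2.0
                for i in range(len(order) - 1)]
        mids = [np.clip(m, margin, shape - 1 - margin) for m in mids]
        return [(mids[i], mids[i + 1]) for i in range(len(mids) - 1)] if len(mids) > 1 else []


def _bc_radius_at(cfg: PhantomConfig, point_vox: np.ndarray, axis: dict) -> float:
    if cfg.bc_radius_axis_range is None:
        return cfg.bc_radius
    r0, r1 = cfg.bc_radius_axis_range
    vs = np.asarray(cfg.voxel_size)
    t = float(np.dot(point_vox * vs - axis["origin"], axis["direction"])) / axis["length"]
    return r0 + np.clip(t, 0.0, 1.0) * (r1 - r0)


def _sinusoid_centerlines(cfg: PhantomConfig, rng: np.random.Generator
                          ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Smooth tubes spanning the x (lobule) axis with gentle lateral wander."""
    nz, ny, nx = cfg.shape
    lines = []
    n_pts = max(8, nx // 8)
    xs = np.linspace(1.0, nx - 2.0, n_pts)
    for _ in range(cfg.n_sinusoids):
        z0, y0 = rng.uniform(0.15, 0.85) * nz, rng.uniform(0.15, 0.85) * ny
        wander_z = np.cumsum(rng.normal(0, nz * 0.02, n_pts))
        wander_y = np.cumsum(rng.normal(0, ny * 0.02, n_pts))
        wander_z = ndimage.gaussian_filter1d(wander_z, 2)
        wander_y = ndimage.gaussian_filter1d(wander_y, 2)
        z = np.clip(z0 + wander_z - wander_z.mean(), 1, nz - 2)
        y = np.clip(y0 + wander_y - wander_y.mean(), 1, ny - 2)
        pts = np.stack([z, y, xs], axis=1)
        lines.append((pts, np.full(n_pts, cfg.sinusoid_radius)))
    return lines


def _kupffer_blob(shape, center, cfg: PhantomConfig, rng: np.random.Generator,
                  out: np.ndarray):
    """Star-shaped blob: a body sphere plus a few radial arms."""
    body_r = max(2.0 * min(cfg.voxel_size), cfg.cell_diameter * 0.12)
    rasterize_tube(shape, np.array([center]), np.array([body_r]),
                   cfg.voxel_size, out=out)
    for _ in range(rng.integers(4, 7)):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        tip = center + direction * cfg.cell_diameter * 0.35 / np.asarray(cfg.voxel_size)
        tip = np.clip(tip, 0, np.asarray(shape) - 1)
        rasterize_tube(shape, np.array([center, tip]),
                       np.array([body_r * 0.5, body_r * 0.2]), cfg.voxel_size, out=out)


# ---------------------------------------------------------------- operations
def generate_phantom(config: PhantomConfig) -> PhantomVolume:
    """Generate a seeded multi-channel liver phantom with ground truth.

    Identical configurations produce bit-identical volumes.
    """
    rng = np.random.default_rng(config.seed)
    vs = np.asarray(config.voxel_size, dtype=float)
    shape = config.shape

    seeds = _poisson_disc_seeds(config, rng)
    labels = _label_map_from_seeds(shape, seeds, config.voxel_size)
    membrane = _membrane_from_labels(labels)

    nz, ny, nx = shape
    axis = {
        "origin": np.array([nz / 2.0 * vs[0], ny / 2.0 * vs[1], 0.0]),
        "direction": np.array([0.0, 0.0, 1.0]),
        "length": float(nx * vs[2]),
    }

    bc_mask = np.zeros(shape, dtype=bool)
    bc_lines: list[tuple[np.ndarray, np.ndarray]] = []
    for p0, p1 in _bc_network_edges(config, seeds, rng):
        radii = np.array([_bc_radius_at(config, p0, axis),
                          _bc_radius_at(config, p1, axis)])
        pts = np.vstack([p0, p1])
        rasterize_tube(shape, pts, radii, config.voxel_size, out=bc_mask)
        bc_lines.append((pts, radii))

    sin_mask = np.zeros(shape, dtype=bool)
    sin_lines = _sinusoid_centerlines(config, rng)
    for pts, radii in sin_lines:
        rasterize_tube(shape, pts, radii, config.voxel_size, out=sin_mask)

    kupffer = np.zeros(shape, dtype=bool)
    centroids = []
    for _ in range(config.kupffer_count):
        center = rng.uniform(0.1, 0.9, size=3) * np.asarray(shape)
        centroids.append(center)
        _kupffer_blob(shape, center, config, rng, kupffer)
    centroids = np.array(centroids) if centroids else np.empty((0, 3))

    channels = {
        "membrane": membrane.astype(np.float32),
        "bc": bc_mask.astype(np.float32),
        "sinusoid": sin_mask.astype(np.float32),
        "kupffer": kupffer.astype(np.float32),
    }
    truth = PhantomTruth(labels, bc_lines, sin_lines, centroids, axis)
    return PhantomVolume(channels, truth, config)


def depth_attenuation_factor(z_um: np.ndarray, depth: float, width: float) -> np.ndarray:
    """Monotone non-increasing logistic attenuation profile.

    ~0.95 at ``depth - width``, 0.5 at the knee, ~0.05 at ``depth + width``.
    """
    scale = width / 3.0
    return 1.0 / (1.0 + np.exp((np.asarray(z_um, dtype=float) - depth) / scale))


def apply_depth_attenuation(volume: PhantomVolume, channel: str, depth: float,
                            width: float) -> PhantomVolume:
    """Multiply one channel by the depth-dependent attenuation factor.

    Emulates the loss of antibody-derived signal past the penetration limit;
    the membrane channel, stained by a deeply penetrating small molecule,
    should be left untouched when emulating the deep-imaging experiment.
    """
    data = volume.channel(channel)
    z_um = np.arange(volume.config.shape[0]) * volume.config.voxel_size[0]
    factor = depth_attenuation_factor(z_um, depth, width).astype(np.float32)
    channels = dict(volume.channels)
    channels[channel] = data * factor[:, None, None]
    return PhantomVolume(channels, volume.truth, volume.config)


def add_noise(channel: np.ndarray, gaussian_sd: float, poisson_scale: float,
              seed: int) -> np.ndarray:
    """Mixed Poisson–Gaussian corruption; preserves the expectation.

    ``poisson_scale`` is the photon count corresponding to unit intensity;
    0 disables the Poisson component, ``gaussian_sd`` 0 the Gaussian one.
    """
    if gaussian_sd < 0:
        raise ValueError("gaussian_sd must be >= 0")
    if poisson_scale < 0:
        raise ValueError("poisson_scale must be >= 0")
    if np.any(channel < 0):
        raise ValueError("add_noise expects non-negative intensities")
    rng = np.random.default_rng(seed)
    out = np.asarray(channel, dtype=np.float32)
    if poisson_scale > 0:
        out = rng.poisson(out * poisson_scale).astype(np.float32) / poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, out.shape).astype(np.float32)
    return out


def make_unpaired(pairs: list[tuple[np.ndarray, np.ndarray]], seed: int
                  ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Destroy the correspondence of registered pairs into two unpaired sets.

    Domain A keeps its order; domain B is permuted by a seeded non-identity
    permutation, so the image multisets are preserved but no index pairing
    survives.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs; mixing a single pair is a no-op")
    rng = np.random.default_rng(seed)
    n = len(pairs)
    perm = rng.permutation(n)
    while np.all(perm == np.arange(n)):
        perm = rng.permutation(n)
    set_a = [a for a, _ in pairs]
    set_b = [pairs[j][1] for j in perm]
    return set_a, set_b
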