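"""Image I/O, intensity normalization, patch extraction and split utilities.

Volumes are TIFF stacks; axes are ``(z, y, x)`` for 3D and ``(y, x)`` for 2D.
Training-time normalization maps each image's min/max to [-1, 1] and records
the affine so predictions can be mapped back to the source intensity range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class NormInfo:
    """Recorded affine of a min-max normalization: v' = 2(v-vmin)/(vmax-vmin)-1."""

    vmin: float
    vmax: float


@dataclass
class Volume:
    data: np.ndarray
    voxel_size: tuple[float, ...] = (1.0, 1.0, 1.0)
    name: str = ""
    norm: NormInfo | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"Volume must be 2D or 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class PatchSet:
    """Equally shaped patches with per-patch provenance.

    ``patches`` is a single stacked array ``(n, *size)``; ``source_ids`` holds
    ``(image_name, z, y, x)`` origins (z is the slice index for 2D patches).
    """

    patches: np.ndarray
    source_ids: list[tuple]
    domain: str = "A"
    size: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.patches) != len(self.source_ids):
            raise ValueError("patches and source_ids length mismatch")
        if len(self.patches):
            self.size = tuple(self.patches.shape[1:])

    def __len__(self):
        return len(self.patches)


# ------------------------------------------------------------------------ IO
def write_stack(volume: Volume, path: str | Path):
    """Write a TIFF stack; voxel size goes into the image description."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    desc = json.dumps({"voxel_size": list(volume.voxel_size), "name": volume.name})
    tifffile.imwrite(path, volume.data, description=desc)


def read_stack(path: str | Path) -> Volume:
    """Read a TIFF stack; bit-identical round trip with :func:`write_stack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"unreadable or unsupported TIFF {path}: {exc}") from exc
    voxel_size = (1.0,) * min(data.ndim, 3)
    name = path.stem
    if desc:
        try:
            meta = json.loads(desc)
            voxel_size = tuple(meta.get("voxel_size", voxel_size))
            name = meta.get("name", name) or name
        except json.JSONDecodeError:
            pass
    return Volume(data, voxel_size=voxel_size, name=name)


# -------------------------------------------------------------- normalization
def normalize(volume: Volume, clip_percentiles: tuple[float, float] | None = None
              ) -> Volume:
    """Affinely map intensities to [-1, 1] and record the affine.

    ``clip_percentiles`` (e.g. ``(0.1, 99.9)``) clips outliers before the
    min-max mapping; off by default.  A constant image maps to all zeros with
    a warning rather than producing NaNs.
    """
    data = np.asarray(volume.data, dtype=np.float32)
    if clip_percentiles is not None:
        lo, hi = np.percentile(data, clip_percentiles)
        data = np.clip(data, lo, hi)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax <= vmin:
        warnings.warn(f"constant image {volume.name!r}: normalized to all zeros")
        out = np.zeros_like(data)
        return replace(volume, data=out, norm=NormInfo(vmin, vmin + 1.0))
    out = 2.0 * (data - vmin) / (vmax - vmin) - 1.0
    return replace(volume, data=out.astype(np.float32), norm=NormInfo(vmin, vmax))


def denormalize(volume: Volume) -> Volume:
    """Invert :func:`normalize` using the recorded affine."""
    if volume.norm is None:
        raise ValueError("volume carries no normalization record to invert")
    vmin, vmax = volume.norm.vmin, volume.norm.vmax
    data = (np.asarray(volume.data, dtype=np.float32) + 1.0) / 2.0 * (vmax - vmin) + vmin
    return replace(volume, data=data, norm=None)


# ----------------------------------------------------------- patch extraction
def _as_volume_list(volumes) -> list[Volume]:
    if isinstance(volumes, Volume):
        return [volumes]
    return list(volumes)


def extract_patches_2d(volumes, size: int, n_per_image: int, seed: int,
                       domain: str = "A") -> PatchSet:
    """Sample ``n_per_image`` square patches per image at uniform positions.

    3D stacks are sampled slice-wise: a random z slice, then a random in-plane
    origin fully inside bounds.  Sampling is with replacement (the training
    protocol draws far more patches per image than any non-overlapping grid
    holds, so overlap is implied).
    """
    volumes = _as_volume_list(volumes)
    rng = np.random.default_rng(seed)
    patches, ids = [], []
    for vol in volumes:
        data = vol.data if vol.data.ndim == 3 else vol.data[None]
        nz, ny, nx = data.shape
        if ny < size or nx < size:
            raise ValueError(
                f"image {vol.name!r} slices of shape ({ny}, {nx}) are smaller than "
                f"the {size}x{size} patch")
        zs = rng.integers(0, nz, n_per_image)
        ys = rng.integers(0, ny - size + 1, n_per_image)
        xs = rng.integers(0, nx - size + 1, n_per_image)
        for z, y, x in zip(zs, ys, xs):
            patches.append(data[z, y:y + size, x:x + size])
            ids.append((vol.name, int(z), int(y), int(x)))
    return PatchSet(np.stack(patches), ids, domain=domain)


def extract_patches_3d(volumes, size: int, n_per_image: int, seed: int,
                       domain: str = "A") -> PatchSet:
    """Sample cubic ``size**3`` patches per image at uniform positions."""
    volumes = _as_volume_list(volumes)
    rng = np.random.default_rng(seed)
    patches, ids = [], []
    for vol in volumes:
        if vol.data.ndim != 3:
            raise ValueError(f"image {vol.name!r} is not 3D")
        nz, ny, nx = vol.data.shape
        if nz < size or ny < size or nx < size:
            raise ValueError(
                f"image {vol.name!r} of shape {vol.data.shape} is smaller than the "
                f"{size}^3 patch")
        zs = rng.integers(0, nz - size + 1, n_per_image)
        ys = rng.integers(0, ny - size + 1, n_per_image)
        xs = rng.integers(0, nx - size + 1, n_per_image)
        for z, y, x in zip(zs, ys, xs):
            patches.append(vol.data[z:z + size, y:y + size, x:x + size])
            ids.append((vol.name, int(z), int(y), int(x)))
    return PatchSet(np.stack(patches), ids, domain=domain)


def split_train_val(patchset: PatchSet, fraction: float = 0.9, seed: int = 0
                    ) -> tuple[PatchSet, PatchSet]:
    """Seeded random partition into train/validation subsets.

    ``|train| = round(fraction * N)``; the two subsets are disjoint and their
    union is the input.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(patchset)
    if n < 2:
        raise ValueError("need at least 2 patches to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    tr, va = np.sort(order[:n_train]), np.sort(order[n_train:])
    make = lambda idx: PatchSet(patchset.patches[idx],
                                [patchset.source_ids[i] for i in idx],
                                domain=patchset.domain)
    return make(tr), make(va)


# ------------------------------------------------------------- persistence
def save_patchset(patchset: PatchSet, directory: str | Path):
    """Persist a patch set as TIFFs plus a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"domain": patchset.domain, "size": list(patchset.size),
                "n": len(patchset), "source_ids": [list(s) for s in patchset.source_ids]}
    tifffile.imwrite(directory / "patches.tif", patchset.patches)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_patchset(directory: str | Path) -> PatchSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    patches = tifffile.imread(directory / "patches.tif")
    return PatchSet(patches, [tuple(s) for s in manifest["source_ids"]],
                    domain=manifest["domain"])
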