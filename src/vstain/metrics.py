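"""Cube-wise image-quality evaluation suite.

Test volumes are partitioned into non-overlapping cubes (128 voxels per edge
by default, giving the canonical 25-cube layout on a 640x640x128 stack) and
ten similarity metrics are estimated independently per cube: FID, MSE, MSLE,
MAE, RMSE, PSNR, SSIM, MS-SSIM, cosine similarity (COS) and Pearson
correlation (CoC).  Foreground/background-split variants use the Otsu mask
of the ground truth, and block-wise MSE heatmaps localize prediction errors.

Degenerate inputs (constant images, zero vectors, empty regions) yield
documented sentinel values with warnings instead of NaNs, so per-cube reports
never silently drop cubes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage
from skimage.metrics import structural_similarity

from .training import otsu_mask

PIXEL_METRICS = ("MSE", "MSLE", "MAE", "RMSE", "PSNR")
ALL_METRICS = ("FID", "MSE", "MSLE", "MAE", "RMSE", "PSNR", "SSIM", "MS-SSIM",
               "COS", "CoC")

#: canonical multi-scale weights (renormalized when fewer scales fit)
_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])


# ----------------------------------------------------------------- partition
@dataclass
class CubePartition:
    edge: int
    origins: list[tuple[int, int, int]]

    @property
    def count(self) -> int:
        return len(self.origins)


def partition_cubes(volume: np.ndarray, edge: int = 128) -> CubePartition:
    """Non-overlapping axis-aligned cube grid; trailing remainders discarded.

    A 640x640x128 volume at edge 128 yields 5*5*1 = 25 cubes.
    """
    shape = volume.shape if hasattr(volume, "shape") else tuple(volume)
    if len(shape) != 3:
        raise ValueError("cube partition requires a 3D volume")
    counts = [s // edge for s in shape]
    if min(counts) < 1:
        raise ValueError(f"volume shape {tuple(shape)} smaller than one {edge}^3 cube")
    origins = [(z * edge, y * edge, x * edge)
               for z in range(counts[0]) for y in range(counts[1])
               for x in range(counts[2])]
    return CubePartition(edge, origins)


def extract_cube(volume: np.ndarray, partition: CubePartition, index: int) -> np.ndarray:
    z, y, x = partition.origins[index]
    e = partition.edge
    return volume[z:z + e, y:y + e, x:x + e]


# ------------------------------------------------------------- pixel metrics
PSNR_INF = np.inf  # sentinel for identical images


def _msle(pred: np.ndarray, gt: np.ndarray) -> float:
    """MSE of log1p intensities, inputs shifted to be non-negative first."""
    shift = min(0.0, float(min(pred.min(), gt.min())))
    return float(np.mean((np.log1p(pred - shift) - np.log1p(gt - shift)) ** 2))


def pixel_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """MSE, MSLE, MAE, RMSE and PSNR between a prediction and ground truth.

    PSNR uses the maximum pixel value of the ground truth as the peak, per the
    metric's definition on the evaluated data (not a bit-depth constant);
    identical images report the +inf sentinel.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    diff = pred - gt
    mse = float(np.mean(diff * diff))
    out = {
        "MSE": mse,
        "MSLE": _msle(pred, gt),
        "MAE": float(np.mean(np.abs(diff))),
        "RMSE": float(np.sqrt(mse)),
    }
    if mse == 0.0:
        out["PSNR"] = PSNR_INF
    else:
        peak = float(np.abs(gt).max())
        if peak == 0.0:
            warnings.warn("PSNR of an all-zero ground truth: reporting -inf")
            out["PSNR"] = -np.inf
        else:
            out["PSNR"] = float(10.0 * np.log10(peak ** 2 / mse))
    return out


# -------------------------------------------------------- structural metrics
def ssim(pred: np.ndarray, gt: np.ndarray, data_range: float | None = None) -> float:
    """Mean SSIM with an 11-point Gaussian window (sigma 1.5, K1/K2 0.01/0.03)."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if data_range is None:
        data_range = float(gt.max() - gt.min())
        if data_range == 0.0:
            warnings.warn("SSIM with constant ground truth: using unit data range")
            data_range = 1.0
    if min(pred.shape) < 11:
        raise ValueError(f"image shape {pred.shape} smaller than the 11-point window")
    return float(structural_similarity(gt, pred, data_range=data_range,
                                       gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False))


def _ssim_lcs(pred, gt, data_range, sigma=1.5):
    """Gaussian-window luminance and contrast-structure maps (for MS-SSIM)."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    f = lambda img: ndimage.gaussian_filter(img, sigma, truncate=3.5)
    mu_p, mu_g = f(pred), f(gt)
    var_p = f(pred * pred) - mu_p ** 2
    var_g = f(gt * gt) - mu_g ** 2
    cov = f(pred * gt) - mu_p * mu_g
    lum = (2 * mu_p * mu_g + c1) / (mu_p ** 2 + mu_g ** 2 + c1)
    cs = (2 * cov + c2) / (var_p + var_g + c2)
    return lum, cs


def _downsample2(img: np.ndarray) -> np.ndarray:
    """2x average pooling along every axis (odd remainders trimmed)."""
    for ax in range(img.ndim):
        n = img.shape[ax] - img.shape[ax] % 2
        sl = [slice(None)] * img.ndim
        sl[ax] = slice(0, n)
        img = img[tuple(sl)]
        a = [slice(None)] * img.ndim
        b = [slice(None)] * img.ndim
        a[ax] = slice(0, None, 2)
        b[ax] = slice(1, None, 2)
        img = 0.5 * (img[tuple(a)] + img[tuple(b)])
    return img


def ms_ssim(pred: np.ndarray, gt: np.ndarray, data_range: float | None = None,
            max_scales: int = 5) -> float:
    """Multi-scale SSIM over up to five dyadic scales.

    Contrast-structure terms are combined across scales and the luminance term
    enters at the coarsest scale only; when the image is too small for five
    scales, the canonical weights of the realized scales are renormalized.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if data_range is None:
        data_range = float(gt.max() - gt.min())
        if data_range == 0.0:
            warnings.warn("MS-SSIM with constant ground truth: using unit data range")
            data_range = 1.0
    n_scales = 1
    m = min(pred.shape)
    while n_scales < max_scales and m // 2 >= 11:
        n_scales += 1
        m //= 2
    weights = _MSSSIM_WEIGHTS[:n_scales]
    weights = weights / weights.sum()
    value = 1.0
    for scale in range(n_scales):
        lum, cs = _ssim_lcs(pred, gt, data_range)
        mean_cs = float(cs.mean())
        if scale == n_scales - 1:
            term = float((lum * cs).mean())
        else:
            term = mean_cs
        value *= np.sign(term) * np.abs(term) ** weights[scale]
        if scale < n_scales - 1:
            pred, gt = _downsample2(pred), _downsample2(gt)
    return float(value)


def structural_metrics(pred: np.ndarray, gt: np.ndarray,
                       data_range: float | None = None) -> dict[str, float]:
    return {"SSIM": ssim(pred, gt, data_range),
            "MS-SSIM": ms_ssim(pred, gt, data_range)}


# ------------------------------------------------------------ vector metrics
def vector_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """Cosine similarity of the flattened images and Pearson correlation.

    A zero vector (COS) or constant image (CoC) yields a 0.0 sentinel with a
    warning rather than NaN.
    """
    p = np.asarray(pred, dtype=np.float64).ravel()
    g = np.asarray(gt, dtype=np.float64).ravel()
    if p.shape != g.shape:
        raise ValueError("shape mismatch")
    norm_p, norm_g = np.linalg.norm(p), np.linalg.norm(g)
    if norm_p == 0.0 or norm_g == 0.0:
        warnings.warn("cosine similarity with a zero vector: reporting 0.0")
        cos = 0.0
    else:
        cos = float(np.dot(p, g) / (norm_p * norm_g))
    sd_p, sd_g = p.std(), g.std()
    if sd_p == 0.0 or sd_g == 0.0:
        warnings.warn("correlation with a constant image: reporting 0.0")
        coc = 0.0
    else:
        coc = float(np.corrcoef(p, g)[0, 1])
    return {"COS": cos, "CoC": coc}


# -------------------------------------------------------------------- FID
def identity_features(image: np.ndarray) -> np.ndarray:
    """Trivial extractor: the flattened image itself."""
    return np.asarray(image, dtype=np.float64).ravel()


class LinearFeatureExtractor:
    """Tiny fixed linear projection to ``n_features`` (deterministic, seeded)."""

    def __init__(self, n_features: int = 8, seed: int = 0):
        self.n_features = n_features
        self.seed = seed
        self._proj: np.ndarray | None = None

    def __call__(self, image: np.ndarray) -> np.ndarray:
        flat = np.asarray(image, dtype=np.float64).ravel()
        if self._proj is None or self._proj.shape[1] != flat.size:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.normal(0, 1.0 / np.sqrt(flat.size),
                                    (self.n_features, flat.size))
        return self._proj @ flat


class RandomConvFeatureExtractor:
    """Default production extractor: seeded random convolutional features.

    Two fixed random 2D convolution banks with ReLU and average pooling,
    followed by spatial mean/max pooling per channel.  Deterministic under its
    seed; absolute FID values are comparable only within one extractor, which
    holds for any learned or random feature backbone.
    """

    def __init__(self, n_channels: int = 16, kernel: int = 5, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.bank1 = rng.normal(0, 1.0, (n_channels, kernel, kernel)) / kernel
        self.bank2 = rng.normal(0, 1.0, (n_channels, n_channels, 3, 3)) / 3.0

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("extractor operates on single 2D images")
        scale = img.std() or 1.0
        img = (img - img.mean()) / scale
        maps1 = np.stack([ndimage.convolve(img, k, mode="reflect") for k in self.bank1])
        maps1 = np.maximum(maps1, 0.0)[:, ::2, ::2]
        maps2 = np.stack([
            np.maximum(sum(ndimage.convolve(maps1[c], self.bank2[o, c], mode="reflect")
                           for c in range(maps1.shape[0])), 0.0)
            for o in range(self.bank2.shape[0])
        ])
        return np.concatenate([maps2.mean(axis=(1, 2)), maps2.max(axis=(1, 2))])


def fid(samples_a, samples_b, feature_extractor=identity_features) -> float:
    """Fréchet distance between Gaussians fitted to feature representations.

    ``||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2})`` with the matrix
    square root symmetrized.  Requires at least two samples per side; the
    extractor maps one image to one feature vector and is pluggable.
    """
    feats_a = np.stack([np.asarray(feature_extractor(s), dtype=np.float64)
                        for s in samples_a])
    feats_b = np.stack([np.asarray(feature_extractor(s), dtype=np.float64)
                        for s in samples_b])
    if len(feats_a) < 2 or len(feats_b) < 2:
        raise ValueError("FID requires at least 2 samples per side")
    if feats_a.shape[1] != feats_b.shape[1]:
        raise ValueError("feature dimension mismatch between the two sample sets")
    mu_a, mu_b = feats_a.mean(axis=0), feats_b.mean(axis=0)
    cov_a = np.atleast_2d(np.cov(feats_a, rowvar=False))
    cov_b = np.atleast_2d(np.cov(feats_b, rowvar=False))
    diff = mu_a - mu_b
    if np.allclose(cov_a, 0) and np.allclose(cov_b, 0):
        if np.allclose(diff, 0):
            warnings.warn("FID with degenerate (constant) features: reporting 0.0")
            return 0.0
        return float(diff @ diff)
    prod = cov_a @ cov_b
    if np.linalg.matrix_rank(prod) < prod.shape[0]:
        # standard regularization for singular feature covariances
        eps = 1e-6 * np.eye(prod.shape[0])
        prod = (cov_a + eps) @ (cov_b + eps)
    covmean = linalg.sqrtm(prod)
    if isinstance(covmean, tuple):  # older scipy returns (sqrtm, errest)
        covmean = covmean[0]
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    covmean = (covmean + covmean.T) / 2.0
    value = float(diff @ diff + np.trace(cov_a) + np.trace(cov_b)
                  - 2.0 * np.trace(covmean))
    return max(value, 0.0)


# ------------------------------------------------------------ fg/bg variants
def fg_bg_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, dict[str, float]]:
    """Pixel metrics restricted to the Otsu foreground / background of ``gt``.

    An empty region's entry is absent from the result rather than zero.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    mask = otsu_mask(gt)
    out: dict[str, dict[str, float]] = {}
    for region, sel in (("foreground", mask), ("background", ~mask)):
        if not sel.any():
            continue
        out[region] = pixel_metrics(pred[sel], gt[sel])
    return out


# ------------------------------------------------------------- error heatmap
def error_heatmap(pred: np.ndarray, gt: np.ndarray,
                  blocks: tuple[int, int] = (9, 9)) -> np.ndarray:
    """Per-block MSE of a 2D image on a ``blocks`` grid.

    Block edges are ``floor(dim / blocks)``; remainder rows/columns are
    assigned to the last block, so the size-weighted mean of block MSEs
    equals the global MSE exactly.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.ndim != 2 or pred.shape != gt.shape:
        raise ValueError("error_heatmap expects two equal-shape 2D images")
    by, bx = blocks
    if pred.shape[0] < by or pred.shape[1] < bx:
        raise ValueError(f"image shape {pred.shape} smaller than the {blocks} grid")
    hy, hx = pred.shape[0] // by, pred.shape[1] // bx
    grid = np.zeros(blocks)
    sq = (pred - gt) ** 2
    for i in range(by):
        y0, y1 = i * hy, (i + 1) * hy if i < by - 1 else pred.shape[0]
        for j in range(bx):
            x0, x1 = j * hx, (j + 1) * hx if j < bx - 1 else pred.shape[1]
            grid[i, j] = sq[y0:y1, x0:x1].mean()
    return grid


# ------------------------------------------------------------ cube-wise suite
@dataclass
class MetricReport:
    """Per-cube metric values plus box-plot style summaries."""

    per_cube: dict[str, list[float]]
    summary: dict[str, dict[str, float]] = field(default_factory=dict)
    fg_bg: list[dict] | None = None
    cube_edge: int = 128

    def __post_init__(self):
        if not self.summary:
            self.summary = {m: summarize(v) for m, v in self.per_cube.items()}


def summarize(values: list[float]) -> dict[str, float]:
    """Median, Tukey quartiles and data range (box plot with min/max whiskers)."""
    finite = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if finite.size == 0:
        return {"median": np.nan, "q1": np.nan, "q3": np.nan,
                "min": np.nan, "max": np.nan}
    q1, med, q3 = np.percentile(finite, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(finite.min()), "max": float(finite.max())}


def evaluate_cubewise(pred_volume: np.ndarray, gt_volume: np.ndarray,
                      partition: CubePartition | None = None, cube_edge: int = 128,
                      feature_extractor=None, fg_bg: bool = False) -> MetricReport:
    """All ten metrics estimated independently for each cube of the partition.

    FID within a cube is computed between the sets of z slices of the
    prediction and of the ground truth, each slice mapped through the feature
    extractor (default: the seeded random-convolutional extractor).
    """
    pred_volume = np.asarray(pred_volume)
    gt_volume = np.asarray(gt_volume)
    if pred_volume.shape != gt_volume.shape:
        raise ValueError("prediction and ground truth shapes differ")
    if partition is None:
        partition = partition_cubes(gt_volume, cube_edge)
    if feature_extractor is None:
        feature_extractor = RandomConvFeatureExtractor(seed=0)
    per_cube: dict[str, list[float]] = {m: [] for m in ALL_METRICS}
    split_reports = [] if fg_bg else None
    for i in range(partition.count):
        p = extract_cube(pred_volume, partition, i).astype(np.float64)
        g = extract_cube(gt_volume, partition, i).astype(np.float64)
        values = pixel_metrics(p, g)
        values.update(structural_metrics(p, g))
        values.update(vector_metrics(p, g))
        values["FID"] = fid(list(p), list(g), feature_extractor)
        for m in ALL_METRICS:
            per_cube[m].append(values[m])
        if split_reports is not None:
            split_reports.append(fg_bg_metrics(p, g))
    return MetricReport(per_cube, fg_bg=split_reports, cube_edge=partition.edge)
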