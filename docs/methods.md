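# Methods

## Problem and approach

Multi-marker 3D reconstruction of liver tissue is limited by antibody
penetration (markers for bile canaliculi and sinusoids drop out beyond
roughly 80–100 µm of depth) and by acquisition time. The package implements
virtual staining: from a single deeply-penetrating actin-mesh (phalloidin)
channel, trained generators synthesize the bile-canaliculi (BC), sinusoid
and Kupffer-cell channels. Because registered image pairs are often
unobtainable (e.g. human tissue where the BC antibody protocol destroys the
actin mesh), the core model is an unpaired cycle-consistent adversarial
translator; a supervised U-Net regression is included as the paired
baseline.

## Models

**Unpaired translator.** Two generators (`G_AB`, `G_BA`) and two patch
discriminators (`D_A`, `D_B`). Generators follow the residual token
architecture `c7s1-64, d128, d256, R256 (x6), u128, u64, c7s1-1` for
128-pixel patches (nine residual blocks for 256-pixel patches): a 7×7
stride-1 convolution, two stride-2 downsampling convolutions, residual
blocks, two stride-2 transposed convolutions and a final 7×7 convolution
with tanh output, instance normalization and ReLU throughout. Discriminators
are `C64-C128-C256-C512-F1`: 4×4 stride-2 convolutions with instance norm
and LeakyReLU, then a 4×4 stride-1 convolution to a one-channel patch score
map. The 3D variants swap every convolution for its 3D counterpart; the
token list is unchanged.

**Objectives.** Least-squares adversarial losses
(`D` minimizes `E[(D(real)-1)^2] + E[D(fake)^2]`, `G` minimizes
`E[(D(fake)-1)^2]`) plus a cycle-consistency reconstruction term weighted by
`lambda_cycle` (default 10). The plain variant uses the mean squared error of
the reconstruction over the whole image. The Otsu-weighted variant computes
an Otsu foreground mask of each cycle target once per patch and weights the
regional MSEs as `w_bg * MSE_bg + w_fg * MSE_fg` with defaults 0.2/0.8,
concentrating reconstruction capacity on the sparse bright structures that
occupy a small voxel fraction of fluorescence stacks. The published
description of the objective ("MSE as the loss function") does not
disambiguate whether it denotes the adversarial or the reconstruction term;
here both are squared-error objectives, each independently switchable in
`TrainConfig`.

**Paired baseline.** A U-Net (default depth 4, 64 base filters, instance
norm, tanh output) regressing the target channel from the membrane channel
with MSE or Otsu-weighted MSE. The baseline's exact published architecture
is not specified beyond "modified U-Net"; the defaults here are documented
choices, not a reconstruction of the original.

## Training protocol

Defaults follow the 2D protocol: per-image min–max normalization to [-1, 1]
(recorded so predictions can be mapped back), 2500 random 2D patches per
image (128² for BC/sinusoid models, 256² for the Kupffer model), Adam with
learning rate 0.002, beta1 0.5, batch size 1, 100 epochs. The 3D protocol
uses 900 patches of 64³ per image, a 90/10 train/validation split, 300
epochs and early stopping (patience 20 epochs on the validation cycle
reconstruction). Patch positions are sampled uniformly with replacement:
2500 patches from one image exceed any non-overlapping grid, so overlap is
implied by the protocol itself. An optional linear learning-rate decay to
zero over a configurable tail of the epoch budget (`lr_decay_start`) leaves
the final generators near a settled optimum rather than the last oscillation
of the adversarial game; the desk-scale studies enable it at 0.5.

The printed learning rate 0.002 is kept as the default even though 0.0002 is
the convention of this architecture family; both run stably at desk scale
and the configuration decides. No identity-mapping loss and no
discriminator history buffer are used by default; flags exist for both.
The discriminator applies instance norm to all C blocks, matching the
printed architecture text; `disc_norm_first=False` gives the conventional
variant that leaves the first block unnormalized. The desk-scale studies use
the conventional variant: with per-image normalized inputs, first-block
normalization discards most of the absolute-intensity signal that separates
the two domains of the inversion task.

## Tensor backend

The networks run on a compact reverse-mode autodiff engine over numpy
float32 arrays written for this package: broadcasting arithmetic,
reductions, ReLU/LeakyReLU/tanh, channel concatenation, and N-dimensional
convolution / transposed convolution implemented as sums over kernel offsets
of batched channel matmuls (peak memory one padded input copy regardless of
kernel size). Reflection padding is used in generator convolutions in 2D and
3D alike; discriminator and resampling convolutions use zero padding.
Weights initialize from N(0, 0.02); instance norm starts at scale 1, offset
0. All randomness flows through explicit `numpy.random.Generator` seeds, so
training traces are bit-reproducible. Gradients are validated against finite
differences and a float64 reference in the test suite.

## Synthetic phantom

The phantom emulates the experimental channel set with known geometry, at a
default desk scale of 192³ voxels at 1 µm (tests use smaller volumes):

- cells: blue-noise (minimum-distance) seed points, nearest-seed tessellation
  via the Euclidean feature transform; hepatocyte-like 22 µm diameter;
- membrane: Gaussian-smoothed shells where the cell label changes —
  the cortical actin mesh;
- bile canaliculi: tubes (default radius 1.5 µm at desk scale) along the
  edges of the tessellation's interface polygons (triple lines), joined as a
  random spanning tree plus a fraction of loop-closing extras so the network
  is connected and interconnected, qualitatively like the canalicular mesh;
  an optional linear radius gradient along the lobule axis emulates zonation;
- sinusoids: smooth 4 µm-radius tubes wandering along the lobule axis;
- Kupffer cells: sparse star-shaped bodies with 4–6 radial arms;
- depth attenuation: multiplicative logistic factor in z, ≈0.95 at
  `depth - width`, 0.5 at the knee (default 80 µm), ≈0.05 at `depth + width`,
  emulating antibody dropout; the membrane channel is never attenuated when
  emulating the deep-imaging experiment since phalloidin penetrates;
- noise: mixed Poisson–Gaussian, expectation-preserving, off by default.

The phantom does not model optics (no PSF, no spectral bleed-through), real
intensity statistics, or anatomically calibrated network topology — the
source study gives no quantitative BC/sinusoid geometry statistics, so
realism is qualitative by necessity. Tests passing on phantoms therefore
demonstrate that the algorithms recover known structure under controlled
conditions, not that trained models transfer to real tissue.

Registered phantom channel pairs are "computationally mixed" into unpaired
sets by a seeded non-identity permutation of one domain, exactly as paired
experimental stacks are mixed to emulate the unpaired regime.

## Evaluation metrics

Test volumes are partitioned into non-overlapping 128³ cubes (a 640×640×128
stack gives the canonical 25) and each metric is estimated per cube: MSE,
MSLE, MAE, RMSE, PSNR, SSIM, MS-SSIM, cosine similarity, Pearson
correlation, and FID. Numerical choices:

- PSNR uses the maximum of the evaluated ground-truth cube as the peak (the
  definition on the data, not a bit-depth constant); identical images report
  a +inf sentinel.
- MSLE shifts inputs to non-negative (for [-1, 1] data, +1) and applies
  log1p before the squared difference, since the logarithm is undefined on
  negatives and the published definition does not address them.
- SSIM uses a Gaussian window (sigma 1.5, K1 0.01, K2 0.03) over the
  declared data range. MS-SSIM combines contrast-structure terms over up to
  five dyadic scales with the canonical weights, renormalized when the image
  supports fewer scales (each scale needs the 11-point window to fit).
- FID fits Gaussians to per-image feature vectors and evaluates
  `||mu_a-mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2})` with a symmetrized
  matrix square root. The feature extractor is pluggable; the default is a
  seeded random-convolutional extractor (two fixed banks, ReLU, mean/max
  pooling) applied to z slices, and a tiny linear extractor serves in tests.
  Absolute FID values are only comparable within one fixed extractor — true
  for any choice of backbone, learned or random.
- Degenerate inputs (constant images, zero vectors, empty Otsu regions)
  yield sentinel values with warnings, never NaNs, so cube reports keep one
  entry per cube; empty foreground/background regions are reported absent.
- Box-plot summaries are median, Tukey quartiles and min/max whiskers.
- Error heatmaps divide an image into a 9×9 grid (remainders to the last
  blocks) of per-block MSEs; the size-weighted block mean reproduces the
  global MSE exactly.

## Inference

Patch-trained models predict whole volumes by sliding overlapping tiles
(default 50 % overlap); tile predictions are blended with separable
raised-cosine weights (floored at 0.05 and renormalized per voxel) to
suppress the seam artifacts adversarial generators produce at tile borders.
Borders are reflect-padded to tile size and cropped back, so output shape
always equals input shape and an identity model round-trips exactly. 2D
models are applied independently per z slice. Depth profiles are per-slice
arithmetic means with z in µm.

## Morphometry

BC channels are segmented (Otsu by default, hence invariant to affine
intensity rescaling), skeletonized (3D medial axis), and reduced to a graph:
skeleton voxels with exactly two 26-neighbours are chain interiors,
everything else is a node; branches are maximal chains, with isolated cycles
kept as closed branches. Branch arc length uses the anisotropic voxel size;
the local radius is the Euclidean distance transform of the mask sampled on
the skeleton. Terminal spurs shorter than a cutoff (default 2 µm) can be
pruned to stabilize branch statistics. Profiles along the lobule (CV–PV)
axis project skeleton samples onto a user-supplied axis (from phantom ground
truth, or manual landmarks for real data), normalize to [0, 1] and bin
(default 10 bins) with per-bin mean and standard deviation; bins with fewer
than two samples report no sd.

On discrete masks the distance transform overestimates small radii by a
lattice-dependent fraction of a voxel (a radius-2-voxel tube reads ≈2.24),
which is why the gradient-recovery study samples its tubes at 0.5 µm voxels
— matching the regime of the real data, where voxels (0.3 µm) are several
times smaller than the structures measured.

## Desk-scale study conditions

The validation studies (shared by the test suite and the acceptance script)
are sized for a single CPU and are fixed choices, not tuning knobs:

- inversion study: a fixed benchmark phantom (32×96×96), bile-canaliculi
  channel; domain B is the analytic inversion `1 - A`, mixed unpaired; 48
  patches of 32² per domain (75/25 train/held-out), reduced translator
  `c7s1-16, d32, R32 (x3), u16, c7s1-1` with discriminator `C16 - C32 - F1`,
  fake-image history pool of 16, learning rate 5e-4 decaying after half of
  50 epochs. The caller's seed drives initialization and shuffling; the
  dataset is fixed, as the real protocol's training images are. Recovery is
  scored as mean held-out SSIM against the known mapping; the paired U-Net
  baseline runs 15 epochs on the same task at the protocol learning rate.
  The sparse tube channel is used because its inversion is identifiable at
  this scale: with dense membrane texture, a small patch discriminator
  cannot distinguish fabricated-but-plausible texture from the true
  inversion, and roughly half of initializations settle in a
  cycle-consistent scrambling equilibrium — a small-scale instance of the
  known failure modes of cycle-consistent translation.
- deep-tissue study: 64³ phantom with the attenuation knee at half depth
  (32 µm, width 6 µm); a membrane-to-BC translator trained 30 epochs on
  unattenuated unpaired patches, applied slice-wise; shallow/deep mean
  intensities are compared two widths away from the knee on either side.
- morphometry study: straight tube of radius 3 µm and length 55 µm at 1 µm
  voxels; gradient tube 2 to 4 µm over 87.5 µm at 0.5 µm voxels.

## Known limitations

- The backend is CPU numpy: full-resolution 3D training at the published
  scale is out of reach; the architecture and protocol are validated at
  reduced scale and the full token specs are validated for shape, parameter
  structure and forward execution.
- Absolute FID values are not comparable to any published number (extractor
  differs; the published inception variant/weights are unspecified anyway).
- Phantom realism is qualitative; no claim of transfer to real tissue is
  made or tested.
- The cycle-consistent objective can settle in non-corresponding equilibria
  at very small dataset/model scale; the studies' reduced architecture was
  chosen large enough to avoid this regime, and the learning-rate decay
  stabilizes the endpoint.
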