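"""Generator/discriminator construction from compact layer-token strings.

The translation networks are described by token lists in the ResNet-generator /
PatchGAN-discriminator family:

``c7s1-k``  7x7 convolution, stride 1, k filters, instance norm, ReLU
            (tanh instead of norm+ReLU when it is the final token)
``dk``      3x3 convolution, stride 2 (downsampling), instance norm, ReLU
``Rk``      residual block of two 3x3 convolutions with k filters
``uk``      3x3 transposed convolution, stride 2 (upsampling), instance norm, ReLU
``Ck``      4x4 convolution, stride 2, instance norm, LeakyReLU (discriminator)
``F1``      final 4x4 convolution to a 1-channel patch score map

The same token list builds a 2D or a 3D network; only the convolution
dimensionality changes.  A repeat suffix ``Rk (xm)`` expands to ``m``
consecutive residual tokens.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import autograd as ag

#: generator used with 128x128 patches (bile-canaliculi and sinusoid models)
GENERATOR_128 = "c7s1-64, d128, d256, R256 (x6), u128, u64, c7s1-1"
#: generator used with 256x256 patches (Kupffer-cell model)
GENERATOR_256 = "c7s1-64, d128, d256, R256 (x9), u128, u64, c7s1-1"
#: patch discriminator shared by all models
DISCRIMINATOR = "C64 - C128 - C256 - C512 - F1"

_DASHES = "‐‑‒–—-"


class ArchParseError(ValueError):
    pass


@dataclass(frozen=True)
class Token:
    kind: str  # one of {"c7s1", "d", "R", "u", "C", "F"}
    k: int

    def __str__(self):
        return f"c7s1-{self.k}" if self.kind == "c7s1" else f"{self.kind}{self.k}"


@dataclass
class ArchSpec:
    tokens: list[Token]
    dims: int
    in_channels: int
    out_channels: int
    source: str = ""

    @property
    def n_layers(self) -> int:
        return len(self.tokens)

    @property
    def n_downsamples(self) -> int:
        return sum(1 for t in self.tokens if t.kind == "d")

    def to_string(self) -> str:
        return ", ".join(str(t) for t in self.tokens)


_TOKEN_RES = [
    (re.compile(r"^c7s1[" + _DASHES + r"](\d+)$"), "c7s1"),
    (re.compile(r"^d(\d+)$"), "d"),
    (re.compile(r"^u(\d+)$"), "u"),
    (re.compile(r"^R(\d+)(?:\s*\(x(\d+)\))?$"), "R"),
    (re.compile(r"^C(\d+)$"), "C"),
    (re.compile(r"^F(\d+)$"), "F"),
]


def _split_tokens(spec_string: str) -> list[str]:
    if "," in spec_string:
        chunks = [c.strip() for c in spec_string.split(",")]
    else:
        # discriminator style: tokens separated by spaced hyphen/dash characters
        chunks = [c.strip() for c in re.split(r"\s+[" + _DASHES + r"]\s+", spec_string)]
    return [c for c in chunks if c and not all(ch in _DASHES for ch in c)]


def parse_arch_spec(spec_string: str, dims: int = 2, in_channels: int = 1,
                    out_channels: int = 1) -> ArchSpec:
    """Parse a token string into an expanded :class:`ArchSpec`.

    Repeat groups expand in place, e.g. ``R256 (x6)`` becomes six residual
    tokens, so ``n_layers`` counts realized blocks.
    """
    if not spec_string or not spec_string.strip():
        raise ArchParseError("empty architecture specification")
    if dims not in (2, 3):
        raise ArchParseError(f"dims must be 2 or 3, got {dims}")
    tokens: list[Token] = []
    for pos, chunk in enumerate(_split_tokens(spec_string)):
        for pattern, kind in _TOKEN_RES:
            m = pattern.match(chunk)
            if m:
                k = int(m.group(1))
                repeat = int(m.group(2)) if kind == "R" and m.group(2) else 1
                tokens.extend(Token(kind, k) for _ in range(repeat))
                break
        else:
            raise ArchParseError(f"unknown token {chunk!r} at position {pos}")
    return ArchSpec(tokens, dims, in_channels, out_channels, source=spec_string)


# --------------------------------------------------------------------- handle
class NetworkHandle:
    """A built network plus its metadata; forward maps numpy -> numpy."""

    def __init__(self, module: nn.Module, dims: int, spec: ArchSpec | None,
                 kind: str, in_channels: int, out_channels: int,
                 size_divisor: int = 1, meta: dict | None = None):
        self.module = module
        self.dims = dims
        self.spec = spec
        self.kind = kind  # "generator" | "discriminator" | "unet"
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.size_divisor = size_divisor
        self.meta = meta or {}

    @property
    def n_parameters(self) -> int:
        return self.module.n_parameters()

    def _check_input(self, x: np.ndarray):
        spatial = x.shape[2:]
        if len(spatial) != self.dims:
            raise ValueError(f"{self.kind} is {self.dims}D but input has "
                             f"{len(spatial)} spatial axes")
        if self.kind != "discriminator":
            for edge in spatial:
                if edge % self.size_divisor:
                    raise ValueError(
                        f"input edge {edge} not divisible by {self.size_divisor}: the "
                        f"stride-2 stages cannot be inverted exactly")

    def forward_tensor(self, x: ag.Tensor) -> ag.Tensor:
        self._check_input(x.data)
        return self.module(x)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass on a batched or unbatched numpy array."""
        x = np.asarray(x, dtype=np.float32)
        unbatched = x.ndim == self.dims
        if unbatched:
            x = x[None, None]
        elif x.ndim == self.dims + 1:
            x = x[None]
        with ag.no_grad():
            out = self.forward_tensor(ag.Tensor(x)).data
        if unbatched:
            out = out[0, 0]
        return out

    def parameters(self):
        return self.module.parameters()


def build_generator(spec: ArchSpec, seed: int = 0) -> NetworkHandle:
    """Build a shape-preserving residual translation generator.

    The final activation is tanh so outputs live in the [-1, 1] range of the
    normalized data.  Inputs must have spatial edges divisible by
    ``2**n_downsamples`` so the up path inverts the down path exactly.
    """
    rng = np.random.default_rng(seed)
    dims = spec.dims
    layers: list[nn.Module] = []
    in_ch = spec.in_channels
    for i, tok in enumerate(spec.tokens):
        last = i == len(spec.tokens) - 1
        if tok.kind == "c7s1":
            out_ch = spec.out_channels if last else tok.k
            layers.append(nn.Conv(dims, in_ch, out_ch, 7, 1, 3, "reflect", rng=rng))
            if last:
                layers.append(nn.Tanh())
            else:
                layers += [nn.InstanceNorm(out_ch, dims), nn.ReLU()]
            in_ch = out_ch
        elif tok.kind == "d":
            layers.append(nn.Conv(dims, in_ch, tok.k, 3, 2, 1, "zeros", rng=rng))
            layers += [nn.InstanceNorm(tok.k, dims), nn.ReLU()]
            in_ch = tok.k
        elif tok.kind == "R":
            if tok.k != in_ch:
                raise ArchParseError(f"residual block R{tok.k} after {in_ch} channels")
            layers.append(nn.ResidualBlock(dims, tok.k, "reflect", rng=rng))
        elif tok.kind == "u":
            layers.append(nn.ConvTranspose(dims, in_ch, tok.k, 3, 2, 1, 1, rng=rng))
            layers += [nn.InstanceNorm(tok.k, dims), nn.ReLU()]
            in_ch = tok.k
        else:
            raise ArchParseError(f"token {tok} not valid in a generator")
    module = nn.Sequential(*layers)
    return NetworkHandle(module, dims, spec, "generator", spec.in_channels,
                         spec.out_channels, size_divisor=2 ** spec.n_downsamples)


def build_discriminator(spec: ArchSpec, seed: int = 0,
                        norm_first_block: bool = True) -> NetworkHandle:
    """Build a patch discriminator returning a spatially reduced score map.

    ``norm_first_block=False`` gives the conventional variant that skips
    instance norm on the first C block.
    """
    if not spec.tokens or spec.tokens[-1].kind != "F":
        raise ArchParseError("discriminator spec must end with an F token")
    rng = np.random.default_rng(seed)
    dims = spec.dims
    layers: list[nn.Module] = []
    in_ch = spec.in_channels
    for i, tok in enumerate(spec.tokens):
        if tok.kind == "C":
            layers.append(nn.Conv(dims, in_ch, tok.k, 4, 2, 1, "zeros", rng=rng))
            if norm_first_block or i > 0:
                layers.append(nn.InstanceNorm(tok.k, dims))
            layers.append(nn.LeakyReLU(0.2))
            in_ch = tok.k
        elif tok.kind == "F":
            layers.append(nn.Conv(dims, in_ch, tok.k, 4, 1, 1, "zeros", rng=rng))
            in_ch = tok.k
        else:
            raise ArchParseError(f"token {tok} not valid in a discriminator")
    module = nn.Sequential(*layers)
    return NetworkHandle(module, dims, spec, "discriminator", spec.in_channels,
                         in_ch)


class _UNet(nn.Module):
    def __init__(self, dims, in_ch, out_ch, depth, base, rng):
        def block(ci, co):
            return nn.Sequential(
                nn.Conv(dims, ci, co, 3, 1, 1, "zeros", rng=rng),
                nn.InstanceNorm(co, dims), nn.ReLU(),
                nn.Conv(dims, co, co, 3, 1, 1, "zeros", rng=rng),
                nn.InstanceNorm(co, dims), nn.ReLU(),
            )

        self.dims = dims
        self.enc = []
        ch = in_ch
        for level in range(depth):
            co = base * 2 ** level
            self.enc.append(block(ch, co))
            ch = co
        self.downs = [nn.Conv(dims, base * 2 ** i, base * 2 ** i, 3, 2, 1, "zeros", rng=rng)
                      for i in range(depth)]
        self.bottleneck = block(ch, ch * 2)
        self.ups = []
        self.dec = []
        for level in reversed(range(depth)):
            co = base * 2 ** level
            self.ups.append(nn.ConvTranspose(dims, co * 2, co, 3, 2, 1, 1, rng=rng))
            self.dec.append(block(co * 2, co))  # skip concat doubles the input
        self.final = nn.Conv(dims, base, out_ch, 1, 1, 0, "zeros", rng=rng)

    def forward(self, x):
        skips = []
        for enc, down in zip(self.enc, self.downs):
            x = enc(x)
            skips.append(x)
            x = down(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up(x)
            x = dec(ag.concat([skip, x], axis=1))
        return ag.tanh(self.final(x))


def build_unet(dims: int, in_channels: int = 1, out_channels: int = 1,
               depth: int = 4, base_filters: int = 64, seed: int = 0) -> NetworkHandle:
    """Paired-baseline U-Net: encoder-decoder with skip connections, tanh output.

    Input edges must be divisible by ``2**depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    module = _UNet(dims, in_channels, out_channels, depth, base_filters, rng)
    handle = NetworkHandle(module, dims, None, "unet", in_channels, out_channels,
                           size_divisor=2 ** depth,
                           meta={"depth": depth, "base_filters": base_filters})
    return handle


# ----------------------------------------------------------------- checkpoints
def save_checkpoint(handle: NetworkHandle, path: str | Path):
    """Self-describing checkpoint: parameters plus the architecture metadata."""
    path = Path(path)
    meta = {
        "kind": handle.kind,
        "dims": handle.dims,
        "in_channels": handle.in_channels,
        "out_channels": handle.out_channels,
        "spec": handle.spec.source if handle.spec else None,
        "meta": handle.meta,
    }
    state = handle.module.named_state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> NetworkHandle:
    path = Path(path)
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    kind, dims = meta["kind"], meta["dims"]
    if kind == "generator":
        spec = parse_arch_spec(meta["spec"], dims, meta["in_channels"], meta["out_channels"])
        handle = build_generator(spec)
    elif kind == "discriminator":
        spec = parse_arch_spec(meta["spec"], dims, meta["in_channels"], meta["out_channels"])
        handle = build_discriminator(spec)
    elif kind == "unet":
        handle = build_unet(dims, meta["in_channels"], meta["out_channels"],
                            meta["meta"]["depth"], meta["meta"]["base_filters"])
    else:  # pragma: no cover - corrupted file
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    handle.module.load_state(state)
    return handle


def derive_seed(seed: int, stage: str) -> int:
    """Derive a decoupled per-stage RNG seed from a global seed."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2 ** 31)
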