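"""Convolutional backbones exposing named per-layer activations.

Two backbones are provided behind one interface:

``vgg19``
    The standard 16-conv-layer / 5-block VGG19 architecture with FC6/FC7
    (4096 units each).  The architecture is always available — the level
    sizes of the deep-feature sets are pure bookkeeping over it — and a
    forward pass runs when a weights file (``.npz`` with ``<layer>_W`` /
    ``<layer>_b`` arrays) is supplied.

``fixture``
    A small three-block network (4/8/16 kernels, two 32-unit fc layers)
    whose weights are generated deterministically from a seed.  The
    feature-extraction mechanism (per-channel max/avg pooling, level
    concatenation, l2-normalization) is weight-agnostic, so the whole
    pipeline exercises on this backbone with no external artifacts.

The forward engine is plain numpy: 3x3 same-padding convolutions + ReLU,
2x2 max-pooling after each block, dense ReLU layers on the flattened
final feature map.  Layer names follow the CONV<block>_<layer> / FC6 /
FC7 scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

__all__ = [
    "BackboneSpec",
    "ActivationBundle",
    "get_spec",
    "vgg19_spec",
    "fixture_spec",
    "fixture_weights",
    "load_weights_npz",
    "preprocess_roi",
    "forward_activations",
]

# ImageNet channel means on the 0-255 scale (RGB order), the native VGG
# input normalization.
_IMAGENET_MEANS = np.array([123.68, 116.779, 103.939])

FIXTURE_WEIGHT_SEED = 20201130  # recorded seed: fixture weights are a constant of the package


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture description: named conv layers grouped in blocks, fc layers."""

    name: str
    conv_layers: tuple[tuple[str, str, int], ...]  # (layer_name, block_name, kernel_count)
    fc_layers: tuple[tuple[str, int], ...]  # (layer_name, unit_count)
    input_size: tuple[int, int, int]  # (height, width, channels)

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.conv_layers] + [n for n, _ in self.fc_layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    @property
    def blocks(self) -> list[str]:
        """Block names in network order."""
        seen: list[str] = []
        for _, b, _ in self.conv_layers:
            if b not in seen:
                seen.append(b)
        return seen

    def block_layers(self, block: str) -> list[tuple[str, int]]:
        return [(n, k) for n, b, k in self.conv_layers if b == block]

    def kernel_count(self, layer_name: str) -> int:
        for n, _, k in self.conv_layers:
            if n == layer_name:
                return k
        raise KeyError(f"unknown conv layer {layer_name!r}")

    def fc_units(self, layer_name: str) -> int:
        for n, u in self.fc_layers:
            if n == layer_name:
                return u
        raise KeyError(f"unknown fc layer {layer_name!r}")

    @property
    def conv_layer_names(self) -> list[str]:
        return [n for n, _, _ in self.conv_layers]

    @property
    def fc_layer_names(self) -> list[str]:
        return [n for n, _ in self.fc_layers]


def vgg19_spec() -> BackboneSpec:
    """The VGG19 architecture: 16 conv layers in 5 blocks, FC6/FC7 with 4096 units."""
    layers_per_block = [(1, 2, 64), (2, 2, 128), (3, 4, 256), (4, 4, 512), (5, 4, 512)]
    conv = tuple(
        (f"CONV{b}_{l}", f"CONV{b}", n)
        for b, count, n in layers_per_block
        for l in range(1, count + 1)
    )
    return BackboneSpec(
        name="vgg19",
        conv_layers=conv,
        fc_layers=(("FC6", 4096), ("FC7", 4096)),
        input_size=(224, 224, 3),
    )


def fixture_spec() -> BackboneSpec:
    """Small deterministic test network: 3 blocks of 2 layers (4/8/16 kernels)."""
    layers_per_block = [(1, 2, 4), (2, 2, 8), (3, 2, 16)]
    conv = tuple(
        (f"CONV{b}_{l}", f"CONV{b}", n)
        for b, count, n in layers_per_block
        for l in range(1, count + 1)
    )
    return BackboneSpec(
        name="fixture",
        conv_layers=conv,
        fc_layers=(("FC6", 32), ("FC7", 32)),
        input_size=(64, 64, 3),
    )


def get_spec(name: str) -> BackboneSpec:
    if name == "vgg19":
        return vgg19_spec()
    if name == "fixture":
        return fixture_spec()
    raise ValueError(f"unknown backbone {name!r} (expected 'vgg19' or 'fixture')")


@dataclass
class ActivationBundle:
    """Named activations: H x W x N arrays per conv layer, vectors per fc layer."""

    conv: dict[str, np.ndarray] = field(default_factory=dict)
    fc: dict[str, np.ndarray] = field(default_factory=dict)


def fixture_weights(spec: BackboneSpec, seed: int = FIXTURE_WEIGHT_SEED) -> dict:
    """He-scaled random weights for ``spec``, reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    weights: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    c_in = spec.input_size[2]
    h = w = None
    h, w = spec.input_size[:2]
    for name, _block, n in spec.conv_layers:
        scale = np.sqrt(2.0 / (9 * c_in))
        weights[name] = (rng.normal(0, scale, size=(n, c_in, 3, 3)), rng.normal(0, 0.1, size=n))
        c_in = n
    # spatial size after per-block 2x2 pooling
    n_blocks = len(spec.blocks)
    fh, fw = h // (2**n_blocks), w // (2**n_blocks)
    in_dim = fh * fw * c_in
    for name, units in spec.fc_layers:
        scale = np.sqrt(2.0 / in_dim)
        weights[name] = (rng.normal(0, scale, size=(units, in_dim)), rng.normal(0, 0.1, size=units))
        in_dim = units
    return weights


def load_weights_npz(path: str | Path) -> dict:
    """Load backbone weights from an .npz with ``<layer>_W`` / ``<layer>_b`` arrays."""
    data = np.load(path)
    names = {k[:-2] for k in data.files if k.endswith("_W")}
    return {n: (data[f"{n}_W"], data[f"{n}_b"]) for n in names}


def preprocess_roi(roi, spec: BackboneSpec) -> np.ndarray:
    """Resize the ROI to the backbone input size and replicate channels.

    Bilinear resize (aspect ratio not preserved), grayscale replicated
    across the three channels, then the backbone-native normalization:
    for VGG19 the ROI is rescaled to [0, 255] and the ImageNet channel
    means subtracted; for the fixture network the ROI is rescaled to
    [0, 1].  A constant ROI maps to the zero tensor before mean removal.
    """
    pixels = np.asarray(roi.pixels if hasattr(roi, "pixels") else roi, dtype=float)
    if pixels.shape[0] < 8 or pixels.shape[1] < 8:
        raise ValueError(f"ROI too small: {pixels.shape} (minimum 8x8)")
    h, w, c = spec.input_size
    lo, hi = pixels.min(), pixels.max()
    unit = np.zeros_like(pixels) if hi == lo else (pixels - lo) / (hi - lo)
    resized = resize(unit, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    tensor = np.repeat(resized[:, :, None], c, axis=2)
    if spec.name == "vgg19":
        tensor = tensor * 255.0 - _IMAGENET_MEANS[: c]
    return tensor


def _conv3x3_relu(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution + ReLU.  x: H x W x Cin, W: N x Cin x 3 x 3."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    windows = sliding_window_view(xp, (3, 3), axis=(0, 1))  # H x W x Cin x 3 x 3
    out = np.einsum("hwcij,ncij->hwn", windows, W, optimize=True) + b
    return np.maximum(out, 0.0)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    x = x[: h - h % 2, : w - w % 2]
    return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


def forward_activations(
    tensor: np.ndarray,
    spec: BackboneSpec,
    layer_names: list[str],
    weights: dict | None = None,
) -> ActivationBundle:
    """Run the network and return activations for exactly ``layer_names``.

    Deterministic for fixed weights and input.  For the fixture backbone
    weights default to the seeded constants; for VGG19 a weights mapping
    (see :func:`load_weights_npz`) must be supplied.
    """
    known = set(spec.conv_layer_names) | set(spec.fc_layer_names)
    unknown = [n for n in layer_names if n not in known]
    if unknown:
        raise KeyError(f"unknown layer(s) {unknown} for backbone {spec.name!r}")
    if weights is None:
        if spec.name == "fixture":
            weights = fixture_weights(spec)
        else:
            raise RuntimeError(
                f"backbone {spec.name!r} needs a weights mapping (load_weights_npz)"
            )
    expected = tuple(spec.input_size)
    if tensor.shape != expected:
        raise ValueError(f"input tensor shape {tensor.shape} != spec input {expected}")
    wanted = set(layer_names)
    need_fc = any(n in wanted for n in spec.fc_layer_names)
    bundle = ActivationBundle()
    x = tensor
    last_conv = max(
        (i for i, (n, _, _) in enumerate(spec.conv_layers) if n in wanted), default=-1
    )
    blocks = spec.blocks
    li = 0
    for block in blocks:
        for name, _k in spec.block_layers(block):
            W, b = weights[name]
            x = _conv3x3_relu(x, W, b)
            if name in wanted:
                if not np.all(np.isfinite(x)):
                    raise FloatingPointError(f"non-finite activation in {name}")
                bundle.conv[name] = x.copy()
            li += 1
            if not need_fc and li > last_conv:
                # remaining layers influence nothing that was requested
                pass
        x = _maxpool2(x)
        if not need_fc and li > last_conv:
            break
    if need_fc:
        v = x.reshape(-1)
        for name, _units in spec.fc_layers:
            W, b = weights[name]
            v = np.maximum(W @ v + b, 0.0)
            if name in wanted:
                bundle.fc[name] = v.copy()
    return bundle
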