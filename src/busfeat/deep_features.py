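"""Assemble deep-feature sets from backbone activations.

Each conv layer of size W x H x N is summarized into a 2N vector: the
per-channel spatial maxima followed by the per-channel spatial means.
Six extraction levels assemble these summaries (and the fc activations)
into named feature sets:

================  ==========================================================
``CF1``           one l2-normalized 2N set per conv layer
``CF2``           per block, concatenation of its (normalized) layer sets,
                  renormalized
``CF3``           concatenation of all block sets, renormalized
``FCF1``          one normalized activation vector per fc layer
``FCF2``          concatenation of the FCF1 sets, renormalized
``CF_FCF``        concatenation of the CF3 and FCF2 constituents, renormalized
================  ==========================================================

For VGG19 this yields 11,008 conv features at CF3, 8,192 fc features at
FCF2 and 19,200 combined features.  Normalization is applied per layer
set first and again after every concatenation; SVM classification is
scale-sensitive, so this nesting order is fixed.

Feature names carry full provenance (``CONV5_4:max:13``, ``FC6:201``) so
that a selected feature maps back to its layer, pooling type and channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .backbone import ActivationBundle, BackboneSpec

__all__ = [
    "FeatureSet",
    "pool_layer",
    "l2_normalize",
    "build_level",
    "level_size",
    "LEVELS",
]

LEVELS = ("CF1", "CF2", "CF3", "FCF1", "FCF2", "CF_FCF")


@dataclass
class FeatureSet:
    """Named, ordered feature vector with a level tag."""

    values: np.ndarray
    names: list[str]
    level_tag: str
    zero_norm: bool = False  # set when the vector could not be normalized

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError("values and names must be 1-D and of equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)


def pool_layer(cl: np.ndarray) -> np.ndarray:
    """Per-channel max then per-channel mean of a W x H x N activation.

    Returns a 2N vector: entries 0..N-1 are the channel maxima, entries
    N..2N-1 the channel means, both in channel order.
    """
    cl = np.asarray(cl, dtype=float)
    if cl.ndim != 3:
        raise ValueError(f"expected a 3-D activation, got shape {cl.shape}")
    if not np.all(np.isfinite(cl)):
        raise ValueError("activation contains non-finite values")
    return np.concatenate([cl.max(axis=(0, 1)), cl.mean(axis=(0, 1))])


def l2_normalize(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale ``v`` to unit Euclidean norm.

    The zero vector is returned unchanged with the flag set (and a
    warning), since it carries no direction to normalize.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        warnings.warn("l2_normalize: zero vector left unchanged", stacklevel=2)
        return v.copy(), True
    return v / norm, False


def _layer_set(bundle: ActivationBundle, spec: BackboneSpec, layer: str) -> FeatureSet:
    if layer not in bundle.conv:
        raise KeyError(f"activation bundle is missing conv layer {layer!r}")
    pooled = pool_layer(bundle.conv[layer])
    n = spec.kernel_count(layer)
    names = [f"{layer}:max:{k}" for k in range(n)] + [f"{layer}:avg:{k}" for k in range(n)]
    values, flag = l2_normalize(pooled)
    return FeatureSet(values=values, names=names, level_tag=f"CF1:{layer}", zero_norm=flag)


def _fc_set(bundle: ActivationBundle, spec: BackboneSpec, layer: str) -> FeatureSet:
    if layer not in bundle.fc:
        raise KeyError(f"activation bundle is missing fc layer {layer!r}")
    v = np.asarray(bundle.fc[layer], dtype=float)
    if len(v) != spec.fc_units(layer):
        raise ValueError(f"fc activation length {len(v)} != spec units for {layer}")
    values, flag = l2_normalize(v)
    names = [f"{layer}:{k}" for k in range(len(v))]
    return FeatureSet(values=values, names=names, level_tag=f"FCF1:{layer}", zero_norm=flag)


def _concat(sets: list[FeatureSet], tag: str) -> FeatureSet:
    values = np.concatenate([s.values for s in sets])
    names = [n for s in sets for n in s.names]
    values, flag = l2_normalize(values)
    return FeatureSet(values=values, names=names, level_tag=tag, zero_norm=flag)


def build_level(
    bundle: ActivationBundle, spec: BackboneSpec, level_tag: str
) -> FeatureSet | list[FeatureSet]:
    """Assemble the feature set(s) of one extraction level from a bundle.

    ``CF1`` and ``FCF1`` return a list (one set per layer, network
    order); the other levels return a single concatenated, renormalized
    set.
    """
    if level_tag == "CF1":
        return [_layer_set(bundle, spec, n) for n in spec.conv_layer_names]
    if level_tag == "CF2":
        return [
            _concat(
                [_layer_set(bundle, spec, n) for n, _ in spec.block_layers(block)],
                f"CF2:{block}",
            )
            for block in spec.blocks
        ]
    if level_tag == "CF3":
        return _concat(
            [_layer_set(bundle, spec, n) for n in spec.conv_layer_names], "CF3"
        )
    if level_tag == "FCF1":
        return [_fc_set(bundle, spec, n) for n in spec.fc_layer_names]
    if level_tag == "FCF2":
        return _concat([_fc_set(bundle, spec, n) for n in spec.fc_layer_names], "FCF2")
    if level_tag == "CF_FCF":
        conv_sets = [_layer_set(bundle, spec, n) for n in spec.conv_layer_names]
        fc_sets = [_fc_set(bundle, spec, n) for n in spec.fc_layer_names]
        return _concat(conv_sets + fc_sets, "CF_FCF")
    raise ValueError(f"unknown level {level_tag!r} (expected one of {LEVELS})")


def level_size(spec: BackboneSpec, level_tag: str) -> int | list[int]:
    """Feature-count bookkeeping from the architecture alone (no forward pass).

    CF1/FCF1 return the per-set sizes; the concatenated levels return a
    single total.
    """
    conv2n = [2 * k for _, _, k in spec.conv_layers]
    fc_units = [u for _, u in spec.fc_layers]
    if level_tag == "CF1":
        return conv2n
    if level_tag == "CF2":
        return [sum(2 * k for _, k in spec.block_layers(b)) for b in spec.blocks]
    if level_tag == "CF3":
        return sum(conv2n)
    if level_tag == "FCF1":
        return fc_units
    if level_tag == "FCF2":
        return sum(fc_units)
    if level_tag == "CF_FCF":
        return sum(conv2n) + sum(fc_units)
    raise ValueError(f"unknown level {level_tag!r}")
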