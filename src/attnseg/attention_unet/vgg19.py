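"""Canonical VGG19 layer registry and exact parameter accounting.

The classifier handle is registry-only (no weight arrays are allocated):
its purpose here is exact architecture bookkeeping — 16 convolutional
layers, 3 fully connected layers (19 weight-bearing layers), 5 max-pools
and a softmax, totalling 143,667,240 trainable parameters for 3-channel
224x224 input.  Discarding the FC stack leaves the 20,024,384-parameter
convolutional feature extractor reused by the segmenter's encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: number of 3x3 convolutions per block and their output channels
VGG19_CONV_BLOCKS = (2, 2, 4, 4, 4)
VGG19_CHANNELS = (64, 128, 256, 512, 512)

#: FC widths of the ImageNet classifier head
VGG19_FC = (4096, 4096, 1000)


@dataclass(frozen=True)
class LayerInfo:
    """One registry entry: layer kind, name, and exact parameter count."""

    name: str
    kind: str  # conv | relu | maxpool | fc | softmax | flatten
    param_count: int
    out_shape: tuple  # (C, H, W) or (features,)


class VGG19Classifier:
    """Registry handle for the standard VGG19 ImageNet configuration."""

    def __init__(self, registry: list[LayerInfo], pretrained: bool = False):
        self.registry = registry
        self.pretrained = pretrained

    def layers(self, kind: str | None = None) -> list[LayerInfo]:
        if kind is None:
            return list(self.registry)
        return [l for l in self.registry if l.kind == kind]

    @property
    def num_conv_layers(self) -> int:
        return len(self.layers("conv"))

    @property
    def num_fc_layers(self) -> int:
        return len(self.layers("fc"))

    @property
    def num_weight_layers(self) -> int:
        return self.num_conv_layers + self.num_fc_layers

    def parameter_count(self, kinds: tuple[str, ...] | None = None) -> int:
        layers = self.registry if kinds is None else [
            l for l in self.registry if l.kind in kinds
        ]
        return sum(l.param_count for l in layers)


def conv_param_count(in_channels: int, out_channels: int, kernel: int = 3) -> int:
    """k*k*c_in*c_out weights + c_out biases."""
    return kernel * kernel * in_channels * out_channels + out_channels


def fc_param_count(in_features: int, out_features: int) -> int:
    return in_features * out_features + out_features


def build_vgg19_classifier(
    pretrained: bool = False,
    in_channels: int = 3,
    input_size: int = 224,
    weights_path: str | None = None,
) -> VGG19Classifier:
    """Construct the standard VGG19 ImageNet classifier registry.

    Conv blocks (2, 2, 4, 4, 4) with channels (64, 128, 256, 512, 512),
    all 3x3 same-padding with bias, each block closed by a 2x2/stride-2
    max-pool; then FC 4096-4096-1000 and a softmax.  ``pretrained`` is an
    optional hook: it requires a caller-supplied ``weights_path`` (no
    weight values ship with the package).
    """
    if pretrained and weights_path is None:
        raise ValueError(
            "pretrained=True needs weights_path; no ImageNet weights are bundled"
        )
    registry: list[LayerInfo] = []
    c_in, hw = in_channels, input_size
    for b, (n_convs, c_out) in enumerate(zip(VGG19_CONV_BLOCKS, VGG19_CHANNELS), 1):
        for k in range(1, n_convs + 1):
            registry.append(
                LayerInfo(
                    name=f"block{b}_conv{k}",
                    kind="conv",
                    param_count=conv_param_count(c_in, c_out),
                    out_shape=(c_out, hw, hw),
                )
            )
            registry.append(
                LayerInfo(f"block{b}_relu{k}", "relu", 0, (c_out, hw, hw))
            )
            c_in = c_out
        hw //= 2
        registry.append(LayerInfo(f"block{b}_pool", "maxpool", 0, (c_out, hw, hw)))
    feat = c_in * hw * hw
    registry.append(LayerInfo("flatten", "flatten", 0, (feat,)))
    f_in = feat
    for i, f_out in enumerate(VGG19_FC, 1):
        registry.append(
            LayerInfo(f"fc{i}", "fc", fc_param_count(f_in, f_out), (f_out,))
        )
        if i < len(VGG19_FC):
            registry.append(LayerInfo(f"fc{i}_relu", "relu", 0, (f_out,)))
        f_in = f_out
    registry.append(LayerInfo("softmax", "softmax", 0, (VGG19_FC[-1],)))
    return VGG19Classifier(registry, pretrained=pretrained)


def conv_stack_parameter_count(
    in_channels: int = 3, width_factor: float = 1.0
) -> int:
    """Closed-form parameter count of the VGG19 conv stack (no FC layers)."""
    total, c_in = 0, in_channels
    for n_convs, c_out in zip(VGG19_CONV_BLOCKS, VGG19_CHANNELS):
        c_out = max(1, round(c_out * width_factor))
        for _ in range(n_convs):
            total += conv_param_count(c_in, c_out)
            c_in = c_out
    return total


def count_parameters(network) -> int:
    """Exact count of trainable scalars in a handle or a live network.

    Accepts a :class:`VGG19Classifier` registry handle or any object
    exposing ``parameters() -> [(name, Parameter), ...]``.
    """
    if isinstance(network, VGG19Classifier):
        return network.parameter_count()
    if hasattr(network, "parameters"):
        return int(sum(p.size for _, p in network.parameters()))
    raise TypeError(f"cannot count parameters of {type(network)!r}")
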