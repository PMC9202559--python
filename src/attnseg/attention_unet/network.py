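"""The segmentation network: VGG19 conv encoder, attention-gated decoder.

The encoder is the VGG19 convolutional stack (FC layers discarded) with
batch norm after every convolution, accepting an arbitrary channel count
and an optional ``width_factor`` that scales every block's width for
desk-scale runs.  The decoder mirrors the encoder with five upsampling
stages; each stage gates its skip connection through a spatial-softmax
attention gate before concatenation.  A 1x1 convolution and per-pixel
softmax produce K class probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from attnseg.attention_unet.attention import AttentionGate
from attnseg.attention_unet.layers import (
    Conv2d,
    ConvBNReLU,
    MaxPool2d,
    Parameter,
    UpsampleNearest2x,
)
from attnseg.attention_unet.losses import softmax
from attnseg.attention_unet.vgg19 import VGG19_CHANNELS, VGG19_CONV_BLOCKS


@dataclass(frozen=True)
class NetworkConfig:
    input_size: int = 224
    in_channels: int = 4
    num_classes: int = 4
    width_factor: float = 1.0
    pretrained_encoder: bool = False
    attention_enabled: bool = True

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0 or self.input_size < 32:
            raise ValueError(
                f"input_size must be a positive multiple of 32 (5 pooling stages), "
                f"got {self.input_size}"
            )
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0 < self.width_factor <= 1:
            raise ValueError("width_factor must be in (0, 1]")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")

    def block_widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(c * self.width_factor)) for c in VGG19_CHANNELS)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        return cls(**json.loads(text))


class _EncoderBlock:
    def __init__(self, n_convs: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.units = []
        for _ in range(n_convs):
            self.units.append(ConvBNReLU(c_in, c_out, rng))
            c_in = c_out
        self.pool = MaxPool2d()

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, np.ndarray]:
        for unit in self.units:
            x = unit.forward(x, training)
        return x, self.pool.forward(x)

    def backward(self, dpooled: np.ndarray, dskip: np.ndarray) -> np.ndarray:
        g = self.pool.backward(dpooled) + dskip
        for unit in reversed(self.units):
            g = unit.backward(g)
        return g


class _DecoderStage:
    def __init__(
        self,
        c_in: int,
        c_skip: int,
        c_out: int,
        attention: bool,
        rng: np.random.Generator,
    ):
        self.up = UpsampleNearest2x()
        self.attention = attention
        if attention:
            self.gate = AttentionGate(c_skip, c_in, max(1, c_skip // 2), rng)
        self.conv1 = ConvBNReLU(c_in + c_skip, c_out, rng)
        self.conv2 = ConvBNReLU(c_out, c_out, rng)
        self.c_in = c_in
        self.c_skip = c_skip

    def forward(self, d: np.ndarray, skip: np.ndarray, training: bool) -> np.ndarray:
        up = self.up.forward(d)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"decoder/skip spatial mismatch: {up.shape} vs {skip.shape}"
            )
        gated = self.gate.forward(skip, up) if self.attention else skip
        cat = np.concatenate([up, gated], axis=1)
        return self.conv2.forward(self.conv1.forward(cat, training), training)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dcat = self.conv1.backward(self.conv2.backward(dout))
        dup = dcat[:, : self.c_in]
        dgated = dcat[:, self.c_in :]
        if self.attention:
            dskip, dup_gate = self.gate.backward(dgated)
            dup = dup + dup_gate
        else:
            dskip = dgated
        return self.up.backward(dup), dskip


class AttentionUNet:
    """Live, trainable network (NumPy forward/backward)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        if config.pretrained_encoder:
            raise ValueError(
                "no pretrained encoder weights are bundled; load a checkpoint instead"
            )
        self.config = config
        rng = np.random.default_rng(seed)
        widths = config.block_widths()

        self.encoder: list[_EncoderBlock] = []
        c_in = config.in_channels
        for n_convs, c_out in zip(VGG19_CONV_BLOCKS, widths):
            self.encoder.append(_EncoderBlock(n_convs, c_in, c_out, rng))
            c_in = c_out

        # decoder stages fuse skips deepest-first: widths[4] ... widths[0]
        self.decoder: list[_DecoderStage] = []
        c_dec = widths[4]
        for i in range(4, -1, -1):
            self.decoder.append(
                _DecoderStage(c_dec, widths[i], widths[i], config.attention_enabled, rng)
            )
            c_dec = widths[i]
        self.head = Conv2d(widths[0], config.num_classes, 1, rng=rng)
        self._skip_shapes = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for b, block in enumerate(self.encoder, 1):
            for u, unit in enumerate(block.units, 1):
                out.extend(
                    (f"enc{b}.unit{u}.{n}", p) for n, p in unit.parameters()
                )
        for s, stage in enumerate(self.decoder, 1):
            if stage.attention:
                out.extend((f"dec{s}.gate.{n}", p) for n, p in stage.gate.parameters())
            out.extend((f"dec{s}.conv1.{n}", p) for n, p in stage.conv1.parameters())
            out.extend((f"dec{s}.conv2.{n}", p) for n, p in stage.conv2.parameters())
        out.extend((f"head.{n}", p) for n, p in self.head.parameters())
        return out

    def encoder_parameters(self) -> list[tuple[str, Parameter]]:
        return [(n, p) for n, p in self.parameters() if n.startswith("enc")]

    def layer_registry(self) -> list[tuple[str, int]]:
        """(name, parameter count) per trainable tensor, in graph order."""
        return [(n, p.size) for n, p in self.parameters()]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"spatial dims must be multiples of 32, got {x.shape[2:]}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for block in self.encoder:
            skip, x = block.forward(x, training)
            skips.append(skip)
        d = x  # bottleneck
        for stage, i in zip(self.decoder, range(4, -1, -1)):
            d = stage.forward(d, skips[i], training)
        return self.head.forward(d)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        skip_grads: dict[int, np.ndarray] = {}
        for stage, i in zip(reversed(self.decoder), range(0, 5)):
            g, dskip = stage.backward(g)
            skip_grads[i] = dskip
        for b in range(4, -1, -1):
            g = self.encoder[b].backward(g, skip_grads[b])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities, (N, K, H, W), summing to 1 per pixel."""
        return softmax(self.forward(x, training=False), axis=1)

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value for name, p in self.parameters()}
        for b, block in enumerate(self.encoder, 1):
            for u, unit in enumerate(block.units, 1):
                state[f"enc{b}.unit{u}.bn.running_mean"] = unit.bn.running_mean
                state[f"enc{b}.unit{u}.bn.running_var"] = unit.bn.running_var
        for s, stage in enumerate(self.decoder, 1):
            for cname, unit in (("conv1", stage.conv1), ("conv2", stage.conv2)):
                state[f"dec{s}.{cname}.bn.running_mean"] = unit.bn.running_mean
                state[f"dec{s}.{cname}.bn.running_var"] = unit.bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.parameters())
        for name, value in state.items():
            if name in params:
                if params[name].value.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].value.shape} vs {value.shape}"
                    )
                params[name].value[...] = value
        for b, block in enumerate(self.encoder, 1):
            for u, unit in enumerate(block.units, 1):
                unit.bn.running_mean[...] = state[f"enc{b}.unit{u}.bn.running_mean"]
                unit.bn.running_var[...] = state[f"enc{b}.unit{u}.bn.running_var"]
        for s, stage in enumerate(self.decoder, 1):
            for cname, unit in (("conv1", stage.conv1), ("conv2", stage.conv2)):
                unit.bn.running_mean[...] = state[f"dec{s}.{cname}.bn.running_mean"]
                unit.bn.running_var[...] = state[f"dec{s}.{cname}.bn.running_var"]


def build_segmenter(config: NetworkConfig | None = None, seed: int = 0) -> AttentionUNet:
    """Construct an :class:`AttentionUNet` from ``config`` (defaults if None)."""
    return AttentionUNet(config or NetworkConfig(), seed=seed)
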