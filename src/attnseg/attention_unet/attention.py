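"""Spatial-softmax attention gate.

Scores per location j combine the encoder feature e_j with the decoder
state o (already brought to e's grid):

    f_j = V^T tanh(U e_j + W o_j)

The weights are the softmax of the scores over all spatial locations, so
alpha_j >= 0 and sum_j alpha_j = 1.  The context vector is the weighted
feature sum C = sum_j alpha_j e_j; the gated skip rescales alpha by the
location count n so a uniform attention map leaves e unchanged:
gated = (n * alpha) (x) e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from attnseg.attention_unet.layers import Conv2d, Layer, Parameter


@dataclass(frozen=True)
class AttentionGateParams:
    """Learned transforms: U maps e, W maps o into a shared d-dim space;
    v projects that space to a scalar score."""

    U: np.ndarray  # (d, Ce)
    W: np.ndarray  # (d, Co)
    v: np.ndarray  # (d,)

    def __post_init__(self) -> None:
        U, W, v = (np.asarray(a, dtype=float) for a in (self.U, self.W, self.v))
        if U.ndim != 2 or W.ndim != 2 or v.ndim != 1:
            raise ValueError("U, W must be 2D and v 1D")
        if U.shape[0] != W.shape[0] or U.shape[0] != v.shape[0]:
            raise ValueError(
                f"intermediate dims disagree: U {U.shape}, W {W.shape}, v {v.shape}"
            )
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "v", v)

    @classmethod
    def random(
        cls, e_channels: int, o_channels: int, dim: int, seed: int = 0
    ) -> "AttentionGateParams":
        rng = np.random.default_rng(seed)
        return cls(
            U=rng.normal(size=(dim, e_channels)),
            W=rng.normal(size=(dim, o_channels)),
            v=rng.normal(size=dim),
        )


@dataclass(frozen=True)
class AttentionOutput:
    """alphas: (H, W) weights; context: (Ce,) weighted sum; gated: (Ce, H, W)."""

    alphas: np.ndarray
    context: np.ndarray
    gated: np.ndarray
    scores: np.ndarray


def _softmax_flat(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max()
    e = np.exp(s)
    return e / e.sum()


def attention_gate(
    e: np.ndarray, o: np.ndarray, params: AttentionGateParams
) -> AttentionOutput:
    """Apply the gate to one feature map pair.

    Parameters
    ----------
    e : (Ce, H, W) encoder feature map.
    o : (Co, H, W) decoder state on the same spatial grid.
    """
    e = np.asarray(e, dtype=float)
    o = np.asarray(o, dtype=float)
    if e.ndim != 3 or o.ndim != 3:
        raise ValueError("e and o must be (C, H, W) feature maps")
    if e.shape[1:] != o.shape[1:]:
        raise ValueError(f"spatial mismatch: e {e.shape[1:]} vs o {o.shape[1:]}")
    if e.shape[0] != params.U.shape[1] or o.shape[0] != params.W.shape[1]:
        raise ValueError("channel counts do not match params")

    h, w = e.shape[1:]
    n = h * w
    pre = np.einsum("dc,cij->dij", params.U, e) + np.einsum(
        "dc,cij->dij", params.W, o
    )
    scores = np.einsum("d,dij->ij", params.v, np.tanh(pre))
    alphas = _softmax_flat(scores.ravel()).reshape(h, w)
    context = np.einsum("ij,cij->c", alphas, e)
    gated = (n * alphas)[None, :, :] * e
    return AttentionOutput(alphas=alphas, context=context, gated=gated, scores=scores)


class AttentionGate(Layer):
    """Trainable batched gate used inside the decoder (NCHW tensors).

    U, W, V are 1x1 convolutions; the forward pass exposes ``last_alphas``
    (N, H, W) and ``last_context`` (N, Ce) for inspection.
    """

    def __init__(
        self,
        e_channels: int,
        o_channels: int,
        inter_channels: int,
        rng: np.random.Generator,
    ):
        self.theta_e = Conv2d(e_channels, inter_channels, 1, rng=rng)
        self.theta_o = Conv2d(o_channels, inter_channels, 1, rng=rng)
        self.psi = Conv2d(inter_channels, 1, 1, rng=rng)
        self.last_alphas: np.ndarray | None = None
        self.last_context: np.ndarray | None = None
        self._cache = None

    def parameters(self):
        out = []
        for prefix, conv in (
            ("theta_e", self.theta_e),
            ("theta_o", self.theta_o),
            ("psi", self.psi),
        ):
            out.extend((f"{prefix}.{n}", p) for n, p in conv.parameters())
        return out

    def forward(self, e: np.ndarray, o: np.ndarray) -> np.ndarray:
        if e.shape[2:] != o.shape[2:]:
            raise ValueError(f"spatial mismatch: e {e.shape} vs o {o.shape}")
        nb, ce, h, w = e.shape
        n = h * w
        pre = self.theta_e.forward(e) + self.theta_o.forward(o)
        t = np.tanh(pre)
        scores = self.psi.forward(t).reshape(nb, n)
        s = scores - scores.max(axis=1, keepdims=True)
        ex = np.exp(s)
        alphas = ex / ex.sum(axis=1, keepdims=True)  # (N, n)
        a_map = alphas.reshape(nb, 1, h, w)
        gated = (n * a_map) * e
        self.last_alphas = alphas.reshape(nb, h, w)
        self.last_context = (a_map * e).sum(axis=(2, 3))
        self._cache = (e, t, alphas, (nb, ce, h, w))
        return gated.astype(e.dtype)

    def backward(self, dgated: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e, t, alphas, (nb, ce, h, w) = self._cache
        n = h * w
        a_map = alphas.reshape(nb, 1, h, w)
        de = (n * a_map) * dgated
        # d alpha_j = n * sum_c e_cj dgated_cj
        dalpha = n * (e * dgated).sum(axis=1).reshape(nb, n)
        # softmax jacobian
        dot = (alphas * dalpha).sum(axis=1, keepdims=True)
        dscores = alphas * (dalpha - dot)
        df = dscores.reshape(nb, 1, h, w).astype(e.dtype)
        dt = self.psi.backward(df)
        dpre = ((1.0 - t * t) * dt).astype(e.dtype)
        de = de + self.theta_e.backward(dpre)
        do = self.theta_o.backward(dpre)
        self._cache = None
        return de.astype(e.dtype), do
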