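"""A NumPy forward pass of the ResNet-50 architecture.

Provides the canonical bottleneck topology (stem 7x7/2 conv + max pool,
stages of [3, 4, 6, 3] bottleneck blocks, global average pool) so that the
architectural feature width — 2048 channels after the last convolutional
stage — is available without any deep-learning framework.  Weights are
He-initialized from a seed; normalization layers use per-feature-map batch
statistics of the input itself, which keeps activations bounded for random
weights.  The forward pass is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ResNet50"]

_STAGES = (  # (n_blocks, mid_channels, out_channels, first_stride)
    (3, 64, 256, 1),
    (4, 128, 512, 2),
    (6, 256, 1024, 2),
    (3, 512, 2048, 2),
)


def _he(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """x: (C, H, W); w: (O, C, kh, kw) -> (O, H', W') via im2col + GEMM."""
    o, c, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    _, h, wd = x.shape
    oh = (h - kh) // stride + 1
    ow = (wd - kw) // stride + 1
    s0, s1, s2 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (c, kh, kw, oh, ow), (s0, s1, s2, s1 * stride, s2 * stride),
        writeable=False,
    ).reshape(c * kh * kw, oh * ow)
    return (w.reshape(o, -1) @ cols).reshape(o, oh, ow)


def _norm_relu(x: np.ndarray, relu: bool = True) -> np.ndarray:
    mu = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    x = (x - mu) / (sd + 1e-5)
    return np.maximum(x, 0.0) if relu else x


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    c, h, w = x.shape
    x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    s0, s1, s2 = x.strides
    win = np.lib.stride_tricks.as_strided(
        x, (c, oh, ow, k, k), (s0, s1 * stride, s2 * stride, s1, s2),
        writeable=False)
    return win.max(axis=(3, 4))


class ResNet50:
    """Seeded random-weight ResNet-50 feature extractor (2048-d output)."""

    dim = 2048
    deterministic = True

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = _he(rng, (64, 3, 7, 7))
        self.blocks = []
        in_ch = 64
        for n_blocks, mid, out, stride in _STAGES:
            for b in range(n_blocks):
                s = stride if b == 0 else 1
                block = {
                    "w1": _he(rng, (mid, in_ch, 1, 1)),
                    "w2": _he(rng, (mid, mid, 3, 3)),
                    "w3": _he(rng, (out, mid, 1, 1)),
                    "stride": s,
                    "proj": _he(rng, (out, in_ch, 1, 1)) if (b == 0) else None,
                }
                self.blocks.append(block)
                in_ch = out

    def forward(self, image: np.ndarray) -> np.ndarray:
        """image: (224, 224, 3) float in [0, 1] -> (2048,) feature vector."""
        if image.shape != (224, 224, 3):
            raise ValueError(f"expected (224, 224, 3) input, got {image.shape}")
        x = np.ascontiguousarray(image.astype(np.float32).transpose(2, 0, 1))
        x = _norm_relu(_conv2d(x, self.stem, stride=2, pad=3))
        x = _maxpool(x)
        for blk in self.blocks:
            idn = x
            y = _norm_relu(_conv2d(x, blk["w1"]))
            y = _norm_relu(_conv2d(y, blk["w2"], stride=blk["stride"], pad=1))
            y = _norm_relu(_conv2d(y, blk["w3"]), relu=False)
            if blk["proj"] is not None:
                idn = _norm_relu(_conv2d(x, blk["proj"], stride=blk["stride"]), relu=False)
            x = np.maximum(y + idn, 0.0)
        return x.mean(axis=(1, 2)).astype(np.float64)

    __call__ = forward
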