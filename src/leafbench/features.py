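"""Fixed-length image descriptors for species classification.

Every image, whatever its size after preprocessing, goes through the same
recipe: bilinear resize so the shortest side is 256 px, central 224x224
crop, a backbone forward pass, then L2 normalization of the resulting
vector.

Two backbones satisfy the same contract (``dim`` attribute plus a
``forward(image_224) -> vector``):

* :class:`FallbackBackbone` — multi-scale color and gradient-orientation
  histograms mixed by a fixed-seed random projection to 256 dimensions.
  Fully deterministic, needs no pretrained weights, and is the default for
  every experiment in the package.
* :class:`~leafbench.resnet.ResNet50` — the CNN architecture whose
  globally average-pooled last convolutional stage gives the classical
  2048-d transfer-learning descriptor.  The interpretation of "the last
  convolutional layer" as that 2048-channel pooled tensor is deliberate:
  it is the only 2048-wide tensor in the architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from skimage import transform

__all__ = [
    "FeatureVector",
    "FallbackBackbone",
    "get_backbone",
    "standardize",
    "extract",
    "extract_manifest",
    "feature_columns",
]


class BackboneContract(Protocol):
    dim: int
    deterministic: bool

    def forward(self, image: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class FeatureVector:
    """An L2-normalized descriptor with its provenance."""

    values: np.ndarray
    backbone_id: str

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


def standardize(image: np.ndarray) -> np.ndarray:
    """Resize shortest side to 256 px (bilinear) then center-crop 224x224.

    Accepts uint8 or float RGB; returns float in [0, 1].  Images whose
    shortest side is already 256 are only cropped.
    """
    h, w = image.shape[:2]
    short = min(h, w)
    if short != 256:
        s = 256.0 / short
        new_h, new_w = int(round(h * s)), int(round(w * s))
        # guard rounding on the short side
        if min(new_h, new_w) < 256:
            if new_h < 256:
                new_h = 256
            if new_w < 256:
                new_w = 256
        if image.dtype == np.uint8:
            from PIL import Image as _PILImage

            resized = _PILImage.fromarray(image).resize((new_w, new_h),
                                                        _PILImage.BILINEAR)
            img = np.asarray(resized).astype(np.float32) / np.float32(255.0)
        else:
            img = transform.resize(image.astype(np.float64), (new_h, new_w),
                                   order=1, mode="edge", anti_aliasing=False,
                                   preserve_range=True)
        h, w = new_h, new_w
    else:
        img = image.astype(np.float64)
        if image.dtype == np.uint8:
            img /= 255.0
    y0 = (h - 224) // 2
    x0 = (w - 224) // 2
    return np.clip(img[y0:y0 + 224, x0:x0 + 224], 0.0, 1.0)


# --------------------------------------------------------------------------
# fallback backbone

def _rgb_to_hsv(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized RGB (float [0,1]) -> (hue, sat, val) planes."""
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    val = np.maximum(np.maximum(r, g), b)
    delta = val - np.minimum(np.minimum(r, g), b)
    sat = np.where(val > 0, delta / (val + 1e-12), 0.0)
    r_is_max = val == r
    g_is_max = ~r_is_max & (val == g)
    b_is_max = ~r_is_max & ~g_is_max
    num = ((g - b) * r_is_max + (b - r) * g_is_max + (r - g) * b_is_max)
    arg = g_is_max * 1.0 + b_is_max * 2.0
    d = np.where(delta > 0, delta, 1.0)
    hue = ((num / d + 2.0 * arg) % 6.0) / 6.0
    hue = np.where(delta > 0, hue, 0.0)
    return hue, sat, val


_REG4: np.ndarray | None = None


def _region_index() -> np.ndarray:
    global _REG4
    if _REG4 is None:
        step = 224 // 4
        yy, xx = np.mgrid[0:224, 0:224]
        _REG4 = ((yy // step) * 4 + (xx // step)).astype(np.intp)
    return _REG4


def _binned(region: np.ndarray, values: np.ndarray, n_bins: int, n_regions: int,
            weights: np.ndarray | None = None) -> np.ndarray:
    """Per-region histograms via one bincount: (n_regions, n_bins)."""
    idx = region * n_bins + values
    w = None if weights is None else weights.ravel()
    return np.bincount(idx.ravel(), weights=w,
                       minlength=n_regions * n_bins).reshape(n_regions, n_bins)


def _region_histograms(img224: np.ndarray) -> np.ndarray:
    """Color + edge histograms at three spatial scales (1, 2x2, 4x4 grids).

    Hue histograms are weighted by saturation so near-gray pixels (white
    sheets, bright sky) contribute almost nothing; orientation histograms
    are weighted by gradient magnitude.  The 4x4 block histograms are
    aggregated upward to the 2x2 and global scales.
    """
    hue, sat, val = _rgb_to_hsv(img224)
    gy, gx = np.gradient(val)
    mag = np.hypot(gx, gy)
    ori = np.arctan2(gy, gx) % np.pi

    reg4 = _region_index()                            # 16 fine regions

    hb = np.minimum((hue * 16).astype(np.intp), 15)
    sb = np.minimum((sat * 8).astype(np.intp), 7)
    vb = np.minimum((val * 8).astype(np.intp), 7)
    ob = np.minimum((ori / np.pi * 8).astype(np.intp), 7)

    h16 = _binned(reg4, hb, 16, 16, weights=sat)
    s16 = _binned(reg4, sb, 8, 16)
    v16 = _binned(reg4, vb, 8, 16)
    o16 = _binned(reg4, ob, 8, 16, weights=mag)
    msum = np.bincount(reg4.ravel(), weights=mag.ravel(), minlength=16)
    msq = np.bincount(reg4.ravel(), weights=(mag ** 2).ravel(), minlength=16)

    def agg(block16: np.ndarray) -> list[np.ndarray]:
        """Stack [global, 2x2, 4x4] region rows from the 16 fine regions."""
        b = block16.reshape(4, 4, -1)
        coarse = b.reshape(2, 2, 2, 2, -1).sum(axis=(1, 3)).reshape(4, -1)
        return [block16.sum(axis=0, keepdims=True), coarse, block16]

    feats = []
    area16 = float((224 // 4) ** 2)
    for scale_i, n_sub in ((0, 16), (1, 4), (2, 1)):
        area = area16 * n_sub
        hh = agg(h16)[scale_i] / area
        sh = agg(s16)[scale_i] / area
        vh = agg(v16)[scale_i] / area
        ohs = agg(o16)[scale_i]
        ms = agg(msum[:, None])[scale_i][:, 0]
        m2 = agg(msq[:, None])[scale_i][:, 0]
        oh = ohs / (ms[:, None] + 1e-9)
        mean = ms / area
        std = np.sqrt(np.maximum(m2 / area - mean ** 2, 0.0))
        feats.append(np.concatenate(
            [hh, sh, vh, oh, mean[:, None], std[:, None]], axis=1).ravel())
    return np.concatenate(feats)


class FallbackBackbone:
    """Deterministic, weight-free descriptor: histograms + random projection.

    The raw multi-scale histogram vector is projected to ``dim`` dimensions
    with a Gaussian matrix drawn once from ``seed``, decorrelating the
    histogram blocks the way a random feature map would.
    """

    deterministic = True

    def __init__(self, dim: int = 256, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._proj: np.ndarray | None = None

    def _projection(self, raw_dim: int) -> np.ndarray:
        if self._proj is None or self._proj.shape[1] != raw_dim:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.normal(0, 1.0 / np.sqrt(raw_dim), (self.dim, raw_dim))
        return self._proj

    def forward(self, image: np.ndarray) -> np.ndarray:
        raw = _region_histograms(image)
        return self._projection(raw.shape[0]) @ raw

    __call__ = forward


def get_backbone(name: str, seed: int = 0) -> BackboneContract:
    if name == "fallback":
        return FallbackBackbone(seed=seed)
    if name == "resnet50":
        from .resnet import ResNet50

        return ResNet50(seed=seed)
    raise ValueError(f"unknown backbone {name!r}")


# --------------------------------------------------------------------------
# extraction

def extract(image: np.ndarray, backbone: BackboneContract) -> FeatureVector:
    """Standardize ``image``, run the backbone and L2-normalize the output."""
    vec = np.asarray(backbone.forward(standardize(image)), dtype=np.float64)
    norm = np.linalg.norm(vec)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("backbone produced a zero/non-finite vector; "
                         "normalization undefined")
    return FeatureVector(values=vec / norm,
                         backbone_id=type(backbone).__name__)


_META_COLUMNS = ["observation_id", "species_id", "perspective", "illumination",
                 "background", "image_type", "strategy"]


def feature_columns(dim: int) -> list[str]:
    return [f"f{i:04d}" for i in range(dim)]


def extract_manifest(
    manifest: pd.DataFrame,
    backbone: BackboneContract,
    strategy: str,
    image_loader: Callable[[pd.Series], np.ndarray],
    marker_counts: pd.Series | None = None,
) -> pd.DataFrame:
    """One feature row per manifest row, in manifest order.

    ``image_loader`` maps a manifest row to the (possibly preprocessed)
    pixels to featurize, which keeps this function agnostic of where images
    live (disk paths, in-memory records, preprocessed crops).
    """
    rows = []
    for idx, row in manifest.iterrows():
        fv = extract(image_loader(row), backbone)
        meta = {c: row[c] for c in _META_COLUMNS if c in row.index}
        meta["strategy"] = strategy
        if marker_counts is not None:
            meta["marker_count"] = marker_counts.loc[idx]
        rows.append({**meta, **dict(zip(feature_columns(fv.dim), fv.values))})
    return pd.DataFrame(rows)


def save_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def load_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
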