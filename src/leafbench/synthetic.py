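"""Seeded synthetic leaf observations with ground truth.

Emulates a field-style leaf image collection: each *observation* is one leaf
individual photographed as nine image types — the factor cross
{top, back} x {flash on, flash off} x {natural, plain background} plus one
destructive *back light* shot (leaf held against a bright sky).  Every record
carries a pixel-accurate foreground mask, its tight bounding box and a focus
point, so downstream segmentation and classification can be scored exactly.

Leaf morphology is a parametric closed curve: a base radius modulated by a
lobe cosine and a high-frequency serration term, anisotropically scaled by an
aspect ratio.  Compound leaves are rendered as disjoint leaflets sharing one
outline.  Species differ in shape, venation density/contrast and base color;
observations of one species add small pose and color jitter.

The photometric condition effects are built in deliberately:

* natural backgrounds contain clutter — distractor leaflets drawn from
  *other* species plus stones and gradients — so unpreprocessed images carry
  misleading context;
* plain (white sheet) backgrounds darken the leaf and compress its contrast
  and saturation;
* flash raises brightness and splashes specular highlights across the blade,
  masking venation;
* back light gives a bright uniform background, a sharp dark leaf margin and
  maximal venation contrast — the most information-rich image type.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw

from ._rng import substream

__all__ = [
    "SpeciesSpec",
    "ImageRecord",
    "GeneratorConfig",
    "IMAGE_TYPES",
    "generate_species_bank",
    "render_leaf",
    "composite",
    "render_backlight",
    "generate_observation",
    "generate_dataset",
    "iter_observations",
    "read_manifest",
    "load_record",
    "separability",
    "venation_contrast",
    "shape_descriptor",
]

PERSPECTIVES = ("top", "back", "backlight")

#: The nine acquisition conditions: 2 perspectives x 2 illuminations x 2
#: backgrounds, plus the destructive back-light shot.
IMAGE_TYPES = tuple(
    f"{p}_{i}_{b}"
    for p in ("top", "back")
    for i in ("flash_off", "flash_on")
    for b in ("natural", "plain")
) + ("backlight",)

_SHAPE_FIELDS = ("base_radius", "lobe_count", "lobe_depth", "serration", "aspect_ratio")


@dataclass(frozen=True)
class SpeciesSpec:
    """Parametric morphology and appearance of one synthetic species."""

    species_id: str
    base_radius: float          # px, radius of the outline before modulation
    lobe_count: int             # >= 0 cosine lobes on the margin
    lobe_depth: float           # 0-1, relative lobe amplitude
    serration: float            # 0-1, margin serration amplitude
    aspect_ratio: float         # x/y anisotropy of the outline
    compoundness: int           # >= 1 leaflets
    vein_density: float         # veins per 100 px of blade diameter
    vein_contrast: float        # 0-1
    hue: float                  # base HSV color
    saturation: float
    value: float
    backside_delta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.lobe_count >= 0 and self.compoundness >= 1):
            raise ValueError("lobe_count must be >= 0 and compoundness >= 1")
        for name in ("lobe_depth", "serration", "vein_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def shape_params(self) -> tuple:
        return tuple(getattr(self, f) for f in _SHAPE_FIELDS)


@dataclass
class ImageRecord:
    """One rendered image with its acquisition factors and ground truth."""

    observation_id: str
    species_id: str
    perspective: str            # top | back | backlight
    illumination: str           # flash_on | flash_off | n/a
    background: str             # natural | plain | n/a
    pixels: np.ndarray          # H x W x 3 uint8
    gt_mask: np.ndarray         # H x W bool
    gt_bbox: tuple              # (x0, y0, x1, y1), 0-based half-open
    focus_point: tuple          # (x, y), inside gt_mask

    @property
    def image_type(self) -> str:
        if self.perspective == "backlight":
            return "backlight"
        return f"{self.perspective}_{self.illumination}_{self.background}"


@dataclass
class GeneratorConfig:
    """Free photometric and layout parameters of the generator.

    The condition effects (plain-background contrast loss, flash gain and
    specularity, clutter budget) are not quantified by field protocols; the
    defaults below are fixed, documented choices.
    """

    width: int = 512
    height: int = 384
    jitter: float = 1.0             # 0 disables pose jitter
    white_level: float = 0.92       # plain-background sheet reflectance
    sky_level: float = 0.95         # back-light background luminance
    plain_contrast: float = 0.55    # leaf contrast retained on plain bg
    plain_brightness: float = 0.82  # leaf brightness factor on plain bg
    plain_saturation: float = 0.70
    flash_gain: float = 1.18
    n_specularities: tuple = (2, 5)     # blobs per flash image (min, max)
    distractor_budget: int = 5          # clutter objects on natural bg
    obs_hue_jitter: float = 0.03        # per-observation appearance spread
    obs_sat_jitter: float = 0.08
    obs_val_jitter: float = 0.06
    noise_sigma: float = 0.018          # per-pixel sensor noise
    # in-situ shots share a per-observation white-balance error and focus
    # softness; the standardized back-light shot is exempt from both
    cast_gain_sigma: float = 0.12       # per-channel gain spread around 1
    blur_range: tuple = (0.4, 1.6)      # px, per-observation defocus sigma


# --------------------------------------------------------------------------
# species bank

def generate_species_bank(n_species: int, seed: int) -> list[SpeciesSpec]:
    """Draw ``n_species`` distinct species specs, deterministically from ``seed``.

    Hues are assigned on a stratified grid over a green-brown band (with a
    seeded permutation and jitter) so every pair of species is separable by
    color as well as by shape — mimicking a curated set of distinct species.
    """
    if n_species < 2:
        raise ValueError(f"n_species must be >= 2, got {n_species}")
    order = substream(seed, "species", "hue-order").permutation(n_species)
    specs: list[SpeciesSpec] = []
    for i in range(n_species):
        rng = substream(seed, "species", i)
        hue_slot = (order[i] + 0.5) / n_species
        hue = 0.12 + 0.38 * hue_slot + rng.uniform(-0.25, 0.25) / max(n_species, 4)
        compound = int(rng.choice([1, 1, 1, 3, 5], p=[0.4, 0.15, 0.15, 0.15, 0.15]))
        spec = SpeciesSpec(
            species_id=f"sp{i:02d}",
            base_radius=float(rng.uniform(65, 105)),
            lobe_count=int(rng.integers(0, 7)),
            lobe_depth=float(rng.uniform(0.05, 0.8)),
            serration=float(rng.uniform(0.0, 0.9)),
            aspect_ratio=float(rng.uniform(0.45, 1.1)),
            compoundness=compound,
            vein_density=float(rng.uniform(3.0, 9.0)),
            vein_contrast=float(rng.uniform(0.35, 0.85)),
            hue=float(np.clip(hue, 0.02, 0.62)),
            saturation=float(rng.uniform(0.45, 0.8)),
            value=float(rng.uniform(0.35, 0.6)),
            backside_delta={
                "value_offset": float(rng.uniform(0.03, 0.1)),
                "sat_scale": float(rng.uniform(0.75, 0.92)),
                "vein_boost": float(rng.uniform(0.05, 0.2)),
            },
        )
        specs.append(spec)
    # continuous draws make collisions measure-zero; assert the invariant
    seen = {s.shape_params() for s in specs}
    assert len(seen) == n_species, "species bank contains duplicate shapes"
    return specs


# --------------------------------------------------------------------------
# leaf rendering

def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    import colorsys

    return np.array(colorsys.hsv_to_rgb(h % 1.0, float(np.clip(s, 0, 1)),
                                        float(np.clip(v, 0, 1))))


def _outline(spec: SpeciesSpec, radius: float, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Closed-curve leaflet outline (x, y) around the origin."""
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = radius * (
        1.0
        + 0.35 * spec.lobe_depth * np.cos(spec.lobe_count * theta)
        + 0.06 * spec.serration * np.sin(29 * theta)
    )
    return r * np.cos(theta) * spec.aspect_ratio, r * np.sin(theta)


def _leaflet_layout(spec: SpeciesSpec, size: tuple[int, int]) -> tuple[float, list[np.ndarray]]:
    """Leaflet radius and center offsets such that leaflets stay disjoint."""
    w, h = size
    k = spec.compoundness
    fit = 0.38 * min(w, h)
    r_max_factor = 1.0 + 0.35 * spec.lobe_depth + 0.06 * spec.serration
    if k == 1:
        radius = min(spec.base_radius, fit / r_max_factor)
        return radius, [np.zeros(2)]
    # leaflets in a row along the rachis axis; spacing > 2 * max extent
    spacing_units = 2.3 * r_max_factor
    radius = min(spec.base_radius, 2 * fit / ((k - 1) * spacing_units + 2 * r_max_factor))
    d = spacing_units * radius
    offsets = [np.array([0.0, (j - (k - 1) / 2.0) * d]) for j in range(k)]
    return radius, offsets


@dataclass
class LeafLayer:
    """A rendered leaf before compositing: color where ``alpha`` is true."""

    color: np.ndarray       # H x W x 3 float in [0, 1]
    alpha: np.ndarray       # H x W bool
    vein_mask: np.ndarray   # H x W bool, subset of alpha


def _draw_veins(mask: np.ndarray, centers: list[np.ndarray], radius: float,
                spec: SpeciesSpec, pose_angle: float, origin: np.ndarray) -> np.ndarray:
    vein = np.zeros(mask.shape, dtype=bool)
    n_veins = max(2, int(round(spec.vein_density * (2 * radius) / 100.0)))
    h, w = mask.shape
    ca, sa = np.cos(pose_angle), np.sin(pose_angle)
    for off in centers:
        cx = origin[0] + off[0] * ca - off[1] * sa
        cy = origin[1] + off[0] * sa + off[1] * ca
        for j in range(n_veins):
            ang = pose_angle + 2 * np.pi * j / n_veins + 0.3 * np.sin(3.7 * j)
            length = 0.85 * radius * (0.75 + 0.25 * np.cos(2 * ang))
            x1 = int(round(cx + length * np.cos(ang) * spec.aspect_ratio))
            y1 = int(round(cy + length * np.sin(ang)))
            rr, cc = skdraw.line(int(round(cy)), int(round(cx)),
                                 int(np.clip(y1, 0, h - 1)), int(np.clip(x1, 0, w - 1)))
            vein[rr, cc] = True
    return vein & mask


@dataclass
class _Geometry:
    """Pose-resolved blade geometry, shared by all renders of one observation."""

    mask: np.ndarray
    vein: np.ndarray
    shade: np.ndarray       # radial shading field in [0.85, 1], defined on mask
    texture: np.ndarray     # per-pixel lamina noise, H x W


def _render_geometry(spec: SpeciesSpec, jitter_seed: int,
                     size: tuple[int, int], jitter: float) -> _Geometry:
    w, h = size
    rng = substream(jitter_seed, "pose")
    angle = jitter * rng.uniform(-0.45, 0.45)
    scale = 1.0 + jitter * rng.uniform(-0.12, 0.12)
    tx = jitter * rng.uniform(-0.06, 0.06) * w
    ty = jitter * rng.uniform(-0.06, 0.06) * h
    origin = np.array([w / 2.0 + tx, h / 2.0 + ty])

    radius, offsets = _leaflet_layout(spec, size)
    radius *= scale
    mask = np.zeros((h, w), dtype=bool)
    ca, sa = np.cos(angle), np.sin(angle)
    x, y = _outline(spec, radius)
    for off in offsets:
        ox, oy = off * scale
        cx = origin[0] + ox * ca - oy * sa
        cy = origin[1] + ox * sa + oy * ca
        rr, cc = skdraw.polygon(x * sa + y * ca + cy, x * ca - y * sa + cx, shape=(h, w))
        mask[rr, cc] = True
    # drop single-pixel rasterization specks of strongly serrated outlines
    from skimage.morphology import remove_small_objects

    mask = remove_small_objects(mask, max_size=15)

    vein = _draw_veins(mask, [o * scale for o in offsets], radius, spec, angle, origin)
    # interior-brightening shade from a blurred mask (a cheap stand-in for
    # a distance transform; only the smooth center-to-margin ramp matters)
    soft = ndimage.gaussian_filter(mask.astype(np.float32), radius / 6.0,
                                   truncate=2.0)
    peak = soft.max()
    shade = 0.85 + 0.15 * (soft / peak) if peak > 0 else np.ones_like(soft)
    texture = 0.02 * substream(jitter_seed, "texture").standard_normal(
        (h, w), dtype=np.float32)
    return _Geometry(mask=mask, vein=vein, shade=shade, texture=texture)


def _colorize(geom: _Geometry, spec: SpeciesSpec, perspective: str) -> LeafLayer:
    sat, val, vein_c = spec.saturation, spec.value, spec.vein_contrast
    if perspective == "back":
        d = spec.backside_delta
        val = val + d.get("value_offset", 0.0)
        sat = sat * d.get("sat_scale", 1.0)
        vein_c = min(1.0, vein_c + d.get("vein_boost", 0.0))
    base = _hsv_to_rgb(spec.hue, sat, val)

    mask, vein = geom.mask, geom.vein
    color = np.zeros(mask.shape + (3,), dtype=np.float32)
    color[mask] = base * geom.shade[mask, None]
    # veins lighter than the lamina on reflected-light views
    color[vein] = np.clip(color[vein] + 0.55 * vein_c * (1.0 - color[vein]), 0, 1)
    color[mask] = np.clip(color[mask] + geom.texture[mask, None], 0, 1)
    if perspective == "back":
        color, mask, vein = color[:, ::-1].copy(), mask[:, ::-1].copy(), vein[:, ::-1].copy()
    return LeafLayer(color=color, alpha=mask, vein_mask=vein)


def render_leaf(
    spec: SpeciesSpec,
    perspective: str,
    jitter_seed: int,
    size: tuple[int, int] = (512, 384),
    jitter: float = 1.0,
) -> LeafLayer:
    """Render the leaf of ``spec`` as an RGB-over-alpha layer.

    ``perspective`` "back" mirrors the blade horizontally and applies the
    species' backside texture offsets.  Pose (rotation, scale, translation)
    is drawn once from ``jitter_seed`` and scaled by ``jitter``; ``jitter=0``
    gives the canonical centered pose.
    """
    if perspective not in ("top", "back"):
        raise ValueError(f"invalid perspective {perspective!r}")
    return _colorize(_render_geometry(spec, jitter_seed, size, jitter), spec, perspective)


# --------------------------------------------------------------------------
# backgrounds and compositing

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    # smooth at 1/8 resolution and bilinearly upsample: visually equivalent
    # for the broad fields used here, an order of magnitude cheaper
    h, w = shape
    hs, ws = max(h // 8, 4), max(w // 8, 4)
    f = ndimage.gaussian_filter(rng.normal(0, 1, (hs, ws)), sigma / 8.0)
    f = np.asarray(Image.fromarray(f.astype(np.float32), mode="F")
                   .resize((w, h), Image.BILINEAR))
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo + 1e-12)


def _natural_background(shape: tuple[int, int], rng: np.random.Generator,
                        distractor_specs: Sequence[SpeciesSpec],
                        budget: int) -> np.ndarray:
    h, w = shape
    field_ = _smooth_field(rng, shape, sigma=18)
    c1 = _hsv_to_rgb(rng.uniform(0.18, 0.32), rng.uniform(0.3, 0.5), rng.uniform(0.2, 0.35))
    c2 = _hsv_to_rgb(rng.uniform(0.05, 0.14), rng.uniform(0.25, 0.45), rng.uniform(0.3, 0.5))
    bg = c1[None, None] * field_[..., None] + c2[None, None] * (1 - field_[..., None])
    # illumination gradient across the scene
    gx = np.linspace(-1, 1, w)[None, :] * rng.uniform(-0.08, 0.08)
    gy = np.linspace(-1, 1, h)[:, None] * rng.uniform(-0.08, 0.08)
    bg = np.clip(bg + (gx + gy)[..., None], 0, 1)

    for _ in range(budget):
        kind = rng.uniform()
        if kind < 0.7 and len(distractor_specs):
            spec = distractor_specs[int(rng.integers(len(distractor_specs)))]
            r = rng.uniform(0.25, 0.5) * spec.base_radius
            x, y = _outline(spec, r, n=72)
            ang = rng.uniform(0, 2 * np.pi)
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            xr = x * np.cos(ang) - y * np.sin(ang) + cx
            yr = x * np.sin(ang) + y * np.cos(ang) + cy
            rr, cc = skdraw.polygon(yr, xr, shape=(h, w))
            col = _hsv_to_rgb(spec.hue + rng.normal(0, 0.015),
                              spec.saturation * rng.uniform(0.7, 1.0),
                              spec.value * rng.uniform(0.6, 1.0))
        else:  # stone-like ellipse
            rr, cc = skdraw.ellipse(rng.uniform(0, h), rng.uniform(0, w),
                                    rng.uniform(8, 30), rng.uniform(8, 30),
                                    shape=(h, w), rotation=rng.uniform(0, np.pi))
            g = rng.uniform(0.35, 0.6)
            col = np.array([g, g * rng.uniform(0.9, 1.0), g * rng.uniform(0.8, 1.0)])
        bg[rr, cc] = 0.85 * col + 0.15 * bg[rr, cc]
    return bg


def _plain_leaf_adjust(color: np.ndarray, mask: np.ndarray,
                       cfg: GeneratorConfig) -> np.ndarray:
    """White-sheet look: compress blade contrast/saturation, darken."""
    leaf = color.copy()
    if mask.any():
        mean = leaf[mask].mean(axis=0)
        leaf[mask] = mean + (leaf[mask] - mean) * cfg.plain_contrast
        gray = leaf[mask].mean(axis=1, keepdims=True)
        leaf[mask] = gray + (leaf[mask] - gray) * cfg.plain_saturation
        leaf[mask] *= cfg.plain_brightness
    return leaf


def _apply_flash(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 cfg: GeneratorConfig, coords=None) -> np.ndarray:
    """Brightness gain plus specular blobs over the blade (in place)."""
    h, w = mask.shape
    img *= cfg.flash_gain
    n_spec = int(rng.integers(cfg.n_specularities[0], cfg.n_specularities[1] + 1))
    ys, xs = np.nonzero(mask) if coords is None else coords
    if len(ys):
        for _ in range(n_spec):
            i = int(rng.integers(len(ys)))
            s = rng.uniform(8, 22)
            r = int(3 * s)
            y0, y1 = max(0, ys[i] - r), min(h, ys[i] + r + 1)
            x0, x1 = max(0, xs[i] - r), min(w, xs[i] + r + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            blob = np.exp(-((yy - ys[i]) ** 2 + (xx - xs[i]) ** 2) / (2 * s * s))
            img[y0:y1, x0:x1] += 0.7 * blob[..., None]
    return img


def composite(
    layer: LeafLayer,
    background: str,
    illumination: str,
    distractor_specs: Sequence[SpeciesSpec] = (),
    seed: int = 0,
    config: GeneratorConfig | None = None,
    scene_background: np.ndarray | None = None,
    scene_cast: np.ndarray | None = None,
    blur_sigma: float = 0.0,
) -> np.ndarray:
    """Place a leaf layer on a background and apply the illumination.

    Plain backgrounds darken the blade and compress its contrast and
    saturation (the washed-out white-sheet look); flash multiplies brightness
    and adds clipped specular blobs over the blade.  Natural backgrounds get
    ``config.distractor_budget`` clutter objects drawn from other species.
    ``scene_background`` lets the caller reuse one rendered scene across the
    shots of an observation (the leaf is photographed in place, so the
    surroundings are the same scene in every shot); ``scene_cast`` is a
    per-channel white-balance gain and ``blur_sigma`` a defocus blur, both
    shared the same way.  Returns uint8 pixels.
    """
    cfg = config or GeneratorConfig()
    if background not in ("natural", "plain"):
        raise ValueError(f"invalid background {background!r}")
    rng = substream(seed, "bg", background)
    h, w = layer.alpha.shape
    mask = layer.alpha

    if background == "plain":
        if scene_background is None:
            scene_background = np.full((h, w, 3), cfg.white_level)
            scene_background = scene_background + rng.normal(0, 0.01, (h, w, 1))
        leaf = _plain_leaf_adjust(layer.color, mask, cfg)
        bg = scene_background
    else:
        if scene_background is None:
            scene_background = _natural_background((h, w), rng, distractor_specs,
                                                   cfg.distractor_budget)
        leaf = layer.color
        bg = scene_background

    img = np.where(mask[..., None], leaf, bg)

    if illumination == "flash_on":
        img = _apply_flash(img, mask, substream(seed, "shot", illumination), cfg)
    elif illumination != "flash_off":
        raise ValueError(f"invalid illumination {illumination!r}")

    if scene_cast is not None:
        img = img * scene_cast[None, None, :]
    if blur_sigma and blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (blur_sigma, blur_sigma, 0),
                                      truncate=2.5)
    img = np.clip(img + rng.normal(0, cfg.noise_sigma, (h, w, 1)), 0, 1)
    return (img * 255).round().astype(np.uint8)


def render_backlight(
    spec: SpeciesSpec,
    jitter_seed: int,
    size: tuple[int, int] = (512, 384),
    jitter: float = 1.0,
    config: GeneratorConfig | None = None,
    layer: LeafLayer | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-light shot: translucent blade against a bright sky.

    The lamina transmits the species hue at high brightness, veins come out
    dark at maximal contrast, and the margin is a sharp dark rim — so this is
    by construction the most separable and information-rich image type.
    ``layer`` may pass the already-rendered top-side layer of the same pose.
    Returns (uint8 pixels, bool mask).
    """
    cfg = config or GeneratorConfig()
    if layer is None:
        layer = render_leaf(spec, "top", jitter_seed, size=size, jitter=jitter)
    mask = layer.alpha
    h, w = mask.shape
    rng = substream(jitter_seed, "backlight")

    sky = np.full((h, w, 3), cfg.sky_level)
    sky += 0.02 * _smooth_field(rng, (h, w), sigma=40)[..., None]

    # transmittance tracks blade thickness/pigment, so lamina brightness is
    # itself a species cue in transmitted light
    lamina = _hsv_to_rgb(spec.hue, min(1.0, spec.saturation * 0.85),
                         0.45 + 0.5 * spec.value)
    img = sky.copy()
    img[mask] = lamina
    # dark, maximal-contrast venation (transmitted light renders veins wide)
    vein = ndimage.binary_dilation(layer.vein_mask) & mask
    vc = 0.6 + 0.4 * spec.vein_contrast
    img[vein] *= (1.0 - 0.85 * vc)
    # sharp dark margin rim
    rim = mask & ~ndimage.binary_erosion(mask, iterations=2)
    img[rim] = 0.12
    img = np.clip(img + rng.normal(0, cfg.noise_sigma * 0.7, (h, w, 1)), 0, 1)
    # keep every leaf pixel strictly darker than the sky floor
    img[mask] = np.minimum(img[mask], cfg.sky_level - 0.12)
    return (img * 255).round().astype(np.uint8), mask


# --------------------------------------------------------------------------
# observations and datasets

def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _focus_point(mask: np.ndarray) -> tuple[int, int]:
    """Mask centroid, snapped to the nearest foreground pixel if outside."""
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    if mask[int(round(cy)), int(round(cx))]:
        return int(round(cx)), int(round(cy))
    i = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))
    return int(xs[i]), int(ys[i])


def _jittered_spec(spec: SpeciesSpec, rng: np.random.Generator,
                   cfg: GeneratorConfig) -> SpeciesSpec:
    """Per-observation appearance variation (individual leaves differ)."""
    return dataclasses.replace(
        spec,
        hue=spec.hue + float(rng.normal(0, cfg.obs_hue_jitter)),
        saturation=float(np.clip(spec.saturation + rng.normal(0, cfg.obs_sat_jitter), 0.2, 0.95)),
        value=float(np.clip(spec.value + rng.normal(0, cfg.obs_val_jitter), 0.15, 0.8)),
    )


def generate_observation(
    spec: SpeciesSpec,
    observation_id: str,
    seed: int,
    config: GeneratorConfig | None = None,
    distractor_specs: Sequence[SpeciesSpec] = (),
) -> list[ImageRecord]:
    """Render the nine image types of one observation.

    All nine records share one pose draw and one appearance draw, so the leaf
    geometry is identical across conditions up to the back-side mirror.
    """
    cfg = config or GeneratorConfig()
    size = (cfg.width, cfg.height)
    rng = substream(seed, "obs", observation_id)
    obs_spec = _jittered_spec(spec, rng, cfg)
    pose_seed = int(rng.integers(2**31))

    geom = _render_geometry(obs_spec, pose_seed, size, cfg.jitter)
    layers = {
        "top": _colorize(geom, obs_spec, "top"),
        "back": _colorize(geom, obs_spec, "back"),
    }
    others = [s for s in distractor_specs if s.species_id != spec.species_id]

    # one scene per background kind: the leaf is shot in place, so all
    # images of the observation see the same surroundings
    h, w = cfg.height, cfg.width
    scene_rng = substream(seed, "scene", observation_id)
    scenes = {
        "natural": _natural_background((h, w), scene_rng, others, cfg.distractor_budget),
        "plain": np.full((h, w, 3), cfg.white_level) + scene_rng.normal(0, 0.01, (h, w, 1)),
    }
    scenes = {k: v.astype(np.float32) for k, v in scenes.items()}
    cast = np.clip(1.0 + scene_rng.normal(0, cfg.cast_gain_sigma, 3), 0.7, 1.3)
    blur = float(scene_rng.uniform(*cfg.blur_range))

    records = []
    for persp in ("top", "back"):
        layer = layers[persp]
        mask = layer.alpha
        coords = np.nonzero(mask)
        bbox, focus = _tight_bbox(mask), _focus_point(mask)
        for bg in ("natural", "plain"):
            scene = scenes[bg][:, ::-1] if persp == "back" else scenes[bg]
            leaf = (_plain_leaf_adjust(layer.color, mask, cfg)
                    if bg == "plain" else layer.color)
            base = np.where(mask[..., None], leaf.astype(np.float32, copy=False),
                            scene)
            base *= cast.astype(np.float32)[None, None, :]
            if blur > 0:
                base = ndimage.gaussian_filter(base, (blur, blur, 0), truncate=2.5)
            for illum in ("flash_off", "flash_on"):
                cond_rng = substream(seed, "cond", observation_id, persp, illum, bg)
                noise = cfg.noise_sigma * cond_rng.standard_normal(
                    (h, w, 1), dtype=np.float32)
                if illum == "flash_on":
                    # flash blobs are smooth already; adding them after the
                    # shared defocus blur is visually equivalent and avoids
                    # re-filtering every illumination variant
                    img = _apply_flash(base.copy(), mask, cond_rng, cfg,
                                       coords=coords)
                    img += noise
                else:
                    img = base + noise
                np.clip(img, 0.0, 1.0, out=img)
                img *= 255.0
                img += 0.5
                records.append(ImageRecord(
                    observation_id=observation_id, species_id=spec.species_id,
                    perspective=persp, illumination=illum, background=bg,
                    pixels=img.astype(np.uint8),
                    gt_mask=mask, gt_bbox=bbox, focus_point=focus,
                ))
    bl_pixels, bl_mask = render_backlight(obs_spec, pose_seed, size=size,
                                          jitter=cfg.jitter, config=cfg,
                                          layer=layers["top"])
    records.append(ImageRecord(
        observation_id=observation_id, species_id=spec.species_id,
        perspective="backlight", illumination="n/a", background="n/a",
        pixels=bl_pixels, gt_mask=bl_mask, gt_bbox=_tight_bbox(bl_mask),
        focus_point=_focus_point(bl_mask),
    ))
    return records


def _observation_plan(bank: Sequence[SpeciesSpec], obs_range: tuple[int, int],
                      seed: int) -> list[tuple[SpeciesSpec, str]]:
    lo, hi = obs_range
    if not (2 <= lo <= hi <= 100):
        raise ValueError(f"obs_range must lie within [2, 100], got {obs_range}")
    plan = []
    for spec in bank:
        n_obs = int(substream(seed, "obs-count", spec.species_id).integers(lo, hi + 1))
        for j in range(n_obs):
            plan.append((spec, f"{spec.species_id}_obs{j:03d}"))
    return plan


def iter_observations(
    n_species: int,
    obs_range: tuple[int, int],
    seed: int,
    config: GeneratorConfig | None = None,
) -> Iterator[list[ImageRecord]]:
    """Stream observations (lists of 9 records) without touching disk."""
    bank = generate_species_bank(n_species, seed)
    for spec, obs_id in _observation_plan(bank, obs_range, seed):
        yield generate_observation(spec, obs_id, seed, config, distractor_specs=bank)


MANIFEST_COLUMNS = [
    "observation_id", "species_id", "perspective", "illumination", "background",
    "image_type", "image_path", "mask_path", "x0", "y0", "x1", "y1",
    "focus_x", "focus_y",
]


def generate_dataset(
    n_species: int,
    obs_range: tuple[int, int],
    seed: int,
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Write a full dataset (PNG images + masks + manifest CSV) to ``out_dir``.

    Per-species observation counts are drawn uniformly from ``obs_range``.
    Identical arguments produce byte-identical files.  Returns the manifest.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for records in iter_observations(n_species, obs_range, seed, config):
        for rec in records:
            stem = f"{rec.observation_id}_{rec.image_type}"
            img_path = f"images/{stem}.png"
            mask_path = f"masks/{stem}.png"
            Image.fromarray(rec.pixels).save(out / img_path)
            Image.fromarray((rec.gt_mask * np.uint8(255))).save(out / mask_path)
            x0, y0, x1, y1 = rec.gt_bbox
            rows.append({
                "observation_id": rec.observation_id, "species_id": rec.species_id,
                "perspective": rec.perspective, "illumination": rec.illumination,
                "background": rec.background, "image_type": rec.image_type,
                "image_path": img_path, "mask_path": mask_path,
                "x0": x0, "y0": y0, "x1": x1, "y1": y1,
                "focus_x": rec.focus_point[0], "focus_y": rec.focus_point[1],
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_record(row: pd.Series, root: str | Path) -> ImageRecord:
    """Reload one manifest row as an in-memory record."""
    root = Path(root)
    pixels = np.asarray(Image.open(root / row["image_path"]).convert("RGB"))
    mask = np.asarray(Image.open(root / row["mask_path"])) > 127
    return ImageRecord(
        observation_id=row["observation_id"], species_id=row["species_id"],
        perspective=row["perspective"], illumination=row["illumination"],
        background=row["background"], pixels=pixels, gt_mask=mask,
        gt_bbox=(int(row["x0"]), int(row["y0"]), int(row["x1"]), int(row["y1"])),
        focus_point=(int(row["focus_x"]), int(row["focus_y"])),
    )


# --------------------------------------------------------------------------
# generator-side quality metrics

def _luminance(pixels: np.ndarray) -> np.ndarray:
    p = pixels.astype(float) / 255.0 if pixels.dtype == np.uint8 else pixels
    return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]


def separability(pixels: np.ndarray, mask: np.ndarray, band: int = 3) -> float:
    """Leaf/background contrast across the mask boundary.

    Mean absolute luminance difference between a band just inside and a band
    just outside the mask boundary; the generator's fixed metric under which
    back light >= plain >= natural on average.
    """
    inner = mask & ~ndimage.binary_erosion(mask, iterations=band)
    outer = ndimage.binary_dilation(mask, iterations=band) & ~mask
    if not inner.any() or not outer.any():
        return 0.0
    lum = _luminance(pixels)
    return float(abs(lum[inner].mean() - lum[outer].mean()))


def venation_contrast(pixels: np.ndarray, mask: np.ndarray) -> float:
    """Mean gradient energy inside the blade interior (venation visibility).

    Luminance is lightly smoothed first so per-pixel sensor noise does not
    register as texture; structured venation edges survive the smoothing.
    """
    from skimage import filters

    interior = ndimage.binary_erosion(mask, iterations=4)
    if not interior.any():
        return 0.0
    grad = filters.sobel(ndimage.gaussian_filter(_luminance(pixels), 1.0))
    return float(grad[interior].mean())


def shape_descriptor(mask: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Scale/translation-invariant radial signature of a mask outline.

    Histogram of boundary-pixel distances from the centroid, normalized by
    the mean radius — a cheap shape fingerprint used to sanity-check that
    species are distinguishable from geometry alone.
    """
    boundary = mask & ~ndimage.binary_erosion(mask)
    ys, xs = np.nonzero(boundary)
    cy, cx = np.nonzero(mask)[0].mean(), np.nonzero(mask)[1].mean()
    r = np.hypot(ys - cy, xs - cx)
    r = r / (r.mean() + 1e-12)
    hist, _ = np.histogram(r, bins=n_bins, range=(0, 2.5), density=True)
    n_comp = ndimage.label(mask)[1]
    return np.concatenate([hist, [n_comp]])
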