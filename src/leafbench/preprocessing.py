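"""The three image-preparation strategies: none, crop, segment.

*none* passes the original pixels through.  *crop* cuts the image to a
bounding box enclosing the leaf.  *segment* runs semi-automated figure/
ground segmentation: the image is downscaled to at most 400 px on its long
side, GrabCut is initialized with a rectangle at the focus area (image
corners as background seeds), a simulated user iteratively places
foreground/background markers on the worst-error region until the mask is
good enough or a marker budget is exhausted, the low-resolution mask is
upsampled and its boundary re-cut with a color watershed after eroding the
labels, and the image is finally cropped to the mask with non-leaf pixels
filled mid-gray.  Marker counts are logged — they drive the per-image
effort accounting downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.segmentation import watershed
from skimage.transform import resize

from .grabcut import GrabCutConfig, GrabCutResult, grabcut
from .synthetic import ImageRecord

__all__ = [
    "BoundingBox",
    "Marker",
    "SegmentationResult",
    "SegmentationConfig",
    "crop",
    "crop_record",
    "downscale_for_segmentation",
    "init_rect_from_focus",
    "grabcut_iterate",
    "simulate_user",
    "refine_fullres",
    "segment",
    "iou",
]

MAX_SEGMENTATION_SIDE = 400


@dataclass(frozen=True)
class BoundingBox:
    """0-based, half-open pixel rectangle."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate bounding box {self}")

    def validate_for(self, shape: tuple[int, int]) -> None:
        h, w = shape[:2]
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise ValueError(f"bounding box {self} outside image {w}x{h}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


@dataclass(frozen=True)
class Marker:
    """A user-placed point constraint in the low-resolution frame."""

    point: tuple[int, int]          # (x, y)
    label: str                      # "foreground" | "background"

    def __post_init__(self) -> None:
        if self.label not in ("foreground", "background"):
            raise ValueError(f"invalid marker label {self.label!r}")


@dataclass
class SegmentationResult:
    mask: np.ndarray                # bool, original resolution
    marker_count: int
    converged: bool
    cropped_image: np.ndarray       # uint8, crop of the masked image
    markers: list = field(default_factory=list)
    low_iou: float = float("nan")   # low-res IoU vs ground truth, if known


@dataclass
class SegmentationConfig:
    rect_fraction: float = 0.5      # init rectangle side as fraction of image side
    grabcut_iters: int = 5
    refine_iters: int = 2           # GrabCut rounds per marker re-run
    iou_target: float = 0.95        # simulated-user stop criterion
    max_markers: int = 20
    erosion_radius: int = 3         # label erosion before the watershed re-cut
    fill_value: int = 128           # gray fill outside the mask in the crop
    grabcut: GrabCutConfig = field(default_factory=GrabCutConfig)


# --------------------------------------------------------------------------
# cropping and scaling

def crop(image: np.ndarray, bbox: BoundingBox) -> np.ndarray:
    """Cut ``bbox`` out of ``image``; pixels are bit-identical to the source."""
    bbox.validate_for(image.shape)
    return image[bbox.y0:bbox.y1, bbox.x0:bbox.x1].copy()


def crop_record(record: ImageRecord) -> np.ndarray:
    """Crop a record to its ground-truth leaf bounding box."""
    return crop(record.pixels, BoundingBox(*record.gt_bbox))


def downscale_for_segmentation(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Resize so the longest side is at most 400 px, keeping aspect ratio.

    Returns (low-res uint8 image, scale factor low/original).  Images already
    small enough pass through unchanged with scale 1.
    """
    h, w = image.shape[:2]
    longest = max(h, w)
    if longest <= MAX_SEGMENTATION_SIDE:
        return image, 1.0
    s = MAX_SEGMENTATION_SIDE / longest
    new_h, new_w = int(round(h * s)), int(round(w * s))
    low = resize(image, (new_h, new_w), order=1, anti_aliasing=True,
                 preserve_range=True)
    return low.round().astype(np.uint8), s


def init_rect_from_focus(focus_point: tuple[int, int], size: tuple[int, int],
                         fraction: float = 0.5) -> BoundingBox:
    """Initial GrabCut rectangle centered on the focus point.

    ``size`` is the low-resolution (width, height); ``focus_point`` must
    already be in that frame.  Each side spans ``fraction`` of the
    corresponding image side.  The rectangle keeps a 1-px border margin so
    the image corners always remain available as background seeds.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    w, h = size
    fx, fy = focus_point
    half_w = max(1, int(round(fraction * w / 2)))
    half_h = max(1, int(round(fraction * h / 2)))
    x0 = int(np.clip(fx - half_w, 1, w - 2))
    x1 = int(np.clip(fx + half_w, x0 + 1, w - 1))
    y0 = int(np.clip(fy - half_h, 1, h - 2))
    y1 = int(np.clip(fy + half_h, y0 + 1, h - 1))
    return BoundingBox(x0, y0, x1, y1)


# --------------------------------------------------------------------------
# segmentation

def grabcut_iterate(low_image: np.ndarray, rect: BoundingBox,
                    markers: list[Marker] = (), iters: int = 5, seed: int = 0,
                    config: GrabCutConfig | None = None) -> GrabCutResult:
    """One GrabCut solve honoring the marker hard constraints."""
    pairs = [(m.point, m.label) for m in markers]
    return grabcut(low_image, rect.as_tuple(), pairs, iters=iters, seed=seed,
                   config=config)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def simulate_user(
    low_image: np.ndarray,
    rect: BoundingBox,
    initial: GrabCutResult,
    low_gt: np.ndarray,
    max_markers: int = 20,
    iou_target: float = 0.95,
    seed: int = 0,
    iters: int = 5,
    config: GrabCutConfig | None = None,
) -> tuple[list[Marker], np.ndarray, float]:
    """Reproducible stand-in for the interactive refinement loop.

    Repeatedly places one marker at the centroid of the largest
    misclassified connected region (labeled with the ground truth there) and
    re-runs GrabCut, until the mask reaches ``iou_target`` or the budget is
    spent.  A foreground marker outside the current rectangle also expands
    the rectangle to cover it (the user re-framing the potential-foreground
    region, as when part of a compound leaf lies outside the focus area).
    A re-cut that worsens the overlap is rejected (the user keeps the
    previous mask), so the returned mask's IoU never decreases below the
    initial one.  Returns (markers used, final low-res mask, IoU).
    """
    h, w = low_image.shape[:2]
    mask = initial.mask
    best_iou = iou(mask, low_gt)
    markers: list[Marker] = []
    used_points: set = set()
    margin = 12
    while best_iou < iou_target and len(markers) < max_markers:
        wrong = mask ^ low_gt
        labels, n = ndimage.label(wrong)
        if n == 0:
            break
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        point = None
        for worst in (np.argsort(sizes)[::-1] + 1):
            ys, xs = np.nonzero(labels == worst)
            cy, cx = ys.mean(), xs.mean()
            i = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))
            cand = (int(xs[i]), int(ys[i]))
            if cand not in used_points:
                point = cand
                break
        if point is None:
            break  # every remaining error region already marked: user gives up
        used_points.add(point)
        label = "foreground" if low_gt[point[1], point[0]] else "background"
        markers.append(Marker(point=point, label=label))
        if label == "foreground":
            rect = BoundingBox(
                min(rect.x0, max(1, point[0] - margin)),
                min(rect.y0, max(1, point[1] - margin)),
                max(rect.x1, min(w - 1, point[0] + margin)),
                max(rect.y1, min(h - 1, point[1] + margin)),
            )
        res = grabcut_iterate(low_image, rect, markers, iters=iters, seed=seed,
                              config=config)
        new_iou = iou(res.mask, low_gt)
        if new_iou >= best_iou:
            mask, best_iou = res.mask, new_iou
    return markers, mask, best_iou


def refine_fullres(low_mask: np.ndarray, image: np.ndarray,
                   erosion_radius: int = 3) -> np.ndarray:
    """Upsample a low-res mask and re-cut its boundary on the color image.

    The mask is nearest-neighbor upscaled to the image size, foreground and
    background are eroded by ``erosion_radius`` to form watershed seeds, and
    a watershed on the summed per-channel color gradient re-assigns the
    boundary band — snapping the segmentation to full-resolution edges.
    """
    h, w = image.shape[:2]
    if low_mask.shape != (h, w):
        mask = resize(low_mask.astype(float), (h, w), order=0,
                      preserve_range=True) > 0.5
    else:
        mask = low_mask.astype(bool)
    if erosion_radius <= 0 or not mask.any() or mask.all():
        return mask
    selem = morphology.disk(erosion_radius)
    fg_seed = ndimage.binary_erosion(mask, structure=selem)
    bg_seed = ndimage.binary_erosion(~mask, structure=selem, border_value=1)
    if not fg_seed.any() or not bg_seed.any():
        return mask
    img = image.astype(float) / 255.0
    gradient = np.zeros((h, w))
    for ch in range(img.shape[2]):
        gy, gx = np.gradient(img[..., ch])
        gradient += np.hypot(gx, gy)
    seeds = np.zeros((h, w), dtype=np.int32)
    seeds[bg_seed] = 1
    seeds[fg_seed] = 2
    basins = watershed(gradient, seeds)
    return basins == 2


def segment(record: ImageRecord, config: SegmentationConfig | None = None,
            seed: int = 0) -> SegmentationResult:
    """Full semi-automated segmentation of one record, with effort logging."""
    cfg = config or SegmentationConfig()
    low, scale = downscale_for_segmentation(record.pixels)
    lh, lw = low.shape[:2]
    fx = min(int(round(record.focus_point[0] * scale)), lw - 1)
    fy = min(int(round(record.focus_point[1] * scale)), lh - 1)
    rect = init_rect_from_focus((fx, fy), (lw, lh), cfg.rect_fraction)

    result = grabcut_iterate(low, rect, [], iters=cfg.grabcut_iters, seed=seed,
                             config=cfg.grabcut)
    if scale == 1.0:
        low_gt = record.gt_mask
    else:
        low_gt = resize(record.gt_mask.astype(float), (lh, lw), order=0,
                        preserve_range=True) > 0.5
    markers, low_mask, low_iou = simulate_user(
        low, rect, result, low_gt, max_markers=cfg.max_markers,
        iou_target=cfg.iou_target, seed=seed, iters=cfg.refine_iters,
        config=cfg.grabcut)

    mask = refine_fullres(low_mask, record.pixels, cfg.erosion_radius)
    converged = bool(mask.any()) and low_iou >= cfg.iou_target

    if mask.any():
        ys, xs = np.nonzero(mask)
        bbox = BoundingBox(int(xs.min()), int(ys.min()),
                           int(xs.max()) + 1, int(ys.max()) + 1)
    else:  # degenerate: fall back to the full frame
        bbox = BoundingBox(0, 0, record.pixels.shape[1], record.pixels.shape[0])
    cropped = crop(record.pixels, bbox)
    crop_mask = crop(mask.astype(np.uint8), bbox).astype(bool)
    cropped[~crop_mask] = cfg.fill_value

    return SegmentationResult(mask=mask, marker_count=len(markers),
                              converged=converged, cropped_image=cropped,
                              markers=markers, low_iou=low_iou)
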