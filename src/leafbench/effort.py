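"""Manual-effort accounting and the accuracy–effort gain statistic.

Effort is measured in *person-seconds*: elapsed seconds multiplied by the
number of people the task requires.  A single photographer suffices for
natural-background shots; plain-background and back-light shots need a
second person to hold the sheet and arrange the leaf.

The gain statistic compares a combination *i* of image type and
preprocessing strategy against a baseline *b* (top-side, natural background,
no preprocessing):

    G_i = (a_i - a_b) / a_b * e_b / (e_i - e_b)

with a the accuracy (percent) and e the per-image effort (person-seconds).
G_i relates the relative accuracy improvement to the relative extra effort;
it is only defined for combinations costlier than the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .synthetic import IMAGE_TYPES

__all__ = [
    "EffortModel",
    "GainResult",
    "UndefinedGainError",
    "BASELINE_KEY",
    "preprocessing_effort",
    "total_effort",
    "gain",
    "gain_table",
]

STRATEGIES = ("none", "crop", "segment")

#: top side, natural background, no flash, unpreprocessed — the cheapest
#: combination, against which every gain is computed.
BASELINE_KEY = ("top_flash_off_natural", "none")


def _default_acquisition() -> dict:
    # Seconds per shot by (perspective, background); flash does not change
    # the handling time.  Only the baseline (top/natural, 13.4 s with one
    # person) is an empirically anchored value; the others are plausible
    # configuration defaults ordered by handling difficulty (bending the
    # leaf for back sides, arranging the sheet, plucking for back light).
    return {
        ("top", "natural"): 13.4,
        ("back", "natural"): 20.0,
        ("top", "plain"): 16.0,
        ("back", "plain"): 22.0,
        ("backlight", "n/a"): 18.0,
    }


def _default_persons() -> dict:
    return {"natural": 1, "plain": 2, "n/a": 2}


@dataclass
class EffortModel:
    """Per-image acquisition and preprocessing times, in seconds."""

    acquisition_seconds: dict = field(default_factory=_default_acquisition)
    persons: dict = field(default_factory=_default_persons)
    crop_seconds: float = 6.8
    marker_seconds: float = 4.7
    confirm_seconds: float = 2.0
    # enabling the flash adds a little handling and recycle time per shot;
    # this also keeps every flash-on combination strictly costlier than its
    # flash-off counterpart so the gain statistic is defined for all of them
    flash_extra_seconds: float = 0.5

    def __post_init__(self) -> None:
        times = list(self.acquisition_seconds.values()) + [
            self.crop_seconds, self.marker_seconds, self.confirm_seconds]
        if any(t <= 0 for t in times):
            raise ValueError("all effort times must be positive")
        for bg, n in self.persons.items():
            if n not in (1, 2):
                raise ValueError(f"persons must be 1 or 2, got {n} for {bg!r}")

    @property
    def baseline_effort(self) -> float:
        """e_b: person-seconds of the top/natural unpreprocessed image."""
        return total_effort(BASELINE_KEY[0], "none", 0, self)

    @classmethod
    def from_yaml(cls, path) -> "EffortModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        acq = {tuple(k.split("/", 1)): float(v)
               for k, v in raw["acquisition_seconds"].items()}
        return cls(
            acquisition_seconds=acq,
            persons={k: int(v) for k, v in raw.get("persons", _default_persons()).items()},
            crop_seconds=float(raw.get("crop_seconds", 6.8)),
            marker_seconds=float(raw.get("marker_seconds", 4.7)),
            confirm_seconds=float(raw.get("confirm_seconds", 2.0)),
            flash_extra_seconds=float(raw.get("flash_extra_seconds", 0.5)),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "acquisition_seconds": {"/".join(k): v for k, v in self.acquisition_seconds.items()},
            "persons": dict(self.persons),
            "crop_seconds": self.crop_seconds,
            "marker_seconds": self.marker_seconds,
            "confirm_seconds": self.confirm_seconds,
            "flash_extra_seconds": self.flash_extra_seconds,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


def _split_image_type(image_type: str) -> tuple[str, str]:
    if image_type == "backlight":
        return "backlight", "n/a"
    parts = image_type.split("_")  # <perspective>_flash_<on|off>_<background>
    return parts[0], parts[-1]


def preprocessing_effort(strategy: str, marker_count: int = 0,
                         model: EffortModel | None = None) -> float:
    """Seconds of manual preprocessing work for one image.

    none: 0; crop: drawing a bounding box; segment: confirming the result
    plus one marker-placement cost per refinement marker (confirm-only when
    ``marker_count`` is 0).
    """
    model = model or EffortModel()
    if strategy == "none":
        return 0.0
    if strategy == "crop":
        return model.crop_seconds
    if strategy == "segment":
        if marker_count < 0:
            raise ValueError("marker_count must be >= 0")
        return model.confirm_seconds + model.marker_seconds * marker_count
    raise ValueError(f"unknown strategy {strategy!r}")


def total_effort(image_type: str, strategy: str, marker_count: int = 0,
                 model: EffortModel | None = None) -> float:
    """Person-seconds to produce one image of a combination.

    Acquisition seconds x persons for the image type, plus the (single
    person) preprocessing seconds.
    """
    model = model or EffortModel()
    if image_type not in IMAGE_TYPES:
        raise ValueError(f"unknown image type {image_type!r}")
    perspective, background = _split_image_type(image_type)
    acq = model.acquisition_seconds[(perspective, background)]
    if "flash_on" in image_type:
        acq = acq + model.flash_extra_seconds
    return acq * model.persons[background] + preprocessing_effort(strategy, marker_count, model)


class UndefinedGainError(ValueError):
    """The gain statistic is undefined (combination not costlier than baseline)."""


def gain(a_i: float, e_i: float, a_b: float, e_b: float) -> float:
    """Accuracy–effort gain G_i = (a_i - a_b)/a_b * e_b/(e_i - e_b)."""
    if a_b <= 0:
        raise ValueError(f"baseline accuracy must be positive, got {a_b}")
    if e_b <= 0:
        raise ValueError(f"baseline effort must be positive, got {e_b}")
    if e_i <= e_b:
        raise UndefinedGainError(
            f"gain defined only for e_i > e_b, got e_i={e_i}, e_b={e_b}")
    return (a_i - a_b) / a_b * e_b / (e_i - e_b)


@dataclass(frozen=True)
class GainResult:
    image_type: str
    strategy: str
    a_i: float
    e_i: float
    a_b: float
    e_b: float
    G_i: float


def gain_table(
    accuracies: Mapping[tuple[str, str], float],
    marker_counts: Mapping[tuple[str, str], float] | None = None,
    model: EffortModel | None = None,
    baseline_key: tuple[str, str] = BASELINE_KEY,
) -> list[GainResult]:
    """Gain of every non-baseline (image type, strategy) combination.

    ``accuracies`` maps each combination to its mean accuracy in percent;
    ``marker_counts`` supplies the mean logged marker count per segmented
    combination (0 where absent).  The baseline itself is excluded.
    """
    model = model or EffortModel()
    marker_counts = marker_counts or {}
    a_b = accuracies[baseline_key]
    e_b = total_effort(baseline_key[0], baseline_key[1], 0, model)
    out = []
    for key in sorted(accuracies):
        if key == baseline_key:
            continue
        image_type, strategy = key
        markers = marker_counts.get(key, 0.0) if strategy == "segment" else 0.0
        e_i = total_effort(image_type, strategy, markers, model)
        out.append(GainResult(image_type, strategy, float(accuracies[key]),
                              e_i, float(a_b), e_b,
                              gain(float(accuracies[key]), e_i, a_b, e_b)))
    return out
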