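"""Shared fixtures: small species banks and rendered observations.

Everything is generated programmatically at fixed seeds; no image files are
stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from leafbench import synthetic


@pytest.fixture(scope="session")
def bank5():
    return synthetic.generate_species_bank(5, seed=7)


@pytest.fixture(scope="session")
def small_config():
    """A reduced frame size for unit tests that don't need the 400-px
    segmentation downscale path."""
    return synthetic.GeneratorConfig(width=256, height=192)


@pytest.fixture(scope="session")
def observation(bank5):
    """Nine records of one observation at the default frame size."""
    return synthetic.generate_observation(bank5[0], "obs-fix", seed=42,
                                          distractor_specs=bank5)


@pytest.fixture(scope="session")
def observation_small(bank5, small_config):
    return synthetic.generate_observation(bank5[1], "obs-small", seed=43,
                                          config=small_config,
                                          distractor_specs=bank5)


def make_single_record(spec, background: str, illumination: str, seed: int,
                       config=None, distractors=()):
    """Render just one reflected-light record (cheaper than a full
    observation when a test needs many fixtures of one condition)."""
    from leafbench.synthetic import (GeneratorConfig, ImageRecord, _colorize,
                                     _focus_point, _render_geometry,
                                     _tight_bbox, composite)

    cfg = config or GeneratorConfig()
    geom = _render_geometry(spec, seed, (cfg.width, cfg.height), cfg.jitter)
    layer = _colorize(geom, spec, "top")
    pixels = composite(layer, background, illumination, distractors, seed, cfg)
    mask = layer.alpha
    return ImageRecord(
        observation_id=f"fix{seed}", species_id=spec.species_id,
        perspective="top", illumination=illumination, background=background,
        pixels=pixels, gt_mask=mask, gt_bbox=_tight_bbox(mask),
        focus_point=_focus_point(mask),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
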