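"""Shared fixtures: small phantoms and geometries sized for fast tests."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lvreg import (
    CArmGeometry,
    PhantomConfig,
    generate_phantom,
    render_drr,
)

#: compact phantom: 48^3 at 4 mm (192 mm cube), same anatomy layout
SMALL = PhantomConfig(shape=(48, 48, 48), spacing_mm=4.0, seed=7)


@pytest.fixture(scope="session")
def geometry():
    return CArmGeometry()


@pytest.fixture(scope="session")
def small_phantom():
    """(volume, model) for the compact default phantom."""
    return generate_phantom(SMALL)


@pytest.fixture(scope="session")
def lv_only_phantom():
    """Phantom with only the LV structure (all confounders transparent)."""
    cfg = replace(
        SMALL,
        body_attenuation=0.0,
        lung_attenuation=0.0,
        spine_attenuation=0.0,
        liver_attenuation=0.0,
        noise_sigma=0.0,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def small_fixed(small_phantom):
    """96 px / 300 mm DRR of the compact phantom, LV-centred geometry."""
    vol, model = small_phantom
    geo = CArmGeometry().with_center(model.center)
    return render_drr(vol, geo, size=96), geo, model
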