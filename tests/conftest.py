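import numpy as np
import pytest

from puncta import (
    SpotParams,
    SynthConfig,
    assign_spots,
    calibrate_unit_intensity,
    detect_spots,
    generate_field,
    segment_nuclei,
)
from puncta.spots import count_all_copies


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic study field: 20 nuclei, one probe at mean 5
    copies per cell, default signal-to-background, fixed seed."""
    cfg = SynthConfig(seed=7)
    field, truth = generate_field(cfg)
    return cfg, field, truth


@pytest.fixture(scope="session")
def processed_scene(default_scene):
    """Default field run through segmentation, detection, copy counting
    and assignment (shared across tests to keep the suite fast)."""
    cfg, field, truth = default_scene
    nuclei = segment_nuclei(field.counterstain, field.pixel_size_um)
    spots = detect_spots(field.channels["PPIB"], field.pixel_size_um, probe="PPIB")
    unit = calibrate_unit_intensity(spots)
    count_all_copies(spots, unit)
    assign_spots(nuclei, spots)
    return cfg, field, truth, nuclei, spots, unit


def gaussian_spot_image(
    shape=(64, 64),
    center_px=(32.0, 32.0),
    sigma_px=1.5,
    integrated=1.5,
    background=0.0,
):
    """A single normalized-sum Gaussian spot on a flat background."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    g = np.exp(
        -((rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2) / (2 * sigma_px**2)
    )
    return background + integrated * g / g.sum()
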