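import numpy as np
import pytest

from condensate.io_formats import CircleRoi, ImagingMeta
from condensate import synth_data as sd


@pytest.fixture
def meta64():
    """0.1 um/px, 0.2 s/frame, single channel, 64x64."""
    return ImagingMeta(
        pixel_size_um=0.1,
        frame_interval_s=0.2,
        channel_names=("GFP",),
        height_px=64,
        width_px=64,
    )


@pytest.fixture
def meta64_2ch():
    return ImagingMeta(
        pixel_size_um=0.1,
        frame_interval_s=0.2,
        channel_names=("GFP", "RFP"),
        height_px=96,
        width_px=96,
    )


@pytest.fixture
def frap_setup(meta64):
    """Droplet + bleach ROI + background ROI for recovery experiments."""
    droplet = sd.DropletSpec(center_px=(31.5, 31.5), diameter_um=3.0, peak_intensity=100.0)
    bleach = CircleRoi((31.5, 31.5), 1.5, label="bleach")
    background = CircleRoi((8.0, 8.0), 0.6, label="background")
    return meta64, droplet, bleach, background


def tangent_parents(diameter_um, pixel_size_um=0.1, center=(31.5, 31.5), peak=100.0):
    """Two equal tangent droplets centered on the frame, lying along x."""
    r_px = diameter_um / (2 * pixel_size_um)
    cx, cy = center
    return (
        sd.DropletSpec((cx - r_px, cy), diameter_um, peak),
        sd.DropletSpec((cx + r_px, cy), diameter_um, peak),
    )


def grid_centers(n, spacing_px=24.0, origin_px=20.0, per_row=5):
    return [
        (origin_px + spacing_px * (i % per_row), origin_px + spacing_px * (i // per_row))
        for i in range(n)
    ]
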