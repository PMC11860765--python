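import numpy as np
import pytest

from censtab import synthetic as syn


@pytest.fixture
def small_field():
    """A small deterministic 2D field with known foci."""
    spec = syn.ImageFieldSpec(
        width=256, height=256, n_cells=6, foci_per_cell=4,
        focus_amplitude=800.0, focus_sigma=1.5,
        background_level=120.0, noise_sd=10.0, nucleus_radius=26.0, seed=11,
    )
    image, labels, truth = syn.make_exofish_field(spec)
    return spec, image, labels, truth


@pytest.fixture
def two_channel_stack():
    """A small 3D stack with one engineered 0.5-overlap pair per nucleus."""
    channels = (
        syn.ChannelSpec("cenpb", n_spots=2, spot_radius_um=0.25, amplitude=1500.0),
        syn.ChannelSpec("halo", n_spots=2, spot_radius_um=0.25, amplitude=1500.0),
    )
    spec = syn.StackSpec(
        shape_zyx=(15, 180, 180), n_nuclei=2, nucleus_radius_um=3.0,
        channels=channels,
        engineered_overlaps=(
            syn.EngineeredOverlap("cenpb", "halo", 0.5),
            syn.EngineeredOverlap("cenpb", "halo", 0.5),
        ),
        seed=7,
    )
    data, truth = syn.make_stack(spec)
    return spec, data, truth
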