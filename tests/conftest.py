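"""Shared fixtures: small synthetic configurations sized for fast tests.

The generator defaults describe the full-scale acquisition (512×512,
102 frames); tests run the same processes on smaller fields and shorter
movies with the ring geometry scaled alongside, which leaves every
statistical property intact at a fraction of the cost.
"""

import pytest

from woundsight import EventProcessParams, SimConfig


@pytest.fixture
def small_cfg() -> SimConfig:
    """32 µm field, 2 pre-wound + 43 post-wound frames, wound at center."""
    return SimConfig(
        image_shape=(128, 128),
        pixel_size=0.25,
        n_frames=45,
        n_prewound_frames=2,
        reseal_time=30.0,
        cell_axes=(14.5, 14.5),
        rng_seed=0,
    )


@pytest.fixture
def small_proc() -> EventProcessParams:
    """Event process matched to the small field: rings step 4 µm in diameter."""
    return EventProcessParams(ring_increment=4.0)


@pytest.fixture
def steady_only_proc() -> EventProcessParams:
    """Homogeneous background only — no wound-evoked bursts."""
    return EventProcessParams(
        exo_boost_by_ring=(1.0,) * 6,
        endo_boost=0.0,
        ring_increment=4.0,
    )
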