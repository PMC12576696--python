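import numpy as np
import pytest

from qbrm.core import reconstruct_parameter_map, render_rgb
from qbrm.synth import (
    SectionSimConfig,
    generate_polarization_stack,
    generate_section_truth,
)


def simulate_rgb(config: SectionSimConfig):
    """Simulate a section and return (truth, reconstructed RGB rendering)."""
    truth = generate_section_truth(config)
    stack = generate_polarization_stack(truth, config)
    return truth, render_rgb(reconstruct_parameter_map(stack))


@pytest.fixture(scope="session")
def small_section():
    """One 256 px section with a healthy number of debris objects."""
    config = SectionSimConfig(
        image_height_px=256, image_width_px=256, debris_density_per_mm2=120.0, seed=11
    )
    truth, rgb = simulate_rgb(config)
    return config, truth, rgb


@pytest.fixture(scope="session")
def trained_detector():
    """Reference detector calibrated on a few simulated sections.

    Session-scoped: training is deterministic, so sharing it across tests
    only saves time.
    """
    from qbrm.detect import TilingConfig, crop_training_patches, train_reference_detector

    patches = []
    for seed in range(3):
        config = SectionSimConfig(
            image_height_px=512,
            image_width_px=512,
            debris_density_per_mm2=80.0,
            seed=seed,
        )
        truth, rgb = simulate_rgb(config)
        patches.extend(
            (p, b)
            for p, b, _ in crop_training_patches(rgb, truth.debris_boxes, TilingConfig())
        )
    detector, log = train_reference_detector(patches)
    return detector, log
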