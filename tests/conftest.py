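import numpy as np
import pytest

from osseoquant import (
    DegradationSpec,
    LabeledVolume,
    ScrewSpec,
    generate_phantom,
    generate_screw,
)

COARSE_SPACING = 0.2  # mm; keeps unit-test phantoms small


@pytest.fixture(scope="session")
def screw_spec():
    return ScrewSpec()


@pytest.fixture(scope="session")
def coarse_screw(screw_spec):
    """Canonical 3.5 x 16 mm screw voxelized at 0.2 mm."""
    return generate_screw(screw_spec, COARSE_SPACING)


@pytest.fixture(scope="session")
def coarse_phantom():
    """Full phantom with degradation and one gas pocket, 0.2 mm spacing."""
    return generate_phantom(
        seed=7,
        spacing=COARSE_SPACING,
        degradation_spec=DegradationSpec(
            recession_depth=0.1,
            layer_thickness=0.2,
            gas_pockets=(((4.0, 3.0, 0.0), 0.8), ((13.0, -2.5, 1.0), 0.5)),
        ),
    )


@pytest.fixture
def digital_sphere():
    """Digital sphere, radius 2 mm at 0.05 mm spacing (center-in-solid)."""
    s, n = 0.05, 90
    ax = (np.arange(n) - n / 2 + 0.5) * s
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (zz**2 + yy**2 + xx**2) <= 4.0
    return LabeledVolume(np.where(mask, 1, 0).astype(np.uint8), (s, s, s))


def make_random_labels(rng, shape=(16, 16, 16)):
    """Random 5-class label volume for oracle comparisons."""
    return rng.integers(0, 5, size=shape).astype(np.uint8)
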