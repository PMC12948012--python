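import numpy as np
import pytest

from speckleflow.forward import (
    PatternStack,
    generate_coded_mask,
    make_trajectory,
    render_reference_stack,
)
from speckleflow.optics import OpticsConfig


@pytest.fixture(scope="session")
def optics():
    """Beamline configuration used throughout: 14 keV, 0.5 m, 0.65 um pixels."""
    return OpticsConfig(energy_keV=14.0, distance_m=0.5, pixel_size_um=0.65)


@pytest.fixture(scope="session")
def small_reference(optics):
    """A 64x64 reference stack with N=6 scan positions (session-cached)."""
    pattern = generate_coded_mask(shape=(160, 160), seed=21)
    trajectory = make_trajectory("diagonal", 6, 3.0, seed=21)
    return render_reference_stack(pattern, trajectory, optics, (64, 64), seed=21)


@pytest.fixture(scope="session")
def medium_reference(optics):
    """A 128x128 reference stack with N=20 scan positions (session-cached)."""
    pattern = generate_coded_mask(shape=(384, 384), seed=5)
    trajectory = make_trajectory("diagonal", 20, 3.0, seed=5)
    return render_reference_stack(pattern, trajectory, optics, (128, 128), seed=5)
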