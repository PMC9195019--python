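import numpy as np
import pytest

import epidpsm as ep


@pytest.fixture(scope="session")
def desk_geometry():
    """Desk-scale panel: 238 x 238 pixels over the full 400 mm active area."""
    return ep.PanelGeometry(238, 238, 400.0)


@pytest.fixture(scope="session")
def odd_geometry():
    return ep.PanelGeometry(33, 33, 400.0)


@pytest.fixture(scope="session")
def beams():
    return ep.beam_library()


@pytest.fixture(scope="session")
def truth_psm(desk_geometry):
    """Default-condition truth PSM: ±2% smooth, 0.5% pixel noise, 0.1% dead."""
    return ep.make_truth_psm(ep.PsmTruthModel(seed=42), desk_geometry)


@pytest.fixture(scope="session")
def unit_psm(desk_geometry):
    """A perfectly uniform panel."""
    model = ep.PsmTruthModel(
        lowfreq_amplitude=0.0, pixel_sigma=0.0, dead_pixel_fraction=0.0, seed=0
    )
    return ep.make_truth_psm(model, desk_geometry)


@pytest.fixture(scope="session")
def flat_beam():
    """A beam with no spatial structure at all: B identically 1 on the panel."""
    return ep.BeamModel(
        "flat", "flattened", horn_coeff=0.0, rolloff_coeff=0.0, collimator_radius_mm=1e6
    )


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
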