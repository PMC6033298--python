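import numpy as np
import pytest

from histostep import morphometry, synth


@pytest.fixture(scope="session")
def desk_threshold_params():
    return morphometry.PhansalkarParams(window_radius=9)


@pytest.fixture(scope="session")
def desk_watershed_params():
    return morphometry.WatershedParams(min_seed_separation=3, min_area=6)


@pytest.fixture(scope="session")
def separated_nuclei_patch():
    """A noiseless patch with 10 well-separated nuclei plus its truth."""
    rng = np.random.default_rng(7)
    nuclei = synth.sample_nonoverlapping_nuclei(rng, 10, (4.0, 6.0), (128, 128))
    assert len(nuclei) == 10
    return synth.render_patch(nuclei, background_eosin=0.25, shape=(128, 128))
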