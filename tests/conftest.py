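import numpy as np
import pandas as pd
import pytest

from affectloop.synthetic import StimulusCatalog, generate_stimulus_catalog, make_subject


@pytest.fixture(scope="session")
def catalog():
    return generate_stimulus_catalog(300, seed=11)


@pytest.fixture(scope="session")
def corner_catalog():
    """Four corners of the score plane plus the centroid."""
    return StimulusCatalog(
        pd.DataFrame(
            {
                "stim_id": ["c11", "c19", "c91", "c99", "mid"],
                "valence": [1.0, 1.0, 9.0, 9.0, 5.0],
                "arousal": [1.0, 9.0, 1.0, 9.0, 5.0],
            }
        )
    )


@pytest.fixture
def subject():
    return make_subject("s000", n_voxels=80, noise_sd=0.2, controllability=0.6, seed=3)


@pytest.fixture
def quiet_subject():
    return make_subject("s001", n_voxels=80, noise_sd=0.0, controllability=0.6, seed=4)


@pytest.fixture
def ps_schedule():
    onsets = 8.0 * np.arange(12)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": 2.0,
            "trial_type": "Id-PS",
            "stim_id": [f"im{i:04d}" for i in range(12)],
        }
    )
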