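import numpy as np
import pytest

from optorecruit.imaging import RoiSet
from optorecruit.scenes import SceneConfig, simulate_recruitment_stack


@pytest.fixture(scope="session")
def recruitment_scene():
    """Default noiseless recruitment scene shared across tests."""
    config = SceneConfig()
    stack, truth = simulate_recruitment_stack(config)
    return config, stack, truth


@pytest.fixture(scope="session")
def recruitment_rois(recruitment_scene):
    _, _, truth = recruitment_scene
    return RoiSet(
        masks={
            "membrane": truth.membrane_mask,
            "cytosol": truth.cytosol_mask,
            "background": ~(truth.membrane_mask | truth.cytosol_mask),
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
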