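import numpy as np
import pandas as pd
import pytest

from breastasym.pipelines import scenes_to_feature_table
from breastasym.synthetic import (
    ThermoSceneParams,
    default_separable_dataset,
    generate_thermogram,
)


@pytest.fixture(scope="session")
def symmetric_scene():
    """Noiseless lesion-free scene: exactly mirror-symmetric by construction."""
    return generate_thermogram(ThermoSceneParams(noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def lesion_scenes():
    """Noiseless scenes at three hot-spot amplitudes (full lesion model)."""
    scenes = {}
    for amp in (0.5, 1.0, 2.0):
        params = ThermoSceneParams(
            noise_sd=0.0,
            lesion_side="left",
            lesion_amplitude=amp,
            lesion_sigma=8.0,
            micro_texture=True,
            seed=11,
        )
        scenes[amp] = generate_thermogram(params)
    return scenes


@pytest.fixture(scope="session")
def separable_features() -> pd.DataFrame:
    """Asymmetry-signature table for the standard separable benchmark
    (40 normal vs 40 lesioned scenes, hot spot 2 degC, noise 0.2 degC).

    Session-scoped: segmentation plus 40 Gabor convolutions per scene make
    this the most expensive fixture in the suite.
    """
    scenes, _ = default_separable_dataset(n_per_class=40, delta_t=2.0, noise_sd=0.2, seed=3)
    return scenes_to_feature_table(scenes)
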