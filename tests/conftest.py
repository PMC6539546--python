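import numpy as np
import pytest

from tomatodet import pipeline as pl
from tomatodet import synthetic_scenes as ss


@pytest.fixture(scope="session")
def small_models():
    """Models trained on a reduced scene set — enough to detect reliably."""
    specs = ss.default_training_specs(5)[:14]
    scenes = [ss.generate_scene(s) for s in specs]
    return pl.train_models(scenes, rng_seed=7)


@pytest.fixture(scope="session")
def easy_scene():
    """A sunny two-fruit scene with its annotation."""
    return ss.generate_scene(ss.SceneSpec(n_tomatoes=2, rng_seed=99))


@pytest.fixture(scope="session")
def experiment_result():
    """The full synthetic detection experiment (training + 75 test scenes)."""
    return pl.run_experiment(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
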