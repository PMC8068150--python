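import numpy as np
import pytest

from catk import AnalysisParams, SceneSpec, generate_movie


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic movie shared by read-only tests."""
    spec = SceneSpec(seed=11)
    stack, truth = generate_movie(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def default_params():
    return AnalysisParams()
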