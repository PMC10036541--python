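import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from realitymix.sdt_models import ModelSpec
from realitymix import synthetic_data as syn

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mixing_model():
    return ModelSpec("mixing")


@pytest.fixture(scope="session")
def all_models():
    return [ModelSpec(m) for m in ("source_separation", "perky", "mixing", "mixing_2param")]


@pytest.fixture(scope="session")
def exp1_mixing():
    """Moderate-size Experiment-1 dataset generated under source mixing."""
    return syn.generate_experiment(ModelSpec("mixing"), 1, 300, seed=101)


@pytest.fixture(scope="session")
def exp2_mixing():
    return syn.generate_experiment(ModelSpec("mixing"), 2, 300, seed=102)


@pytest.fixture(scope="session")
def neural_planted():
    """Pattern dataset with the default planted shared-strength axis."""
    return syn.generate_neural(12, seed=103)


@pytest.fixture(scope="session")
def neural_null():
    design = syn.NeuralDesign(
        strength_loading=0.0, content_snr_by_rating=(0.0, 0.0, 0.0, 0.0)
    )
    return syn.generate_neural(12, design, seed=104)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
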