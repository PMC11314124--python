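import numpy as np
import pytest

from lemonsurf.arch import ModelVariant, build_model


@pytest.fixture(scope="session")
def baseline_model():
    return build_model(ModelVariant(num_classes=2), seed=0)


@pytest.fixture(scope="session")
def full_model():
    return build_model(ModelVariant(use_sac=True, use_sod=True, use_cbam=True,
                                    num_classes=2), seed=0)


@pytest.fixture(scope="session")
def variant_counts():
    """Trainable-parameter counts of all eight ablation variants."""
    import itertools
    from lemonsurf.arch import count_parameters
    counts = {}
    for sac, sod, cbam in itertools.product([False, True], repeat=3):
        v = ModelVariant(use_sac=sac, use_sod=sod, use_cbam=cbam, num_classes=2)
        counts[(sac, sod, cbam)] = count_parameters(build_model(v, seed=0))
    return counts


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
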