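import numpy as np
import pytest

from licseg import PhantomSpec, generate_phantom, run_pipeline


@pytest.fixture(scope="session")
def default_case():
    """One default phantom (moderate noise) and its ground truth."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def default_result(default_case):
    stack, _ = default_case
    return run_pipeline(stack)


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_phantom(PhantomSpec(seed=3, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noiseless_plain_liver_case():
    """Noiseless phantom without intrahepatic vessels: the liver tissue label
    is exactly the expected raw FCM segmentation."""
    return generate_phantom(PhantomSpec(seed=3, noise_sigma=0.0, intrahepatic_vessels=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
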