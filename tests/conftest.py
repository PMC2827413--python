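import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_data():
    """One realisation of the default three-experiment study design."""
    from tuberome.simulate import generate_expression
    from tuberome.simulate.expression import default_study_spec

    spec = default_study_spec(seed=11)
    matrices, design, annotation, truth = generate_expression(spec)
    return spec, matrices, design, annotation, truth


@pytest.fixture(scope="session")
def noisefree_sphere():
    """Noise-free, blur-free sphere phantom of radius 15 voxels."""
    from tuberome.simulate import generate_phantom, sphere_spec

    spec = sphere_spec(15.0, spacing=1.0, blur_sigma=0.0, grey_sd=0.0, seed=3)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
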