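import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vertseg import PhantomSpec, RunConfig, generate_phantom, run_noise_sweep, segment

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_phantom():
    """Default vertebra-like phantom (weak arc + double edge + texture), seed 1."""
    spec = PhantomSpec(seed=1)
    image, gt = generate_phantom(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def clean_run(default_phantom):
    """Full-pipeline segmentation of the clean default phantom (shared, expensive)."""
    spec, image, gt = default_phantom
    return segment(image), image, gt, spec


@pytest.fixture(scope="session")
def sweep_runs():
    """Noise sweep at {0, 1, 3, 5, 7}%% salt-and-pepper, 3 replicates (shared)."""
    return run_noise_sweep(RunConfig(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
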