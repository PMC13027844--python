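import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from hsifuse.datacube import make_datacube  # noqa: E402
from hsifuse.phantom import generate_phantom, phantom_reference  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cube():
    """Factory for small seeded random NIR cubes."""

    def _make(shape=(8, 8, 5), seed=0, modality="NIR"):
        r = np.random.default_rng(seed)
        data = r.random(shape).astype(np.float32)
        wl = 960.0 + 2.0 * np.arange(shape[2])
        return make_datacube(data, wl, modality, 76.0)

    return _make


@pytest.fixture(scope="session")
def tiny_phantom():
    """Small phantom (80 x 100 reference grid) for fast structural tests."""
    return generate_phantom(seed=11, scale=0.05)


@pytest.fixture(scope="session")
def default_phantom():
    """The study-scale phantom: seed 42, scale 0.2 (320 x 400 grid)."""
    return generate_phantom(seed=42, scale=0.2)


@pytest.fixture(scope="session")
def pipeline_run(default_phantom):
    """Full default pipeline on the default phantom, singles included."""
    from hsifuse.pipeline import run_default_pipeline

    nir, mir, rgb, truth = default_phantom
    out = run_default_pipeline(nir, mir, rgb, phantom_reference(truth),
                               seed=42, cluster_singles=True)
    out["truth"] = truth
    return out
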