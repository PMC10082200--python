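import numpy as np
import pytest

from orgloc.phantom import Ellipsoid, PhantomSpec, default_spec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A quick-to-render phantom on a 20x128x128 grid."""
    return PhantomSpec(
        shape=(20, 128, 128),
        organs=[
            Ellipsoid(center=(10, 64, 33), semiaxes=(6, 26, 17), intensity=0.78,
                      label="kidney_right")
        ],
        distractors=[],
        noise_sigma=0.005,
        texture_scale=0.16,
        texture_wavelength=24.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_small_spec(small_spec):
    """Noise- and texture-free variant: intensities are exactly two values."""
    import copy

    spec = copy.deepcopy(small_spec)
    spec.noise_sigma = 0.0
    spec.texture_scale = 0.0
    return spec


@pytest.fixture(scope="session")
def clean_small_phantom(clean_small_spec):
    return make_phantom(clean_small_spec)


@pytest.fixture(scope="session")
def fullsize_phantom():
    """One default-geometry 43x512x512 phantom (shared; ~5 s to render)."""
    return make_phantom(default_spec(seed=3))


@pytest.fixture(scope="session")
def demo_config(tmp_path_factory):
    from orgloc.pipeline import RunConfig

    out = tmp_path_factory.mktemp("demo_run")
    return RunConfig(seed=7, out_dir=str(out), ablation=True)


@pytest.fixture(scope="session")
def demo_result(demo_config):
    """The full demo pipeline (10 phantoms, 4-epoch training); shared by the
    acceptance criteria.  Several minutes of CPU."""
    from orgloc.pipeline import run_pipeline

    return run_pipeline(demo_config)
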