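import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230723)


@pytest.fixture(scope="session")
def small_library():
    from metabfuse.synthetic import make_library

    return make_library(10, seed=7)


@pytest.fixture(scope="session")
def two_arm_truth():
    """2 x 8 single-factor design with one planted responder."""
    from metabfuse import synthetic as syn

    lib = syn.make_library(5, seed=3)
    design = syn.StudyDesign(
        [("A", 8), ("B", 8)], {"group": {"A": 0.0, "B": 1.0}}, seed=11
    )
    eff = syn.EffectSpec(affected={"M01": ("group", 1.0)})
    truth = syn.simulate_concentrations(design, lib, eff, sigma=0.3)
    return lib, truth
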