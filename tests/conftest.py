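import numpy as np
import pytest

from evprofile import synth


@pytest.fixture(scope="session")
def small_scenario():
    """Down-scaled five-class dataset shared by the cheaper tests."""
    return synth.default_five_class_scenario(123, n_replicates=4, duration=300.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def minimal_class_spec():
    """One-marker class with full positivity everywhere (kinetics-only tests)."""
    return synth.ClassSpec(
        label="toy",
        size_dist=synth.SizeDistribution(),
        profiles={
            "PSMA": synth.MarkerSizeProfile("PSMA", np.ones(13), k=0.0070, n_max=500)
        },
        total_n_max=1000,
        total_k=0.005,
    )
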