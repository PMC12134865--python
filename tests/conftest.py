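import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A planted transcriptomic cohort reused across tests."""
    from sigrev.synth import CohortSpec, gen_transcriptomic_cohort

    spec = CohortSpec(
        n_group1=20, n_group2=20, n_features=400,
        frac_shifted=0.1, effect_size=2.0, seed=7,
    )
    return gen_transcriptomic_cohort(spec)


@pytest.fixture()
def toy_signature():
    from sigrev.signature import SignedSignature

    return SignedSignature.from_lists(
        up=[f"G{i:04d}" for i in range(1, 11)],
        down=[f"G{i:04d}" for i in range(11, 21)],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
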