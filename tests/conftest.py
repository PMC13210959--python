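import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emgintent as ei

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_PROTOCOL = ei.ProtocolSpec(
    n_blocks=1,
    trials_per_class_per_block=3,
    prep_duration=1.0,
    execution_duration=2.0,
    return_duration=1.0,
    inter_block_rest=5.0,
)


@pytest.fixture(scope="session")
def small_session():
    """A compact noisy session shared by read-only tests."""
    rec, anns = ei.generate_session(
        SMALL_PROTOCOL, ei.default_profiles(), ei.ContaminantSpec(), seed=42
    )
    return rec, anns


@pytest.fixture(scope="session")
def small_batch(small_session):
    rec, anns = small_session
    clean, _ = ei.preprocess_recording(rec)
    return ei.slide_session(
        ei.extract_effective(clean, anns), ei.WindowSpec(fs=rec.fs)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
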