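import dataclasses

import pytest

from vsabci.paradigm import (
    ConditionProfile,
    NoiseSpec,
    ParadigmConfig,
    default_condition_profiles,
    simulate_session,
)
from vsabci.preprocess import standard_chain


@pytest.fixture(scope="session")
def default_session():
    """Full 18-block session with default (realistic) settings."""
    return simulate_session(seed=1234)


@pytest.fixture(scope="session")
def default_epochs(default_session):
    return standard_chain(default_session)


@pytest.fixture(scope="session")
def covert_session():
    """Covert-only session (6 blocks): the jitter-heavy condition."""
    return simulate_session(seed=777, conditions=("covert",))


@pytest.fixture(scope="session")
def covert_epochs(covert_session):
    return standard_chain(covert_session)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free, jitter-free, non-overlapping-epoch session.

    SOA is stretched to 1.5 s so that the [-0.2, 1.0] s visualization window
    of one stimulus never contains a neighboring response, and central
    fixation makes the early visual components identical across stimuli, so
    the target-minus-nontarget contrast isolates the attention component
    exactly.
    """
    cfg = ParadigmConfig(
        isi_nominal_ms=1500.0, isi_jitter_ms=0.0, reps_min=5, reps_max=5,
        conditions=("covert",),
    )
    profile = dataclasses.replace(
        default_condition_profiles()["covert"],
        p3_jitter_sd_ms=0.0, gaze_noise_sd_deg=0.0, dropout_prob_per_eye=0.0,
    )
    from vsabci.paradigm import default_erp_model

    erp = [
        dataclasses.replace(c, latency_jitter_sd_ms=0.0) for c in default_erp_model()
    ]
    return simulate_session(
        cfg=cfg, erp=erp, profiles={"covert": profile}, noise=NoiseSpec(rms_uv=0.0),
        seed=5, conditions=("covert",),
    )


@pytest.fixture(scope="session")
def separable_session():
    """Noise-free overt-only session: perfectly decodable."""
    return simulate_session(noise=NoiseSpec(rms_uv=0.0), seed=7, conditions=("overt",))
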