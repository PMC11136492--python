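import numpy as np
import pytest

from driftdecode.design import StimulusSpec, build_run_schedule
from driftdecode.glm import canonical_block_hrf
from driftdecode.synthdata import (
    EffectConfig,
    NoiseConfig,
    OculomotorConfig,
    default_rois,
    simulate_session,
)


@pytest.fixture(scope="session")
def spec():
    return StimulusSpec()


@pytest.fixture(scope="session")
def hrf_truth():
    return canonical_block_hrf()


@pytest.fixture(scope="session")
def expt2_schedule():
    return build_run_schedule(2, seed=11)


@pytest.fixture(scope="session")
def null_session():
    """Small null session (no condition effects), shared across tests."""
    return simulate_session(2, 4, seed=101)


@pytest.fixture(scope="session")
def effect_session():
    """Session with the study's effect structure injected."""
    return simulate_session(2, 8, seed=202, effects=EffectConfig.study_effects())


@pytest.fixture(scope="session")
def noiseless_session():
    """Deterministic session: effects but no scanner noise."""
    return simulate_session(
        2,
        2,
        seed=303,
        effects=EffectConfig.study_effects(),
        noise=NoiseConfig.none(),
    )
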