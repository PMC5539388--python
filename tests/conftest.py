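import dataclasses

import numpy as np
import pytest

from paconcord import CohortParams


@pytest.fixture
def rng():
    return np.random.default_rng(20120102)


@pytest.fixture
def small_params():
    """A small, fast cohort with the default noise/bias structure."""
    return CohortParams(n_participants=24, n_days=7, seed=11)


@pytest.fixture
def noise_free_params():
    """All noise, bias and missingness switched off: instruments see the truth."""
    return CohortParams(
        n_participants=12,
        n_days=7,
        seed=5,
        ema_noise_sd=0.0,
        questionnaire_bias_factor=1.0,
        questionnaire_noise_cv=0.0,
        ema_completion_prob=1.0,
        accel_compliance_prob=1.0,
    )


def replace_params(params: CohortParams, **kw) -> CohortParams:
    return dataclasses.replace(params, **kw)
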