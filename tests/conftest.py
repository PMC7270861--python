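import numpy as np
import pytest

from walkbeat.simulate import (
    CohortSpec,
    default_high_profile,
    default_low_profile,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_spec(seed=7, n_low=2, n_high=2, noiseless=False, **kw):
    """A small cohort spec for fast end-to-end tests."""
    prof_kw = {}
    if noiseless:
        prof_kw = dict(
            hr_noise_sd=0.0,
            coeff_patient_rel_sd=0.0,
            tau_patient_rel_sd=0.0,
            rest_hr_sd=0.0,
        )
        kw.setdefault("rr_jitter_sd", 0.0)
        kw.setdefault("n_artifact_bursts", 0)
        kw.setdefault("ecg_broadband_sd", 0.0)
    low = default_low_profile(n_patients=n_low, **prof_kw)
    high = default_high_profile(n_patients=n_high, **prof_kw)
    return CohortSpec(profiles=(low, high), seed=seed, **kw)


@pytest.fixture
def small_spec():
    return tiny_spec()


@pytest.fixture
def noiseless_spec():
    return tiny_spec(noiseless=True)
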