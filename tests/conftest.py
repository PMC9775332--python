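import numpy as np
import pytest

from sonokinetics import (
    ReleaseProfile,
    evaluate_cfr,
    get_model,
    list_models,
)


@pytest.fixture(scope="session")
def catalog():
    return list_models()


def make_profile(model_name, params, t, noise_sd=0.0, rng=None, provenance=None):
    """Build a release profile directly from a model curve (+ optional CFR noise).

    Bypasses the trace simulator for fitting tests that only need a known
    CFR-vs-time dataset.
    """
    model = get_model(model_name)
    t = np.asarray(t, dtype=float)
    cfr = np.asarray(evaluate_cfr(model, params, t), dtype=float)
    if noise_sd > 0.0:
        rng = np.random.default_rng(0) if rng is None else rng
        cfr = cfr + rng.normal(0.0, noise_sd, size=t.shape)
    return ReleaseProfile(t_us=t, cfr=cfr, provenance=dict(provenance or {}))


@pytest.fixture
def kp_albumin_profile():
    """Noiseless power-law curve with the published albumin 6.2 mW/cm^2 pair."""
    return make_profile("korsmeyer_peppas", (3.50e-3, 0.73), np.arange(600.0))
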