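import numpy as np
import pytest

from oncostruct.fitting import EndpointDataset, FittedSurvivalModel


def exp_model(rate: float) -> FittedSurvivalModel:
    return FittedSurvivalModel("exponential", [rate])


def random_stm5_models(rng) -> dict[str, FittedSurvivalModel]:
    """Random but plausible driving curves (mixed exponential/weibull) for
    property tests over the five-state engine."""
    def rand_model():
        if rng.random() < 0.5:
            return FittedSurvivalModel("exponential", [rng.uniform(1e-4, 8e-3)])
        shape = rng.uniform(0.6, 1.8)
        scale = rng.uniform(100.0, 2000.0)
        return FittedSurvivalModel("weibull", [shape, scale])

    keys = (
        "ttnt_from_pf",
        "death_from_pf",
        "bm_from_pf",
        "death_from_pp",
        "bm_from_pp",
        "ttnt_in_bmit",
        "death_in_bmit",
        "death_in_bmst",
    )
    return {k: rand_model() for k in keys}


def simulate_censored(rng, sampler, n, admin_censor):
    """Draw n event times from ``sampler`` and apply administrative censoring."""
    t = sampler(rng, n)
    time = np.minimum(t, admin_censor)
    event = t <= admin_censor
    return EndpointDataset("sim", np.maximum(time, 1e-6), event)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
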