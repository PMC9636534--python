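import pytest

from flashmobile import SimConfig, simulate_household


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A short, busy scenario for fast tests."""
    base = dict(
        seed=seed,
        span_hours=2.0,
        p_comply=0.8,
        p_misid=0.05,
        response_latency_mean_s=4.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def sim_pair():
    return simulate_household(small_config(seed=11))


@pytest.fixture
def perfect_config():
    return small_config(
        seed=5, p_comply=1.0, p_misid=0.0, p_coview=0.0, p_multitask=0.0, p_audio=0.0
    )
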