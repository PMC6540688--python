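import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def seed1_dataset():
    """The canonical planted-block dataset: 100 kb, 3 samples, 3 divergent
    blocks at density 0.015, background 0.002, one 2x duplicated block."""
    from hqhvscan import SimConfig, simulate_dataset

    config = SimConfig(
        seed=1,
        ref_len=100_000,
        n_samples=3,
        background_density=0.002,
        planted_blocks=[(20_000, 500, 0.015), (50_000, 500, 0.015), (80_000, 500, 0.015)],
        duplicated_blocks=[(60_000, 500, 2)],
    )
    return simulate_dataset(config)


@pytest.fixture
def scan_samples(seed1_dataset):
    from hqhvscan import SampleData

    return [SampleData(s.name, s.calls, s.depth) for s in seed1_dataset.samples]
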