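import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sevaforge.fixtures import FixtureConfig, make_entry_set, make_toy_genome

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> FixtureConfig:
    return FixtureConfig(seed=1, genome_length=3000, loci=(("amyE", 300),),
                         arm_length=400)


@pytest.fixture(scope="session")
def toy_genome(small_cfg):
    return make_toy_genome(small_cfg)


@pytest.fixture(scope="session")
def entry_set(small_cfg):
    return make_entry_set(small_cfg)
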