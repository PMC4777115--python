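import random

import pytest

from triovar.simulate import (
    SimulationConfig,
    simulate_reference,
    simulate_trio_vcf,
    write_fixture_dir,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_decoy_variants=400)


@pytest.fixture(scope="session")
def small_reference(small_config):
    rng = random.Random(small_config.seed)
    return simulate_reference(small_config, rng)


@pytest.fixture(scope="session")
def small_sim(small_config):
    # same RNG stream as write_fixture_dir, so records match fixture_dir
    rng = random.Random(small_config.seed)
    reference, transcripts = simulate_reference(small_config, rng)
    return simulate_trio_vcf(small_config, reference, transcripts, rng)


@pytest.fixture(scope="session")
def fixture_dir(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    paths = write_fixture_dir(small_config, outdir)
    return paths
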