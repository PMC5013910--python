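import hypothesis
import numpy as np
import pytest

from pmdabench.architectures import FilterConfig, build_protein_records
from pmdabench.synthetic import SynthConfig, generate_benchmark_fixture

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """One seeded synthetic benchmark bundle shared across the suite."""
    return generate_benchmark_fixture(SynthConfig(rng_seed=11))


@pytest.fixture(scope="session")
def default_records(default_bundle):
    b = default_bundle
    return build_protein_records(
        b.sequences,
        b.genome_map,
        b.domain_hits(),
        b.families.clan_maps,
        b.families.meta,
        FilterConfig(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
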