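import numpy as np
import pytest

from inips import SampleSpec, build_genome, default_length_model, simulate_sample


@pytest.fixture(scope="session")
def genome():
    """Default miniature genome (hg19/500, 20-kb bins, ~320 bins)."""
    return build_genome(seed=0)


@pytest.fixture(scope="session")
def length_model():
    return default_length_model()


@pytest.fixture(scope="session")
def male_sample(genome):
    """Count-mode male euploid sample, FF = 10%, 5e6 fragments."""
    spec = SampleSpec(fetal_fraction=0.10, fetal_sex="male", n_fragments=5_000_000, seed=42)
    return simulate_sample(genome, spec, mode="count")


@pytest.fixture(scope="session")
def fragment_sample(genome):
    """Fragment-mode male euploid sample, FF = 15%, 3e5 fragments."""
    spec = SampleSpec(
        fetal_fraction=0.15, fetal_sex="male", n_fragments=300_000, seed=7,
        sample_id="frag",
    )
    return simulate_sample(genome, spec, mode="fragment")
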