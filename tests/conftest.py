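import numpy as np
import pytest

from crisprtx.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def small_config():
    """A fast, error-free study: 2 subjects, 3 small loci each."""
    return SimulationConfig(
        n_subjects=2,
        loci_per_subject=3,
        spacers_per_locus=(2, 6),
        substitution_rate=0.0,
        indel_rate=0.0,
        coverage=30,
        seed=101,
    )


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
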