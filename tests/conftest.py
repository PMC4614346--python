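import numpy as np
import pytest

from srnakit.simulate import SimConfig, simulate_libraries, simulate_reference

DEPTHS_SMALL = {"control-1": 1500, "control-2": 1500,
                "treated-1": 1500, "treated-2": 1500}


def small_config(seed=11, **overrides):
    fields = dict(seed=seed, n_known_mirnas=10, n_novel_loci=2,
                  n_transcripts=8, library_depths=dict(DEPTHS_SMALL))
    fields.update(overrides)
    return SimConfig(**fields)


@pytest.fixture(scope="session")
def small_corpus():
    """One small synthetic corpus shared by read-level tests."""
    config = small_config()
    reference = simulate_reference(config)
    reads, summaries, true_counts = simulate_libraries(reference, config)
    return config, reference, reads, summaries, true_counts


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
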