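import pytest

import cdr3pipe as c


@pytest.fixture(scope="session")
def db():
    return c.default_toy_db()


@pytest.fixture(scope="session")
def motifs():
    return c.default_motif_library()


@pytest.fixture(scope="session")
def primers():
    return c.default_primer_set()


@pytest.fixture(scope="session")
def clean_igm_sample():
    """A zero-error IgM sample with mixed length classes."""
    config = c.SimConfig(
        n_reads=300, isotype="IgM", seed=101, class_probs=(0.2, 0.7, 0.1)
    )
    reads, truths = c.simulate_sample(config)
    return config, reads, truths


@pytest.fixture(scope="session")
def noisy_igm_sample():
    """An IgM sample with sequencing errors, duplicates and planted stops."""
    config = c.SimConfig(
        n_reads=300,
        isotype="IgM",
        seed=202,
        class_probs=(0.2, 0.7, 0.1),
        sub_rate=0.02,
        ins_rate=0.01,
        del_rate=0.01,
        dup_rate=0.15,
        stop_rate=0.1,
    )
    reads, truths = c.simulate_sample(config)
    return config, reads, truths
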