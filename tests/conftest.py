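import numpy as np
import pytest

from waxbill import synthgen


SMALL_PLAN = (
    ("1", 150_000, 4, 1.0, 0.002),
    ("4A", 150_000, 3, 0.6, 0.01),
    ("Z", 150_000, 3, 1.5, 0.0006),
)


@pytest.fixture(scope="session")
def small_config():
    return synthgen.SimConfig(seed=42, chromosome_plan=SMALL_PLAN,
                              codons_per_gene=150)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One small simulated study shared across tests: reference annotation,
    evolved orthologs, diploid focal individual, fragments and reads."""
    reference = synthgen.build_reference(small_config)
    truth = synthgen.evolve_orthologs(reference, small_config)
    diploid, fragments, reads = synthgen.make_diploid_and_reads(
        reference, truth, small_config)
    return {"config": small_config, "reference": reference, "truth": truth,
            "diploid": diploid, "fragments": fragments, "reads": reads}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
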