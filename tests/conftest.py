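import numpy as np
import pytest

import iterref as ir


@pytest.fixture(scope="session")
def small_truth():
    """A 20 kb diverged breed with reads at 30x, shared across tests."""
    ref = ir.random_reference(20_000, seed=42)
    truth = ir.simulate_breed(
        ref, ir.BreedSimParams(genome_length=20_000, n_hvr=6, seed=42)
    )
    reads = ir.simulate_reads(truth, ir.ReadSimParams(coverage=30.0, seed=42))
    return ref, truth, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_genome(length: int, seed: int, n_fraction: float = 0.0) -> ir.Genome:
    return ir.random_reference(length, seed=seed, n_fraction=n_fraction)
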