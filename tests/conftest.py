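import numpy as np
import pytest

from nanochrom import synthgen


@pytest.fixture(scope="session")
def small_assembly():
    """A 100-nanochromosome assembly with planted contaminants and chaff."""
    spec = synthgen.GenomeSpec(n_nanochromosomes=100, n_contaminants=10,
                               n_chaff=10, seed=7)
    contigs, truth = synthgen.generate_assembly(spec)
    return spec, contigs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
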