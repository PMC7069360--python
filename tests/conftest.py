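import numpy as np
import pytest

from numtscan import (GenomeAssembly, InsertionSpec, SimConfig, plant_numts,
                      random_query)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def query():
    return random_query(1534, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def planted():
    """A small assembly with plants from every placement class plus truth."""
    rng = np.random.default_rng(11)
    query = random_query(1534, rng=rng)
    insertions = [InsertionSpec("interior", (150, 600), 0.08, 0.01) for _ in range(10)]
    insertions += [
        InsertionSpec("edge_start", (150, 400), 0.02, 0.0),
        InsertionSpec("edge_end", (150, 400), 0.02, 0.0),
        InsertionSpec("contamination", (400, 700), 0.02, 0.0),
    ]
    config = SimConfig(
        n_scaffolds=12, scaffold_length_range=(20_000, 40_000),
        gc=0.40, insertions=insertions, seed=11,
    )
    assembly, truths = plant_numts(config, query, rng)
    return assembly, truths, query, config
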