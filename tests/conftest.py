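import numpy as np
import pytest

from picmi import DetectionModel, SimulationConfig, detect_elements, generate_genome


@pytest.fixture(scope="session")
def default_model():
    return DetectionModel()


@pytest.fixture(scope="session")
def planted_genome():
    """One genome with a plus-strand element and every decoy kind."""
    cfg = SimulationConfig(
        seed=11,
        decoys=frozenset({"other_family", "scattered_cores", "cross_contig"}),
    )
    return generate_genome(cfg, 0)


@pytest.fixture(scope="session")
def planted_element(planted_genome, default_model):
    genome, truth = planted_genome
    elements, _ = detect_elements(genome, default_model, truth.fis_protein)
    assert len(elements) == 1
    return elements[0], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
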