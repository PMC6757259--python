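import pytest

from paralogcs import generate_study, score_study
from paralogcs.config import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but fully structured study: 300 genes, 90 pairs, 3 screens."""
    return SimulationConfig(
        n_genes=300, n_cell_lines=(2, 2, 1), n_gene_sets=10, min_set_pairs=5, seed=1
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_scores(small_study):
    return score_study(small_study)
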