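import pytest

from sizescale import generate_cell_population, generate_phospho_panel, make_default_config


@pytest.fixture(scope="session")
def breast_table():
    """Default breast-like synthetic population used across test modules."""
    cfg = make_default_config("breast_default", n_cells=4000, seed=11)
    return generate_cell_population(cfg)


@pytest.fixture(scope="session")
def default_panel():
    """Default phospho/total panel (8 lines x 200 peptides, 10 informative)."""
    return generate_phospho_panel(seed=5)
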