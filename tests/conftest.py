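import pytest

from tpsinv.classify import load_taxonomy
from tpsinv.motifs import default_motifs
from tpsinv.synthetic import PanelSpec, generate_protein_panel


@pytest.fixture(scope="session")
def patterns():
    return default_motifs()


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def clean_panel():
    """One protein per functional group, no mutation, seed 1."""
    return generate_protein_panel(PanelSpec(n_per_group=1, mutation_rate=0.0, seed=1))
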