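import pytest

from phare import figure_fixture, fixture_ontology, fixture_raw_relationships


@pytest.fixture()
def onto():
    """A fresh fixture ontology (mutable: normalization appends axioms)."""
    return fixture_ontology()


@pytest.fixture()
def fig_raws():
    return fixture_raw_relationships()


@pytest.fixture()
def fig(onto, fig_raws):
    return onto, fig_raws
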