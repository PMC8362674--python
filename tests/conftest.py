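import pytest

from vegclass import default_hierarchy, load_groups
from vegclass.releve_io import Releve


def make_releve(species, plot_id="p1", layer="herb", **header):
    """Build a relevé from {taxon: percent cover}."""
    return Releve(
        plot_id,
        {(taxon, layer): cover / 100.0 for taxon, cover in species.items()},
        **header,
    )


@pytest.fixture(scope="session")
def groups():
    return load_groups()


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()
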