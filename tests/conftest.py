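import pytest

from paleofv import datasets as ds


@pytest.fixture(scope="session")
def study_trees():
    """The bundled 17-taxon virus/host topology pair with associations."""
    return ds.foamy_virus_tree(), ds.host_tree(), ds.fv_host_associations()


@pytest.fixture(scope="session")
def study_ages():
    return ds.host_node_ages()
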