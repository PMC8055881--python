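import pytest

from phospho3d.pipeline import cluster_dataset
from phospho3d.synthetic import make_scatter_dataset, plant_hotspot_dataset


@pytest.fixture(scope="session")
def planted():
    return plant_hotspot_dataset(seed=0)


@pytest.fixture(scope="session")
def scatter():
    return make_scatter_dataset(seed=3)


@pytest.fixture(scope="session")
def planted_run(planted):
    """(pairs, clusters, qc) from the full pipeline on the planted fixture."""
    return cluster_dataset(planted.mutations, planted.sites,
                           planted.structures, planted.transcript_map)
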