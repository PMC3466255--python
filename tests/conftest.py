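import numpy as np
import pytest

from qmdmd import synthetic
from qmdmd.backend import SurrogateBackend
from qmdmd.partition import assign_domains, extract_capped_cluster


@pytest.fixture(scope="session")
def mg_site():
    """Default Mg-like toy site with its ground truth (session-shared,
    treated as read-only by tests)."""
    return synthetic.make_toy_site()


@pytest.fixture(scope="session")
def mg_backend(mg_site):
    system, _truth = mg_site
    return SurrogateBackend(system.backend_params)


@pytest.fixture(scope="session")
def mg_partition(mg_site):
    system, _truth = mg_site
    return assign_domains(system)


@pytest.fixture(scope="session")
def mg_cluster(mg_site, mg_partition):
    system, _truth = mg_site
    return extract_capped_cluster(system, mg_partition)


def heavy_rmsd(system, positions, reference):
    heavy = system.heavy_atoms()
    d = positions[heavy] - reference[heavy]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
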