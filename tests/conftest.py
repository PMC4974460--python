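import warnings

import numpy as np
import pytest

from dbpnet.fixtures import FixtureSpec, make_fixture, fixture_score_tracks
from dbpnet.layout import GenomeLayout
from dbpnet.network import network_from_tracks


@pytest.fixture(scope="session")
def tiny_layout():
    """Two short chromosomes, 1-kb bins (12 + 8 bins)."""
    return GenomeLayout(("chr1", "chr2"), (12_000, 7_500), 1000)


@pytest.fixture(scope="session")
def std_fixture():
    """The default synthetic study: planted 1D and 3D pairs, seed 0."""
    return make_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def std_tracks(std_fixture):
    tracks, calls = fixture_score_tracks(std_fixture)
    return tracks, calls


@pytest.fixture(scope="session")
def std_network(std_fixture, std_tracks):
    tracks, _ = std_tracks
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net, pairs = network_from_tracks(tracks, std_fixture.layout,
                                         std_fixture.loops)
    return net, pairs


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*graphical lasso hit.*")
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
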