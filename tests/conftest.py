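"""Shared fixtures.

Heavy synthetic objects (textured head, painted electrodes, detection run)
are session-scoped: they are deterministic for a fixed seed, so sharing them
across tests only saves time, never hides state.
"""

import numpy as np
import pytest

import headgeo as hg

HEAD_SEED = 1


@pytest.fixture(scope="session")
def head():
    return hg.make_head(seed=HEAD_SEED)


@pytest.fixture(scope="session")
def small_head():
    """Coarser head for I/O and geometry tests."""
    return hg.make_head(seed=2, n_subdiv=2)


@pytest.fixture(scope="session")
def layout(head):
    return hg.canonical_68_layout(head)


@pytest.fixture(scope="session")
def painted(head, layout):
    """(textured mesh with 68 painted electrodes, ground-truth centers)."""
    return hg.paint_electrodes(head, layout)


@pytest.fixture(scope="session")
def detection(painted):
    """Run the full electrode-detection pipeline once for the session."""
    mesh, gt = painted
    detected = hg.detect_electrodes(mesh)
    return detected, gt


@pytest.fixture(scope="session")
def sphere_layout():
    return hg.canonical_68_layout()


@pytest.fixture(scope="session")
def templates():
    return hg.default_templates()


@pytest.fixture(scope="session")
def sphere_with_disc():
    """Head with a single painted disc at the top pole."""
    h = hg.make_head(seed=3, n_subdiv=2)
    eset = hg.ElectrodeSet(np.array([[0.0, 0.0, 100.0]]), ["Cz"])
    return hg.paint_electrodes(h, eset, radius_mm=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
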