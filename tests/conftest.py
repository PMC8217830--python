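import numpy as np
import pytest

import oxywindow as ow


@pytest.fixture(scope="session")
def tissue():
    return ow.TissueParams()


@pytest.fixture(scope="session")
def membrane():
    return ow.MembraneParams()


@pytest.fixture(scope="session")
def small_spec():
    """Small 3D domain with a membrane, cheap enough for every solver test."""
    return ow.DomainSpec(Lx=200.0, Ly=200.0, Lz_tissue=120.0, h_pdms=20.0, dx=10.0)


@pytest.fixture(scope="session")
def small_grid(small_spec):
    return ow.build_grid(small_spec, ow.single_window_layout(small_spec, 80.0, 40.0))


@pytest.fixture(scope="session")
def windowless_grid(small_spec):
    return ow.build_grid(small_spec, ow.WindowLayout(()))
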