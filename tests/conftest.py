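import numpy as np
import pytest

from spheroquant import Micrograph, SpheroidScene, render_scene


@pytest.fixture
def constant_image():
    return Micrograph(np.full((64, 64), 100.0))


@pytest.fixture
def compact_scene():
    """Compact spheroid with a sharp edge: the proliferative reference."""
    return SpheroidScene(seed=2, halo_width=2.0, n_peripheral_cells=10)


@pytest.fixture
def diffuse_scene():
    """Spread-out core: wide intensity ramp around a smaller dense center."""
    return SpheroidScene(seed=2, core_radius=40.0, halo_width=40.0)


@pytest.fixture
def compact_render(compact_scene):
    return render_scene(compact_scene)


@pytest.fixture
def diffuse_render(diffuse_scene):
    return render_scene(diffuse_scene)
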