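"""Shared phantom scenes (session-scoped: rendering is the slow part)."""

import numpy as np
import pytest

from memthick.graph import build_mesh_graph
from memthick.phantom import (PhantomSpec, add_noise, apply_missing_wedge,
                              make_bilayer_phantom)


@pytest.fixture(scope="session")
def plane_scene():
    """Clean 60x60 nm plane bilayer, t=3.6, sigma=0.5, voxel 0.8."""
    spec = PhantomSpec(geometry="plane", extent=60.0, t_true=3.6,
                       sigma_hg=0.5, voxel_size=0.8, seed=0)
    vol, mesh, truth = make_bilayer_phantom(spec)
    return spec, vol, mesh, truth


@pytest.fixture(scope="session")
def plane_graph(plane_scene):
    _, _, mesh, _ = plane_scene
    return build_mesh_graph(mesh)


@pytest.fixture(scope="session")
def noisy_wedge_volume(plane_scene):
    """The same plane with a +-60 degree wedge and noise sd 0.5x amplitude."""
    spec, vol, _, _ = plane_scene
    return add_noise(apply_missing_wedge(vol, 60.0), 0.5 * spec.amplitude,
                     seed=11)


@pytest.fixture(scope="session")
def sphere20():
    """Closed sphere mesh + graph, R=20 nm (curvedness 0.05 /nm)."""
    spec = PhantomSpec(geometry="sphere", radius=20.0, mesh_edge=2.0)
    _, mesh, truth = make_bilayer_phantom(spec)
    return mesh, build_mesh_graph(mesh), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
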