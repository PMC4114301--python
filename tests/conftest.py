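"""Shared fixtures.

Geometry and simulation fixtures are session-scoped: meshes and hybrid
runs are deterministic, so tests share them instead of rebuilding.
"""

import numpy as np
import pytest

from hybridcell import meshgen, morphology
from hybridcell.hybrid import HybridConfig, MorphologySource


@pytest.fixture(scope="session")
def cylinder_graph():
    return morphology.generate_synthetic("cylinder", length=10.0, radius=1.0)


@pytest.fixture(scope="session")
def y_branch_graph():
    return morphology.generate_synthetic("y_branch")


@pytest.fixture(scope="session")
def soma_tree_graph():
    return morphology.generate_synthetic("soma_tree", seed=7)


@pytest.fixture(scope="session")
def cylinder_mesh(cylinder_graph):
    """Mid-resolution conforming (surface, volume) pair for the cylinder."""
    return meshgen.build_mesh_pair(cylinder_graph, h=0.25)


@pytest.fixture(scope="session")
def coarse_hybrid_config():
    """Short, coarse hybrid setup shared by the coupling tests."""
    return HybridConfig(
        morphology=MorphologySource("cylinder",
                                    dims=dict(length=10.0, radius=1.0)),
        mesh_h=0.3, t_total=20.0)


@pytest.fixture(scope="session")
def coarse_hybrid_run(coarse_hybrid_config):
    from hybridcell import hybrid
    return hybrid.run(coarse_hybrid_config)


@pytest.fixture(scope="session")
def reference_sweep_config():
    """The scaled-down reference protocol: ~10^4-vertex cylinder dendrite,
    100 ms at dt = 0.1 ms."""
    return HybridConfig(
        morphology=MorphologySource("cylinder",
                                    dims=dict(length=10.0, radius=1.0)),
        mesh_h=0.16, t_total=100.0)


@pytest.fixture(scope="session")
def diffusion_sweep(reference_sweep_config):
    from hybridcell import hybrid
    return hybrid.sweep_diffusion(reference_sweep_config,
                                  [20.0, 40.0, 60.0, 80.0, 100.0])


@pytest.fixture(scope="session")
def density_sweep(reference_sweep_config):
    from hybridcell import hybrid
    return hybrid.sweep_density(reference_sweep_config,
                                [200.0, 400.0, 600.0, 800.0, 1000.0])
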