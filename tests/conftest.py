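"""Shared fixtures.

Expensive artifacts (a full pipeline run, the seeded cohort) are session
scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest
import trimesh

from canalplan.anatomy import AnatomyParams, generate_case
from canalplan.geometry import tube_along_curve
from canalplan.pipeline import PipelineConfig, run_case


@pytest.fixture(scope="session")
def default_params():
    return AnatomyParams()

@pytest.fixture(scope="session")
def default_case(default_params):
    return generate_case(default_params)


@pytest.fixture(scope="session")
def coarse_config():
    return PipelineConfig.coarse(seed=1)


@pytest.fixture(scope="session")
def case_artifacts(default_case, coarse_config):
    """One full pipeline run on the default synthetic case."""
    report, artifacts = run_case(default_case, coarse_config)
    return report, artifacts


@pytest.fixture(scope="session")
def torus_tube():
    """Torus-arc phantom matching a semicircular canal: major radius
    3.2 mm, lumen radius 0.55 mm, 270 degree span."""
    t = np.linspace(0.0, 1.5 * np.pi, 120)
    curve = np.column_stack([3.2 * np.cos(t), 3.2 * np.sin(t), np.zeros_like(t)])
    return tube_along_curve(curve, 0.55, n_circ=24)


@pytest.fixture(scope="session")
def random_bumpy_meshes():
    """Three seeded random star-shaped meshes (deformed icospheres)."""
    meshes = []
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        m = trimesh.creation.icosphere(subdivisions=3)
        v = m.vertices.view(np.ndarray).copy()
        radial = 1.0 + 0.2 * rng.standard_normal(len(v))
        v *= radial[:, None]
        meshes.append(trimesh.Trimesh(vertices=v, faces=m.faces, process=False))
    return meshes


def brute_force_distance(points, mesh):
    """Independent closest-point oracle: exhaustive distance to every
    triangle through trimesh's reference implementation."""
    tris = mesh.triangles.view(np.ndarray)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        cp = trimesh.triangles.closest_point(tris, np.repeat(p[None], len(tris), 0))
        out[i] = np.linalg.norm(cp - p, axis=1).min()
    return out
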