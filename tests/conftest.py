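"""Shared fixtures and independent oracles.

All geometry fixtures are generated programmatically; the brute-force
Hausdorff oracle computes all-pairs point-to-triangle distances with no
spatial acceleration, so it is independent of the package's KD-tree
candidate search.
"""

import numpy as np
import pytest
import trimesh
import trimesh.triangles


@pytest.fixture(scope="session")
def sphere10():
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)

@pytest.fixture(scope="session")
def sphere12():
    return trimesh.creation.icosphere(subdivisions=4, radius=12.0)


@pytest.fixture(scope="session")
def cylinder():
    """Axis-aligned cylinder r=10 mm, h=300 mm, base at z=0."""
    cyl = trimesh.creation.cylinder(radius=10.0, height=300.0, sections=64)
    cyl.apply_translation([0, 0, 150.0])
    return cyl


@pytest.fixture(scope="session")
def spindle_q1():
    """Unit-exponent spindle with its landmarks (closed-form volume)."""
    from musclemorph.synthgen import SpindleParams, make_spindle
    return make_spindle(SpindleParams(mesh_resolution=(120, 48)))


def brute_force_directed(points: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    """Min distance from each point to any triangle, all pairs (oracle)."""
    tris = mesh.triangles
    out = np.empty(len(points))
    for i, p in enumerate(points):
        closest = trimesh.triangles.closest_point(
            tris, np.repeat(p[None, :], len(tris), axis=0))
        out[i] = np.linalg.norm(closest - p, axis=1).min()
    return out


def brute_force_hausdorff(a: trimesh.Trimesh, b: trimesh.Trimesh,
                          extra_samples: int = 2000) -> float:
    """Symmetric Hausdorff from vertices + seeded samples, all-pairs."""
    pa = np.vstack([a.vertices,
                    trimesh.sample.sample_surface(a, extra_samples, seed=11)[0]])
    pb = np.vstack([b.vertices,
                    trimesh.sample.sample_surface(b, extra_samples, seed=12)[0]])
    return max(brute_force_directed(pa, b).max(),
               brute_force_directed(pb, a).max())
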