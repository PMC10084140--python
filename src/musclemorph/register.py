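"""Bilateral pair preparation: mirror, length-scale, landmark rigid fit.

One limb's surface is reflected across a sagittal-proxy plane, uniformly
scaled so its centerline length matches the contralateral side (isolating
shape from gross size), and rigidly aligned by least squares on the six
labelled MTJ landmarks (Kabsch/Umeyama without scaling or reflection).
``part_comparison`` then yields the per-vertex signed distances used for
the deviation heatmap.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .core import (
    DegenerateLandmarkError,
    LandmarkSet,
    ParameterError,
    RigidTransform,
)
from ._geometry import SurfaceDistance

__all__ = [
    "mirror_and_scale",
    "fit_rigid",
    "apply_rigid",
    "part_comparison",
    "export_heatmap_ply",
]

_AXES = {"x": 0, "y": 1, "z": 2}


def mirror_and_scale(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                     fixed_length_mm: float, mirror_plane: str = "x",
                     moving_length_mm: float | None = None,
                     scale_mode: str = "isotropic"):
    """Reflect across the named world plane, then scale to the fixed length.

    The mirror plane passes through the mesh centroid perpendicular to the
    named axis (x by default — the sagittal proxy); reflection flips face
    winding, which is restored so orientation stays outward. Scaling is
    uniform isotropic about the centroid by ``fixed_length / moving length``;
    ``scale_mode="axis"`` instead stretches only the long axis, kept as a
    sensitivity-check mode. Returns (mesh, landmarks, factor).
    """
    if not (fixed_length_mm > 0 and np.isfinite(fixed_length_mm)):
        raise ParameterError("fixed_length_mm must be positive")
    if mirror_plane not in _AXES:
        raise ParameterError(f"mirror_plane must be one of {sorted(_AXES)}")
    if scale_mode not in ("isotropic", "axis"):
        raise ParameterError("scale_mode must be 'isotropic' or 'axis'")

    axis = _AXES[mirror_plane]
    centroid = mesh.vertices.mean(axis=0)

    verts = np.array(mesh.vertices, float)
    verts[:, axis] = 2.0 * centroid[axis] - verts[:, axis]
    faces = np.array(mesh.faces)[:, ::-1]  # restore outward winding
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    lm_pts = np.array(landmarks.points, float)
    lm_pts[:, axis] = 2.0 * centroid[axis] - lm_pts[:, axis]

    if moving_length_mm is None:
        from .morphometry import fit_centerline  # avoid import cycle
        moving_length_mm = fit_centerline(out).total_length_mm
    if not (moving_length_mm > 0):
        raise ParameterError("moving centerline length must be positive")

    factor = float(fixed_length_mm / moving_length_mm)
    scale = np.ones(3)
    if scale_mode == "isotropic":
        scale[:] = factor
    else:  # stretch the long (principal) axis only
        long_axis = int(np.argmax(out.vertices.max(0) - out.vertices.min(0)))
        scale[long_axis] = factor
    c = out.vertices.mean(axis=0)
    out = trimesh.Trimesh(vertices=c + (out.vertices - c) * scale,
                          faces=out.faces, process=False)
    lm_pts = c + (lm_pts - c) * scale
    return out, LandmarkSet(lm_pts), factor


def fit_rigid(moving: LandmarkSet, fixed: LandmarkSet) -> RigidTransform:
    """Least-squares rigid transform T minimizing sum ||T(m_i) - f_i||^2.

    Correspondence is by landmark label. The solution is the classical
    SVD/Kabsch construction with the determinant correction, so no
    reflection can be returned; scaling is never estimated.
    """
    m = moving.points
    f = fixed.points
    cm, cf = m.mean(axis=0), f.mean(axis=0)
    m0, f0 = m - cm, f - cf

    # degenerate if the combined configuration is (near-)collinear
    s_m = np.linalg.svd(m0, compute_uv=False)
    s_f = np.linalg.svd(f0, compute_uv=False)
    for s in (s_m, s_f):
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise DegenerateLandmarkError("landmark configuration is collinear")

    H = m0.T @ f0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cf - R @ cm
    resid = (m @ R.T + t) - f
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return RigidTransform(R, t, residual_rms_mm=rms)


def apply_rigid(mesh: trimesh.Trimesh, transform: RigidTransform) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=transform.apply(mesh.vertices),
                           faces=np.array(mesh.faces), process=False)


def part_comparison(test: trimesh.Trimesh, reference: trimesh.Trimesh,
                    distance: SurfaceDistance | None = None) -> np.ndarray:
    """Per-vertex signed distance of ``test`` to the reference surface (mm).

    Positive outside the reference, negative inside — the convention of the
    usual asymmetric deviation colormap (about -10 mm blue to +25 mm red).
    """
    if len(test.vertices) == 0 or len(reference.faces) == 0:
        raise ParameterError("part comparison needs non-empty meshes")
    if distance is None:
        distance = SurfaceDistance(reference)
    return distance.signed_distance(np.asarray(test.vertices, float))


def export_heatmap_ply(mesh: trimesh.Trimesh, scalars: np.ndarray, path) -> None:
    """ASCII PLY with a per-vertex ``quality`` scalar for heatmap rendering."""
    scalars = np.asarray(scalars, float).reshape(-1)
    if len(scalars) != len(mesh.vertices):
        raise ParameterError("one scalar per vertex required")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, q in zip(mesh.vertices, scalars):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {q:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
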