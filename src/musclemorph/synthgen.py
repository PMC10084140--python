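"""Parametric bilateral muscle phantoms with known ground truth.

The phantom family is a surface of revolution with radial profile
``r(z) = r_max * sin(pi z / L) ** q`` and elliptical cross-sections: it is
fusiform, tapers to MTJ-like tips, and for ``q = 1`` has the closed-form
volume ``pi * r_max**2 * L / 2`` used as an analytic oracle. Deformations
encode the maladaptations seen after tendon harvest — distal retraction,
regional atrophy (radial scaling), and a laterally deviated distal tip whose
magnitude is a known Hausdorff-distance target — so every downstream stage
can be tested against ground truth without imaging data.

Conventions: the phantom axis is z, the distal end at minimal z; arc-length
fraction s runs 0 (distal tip) to 1 (proximal tip).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .core import (
    DegenerateGeometryError,
    LandmarkSet,
    ParameterError,
    SubjectCase,
    SubjectMeta,
)
from ._geometry import require_watertight

__all__ = [
    "SpindleParams",
    "DeformationParams",
    "DeformationSampler",
    "CohortParams",
    "make_spindle",
    "apply_deformation",
    "simulate_cohort",
]


# --------------------------------------------------------------------------- #
# parameter types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SpindleParams:
    """Geometry of one fusiform phantom.

    length_mm, r_max_mm
        axial length and peak radius of the profile.
    taper_exponent
        exponent q of the sin^q radial profile; smaller q gives a fuller
        belly (volume / (peak CSA x length) rises toward 2/pi as q -> 0).
    ellipse_ratio
        minor/major axis ratio of the elliptical cross-section, in (0, 1].
    axial_curvature_per_mm
        gentle bow of the axis (lateral deflection kappa * z^2 / 2).
    mesh_resolution
        (axial stations, circumferential vertices).
    """

    length_mm: float = 300.0
    r_max_mm: float = 20.0
    taper_exponent: float = 1.0
    ellipse_ratio: float = 1.0
    axial_curvature_per_mm: float = 0.0
    mesh_resolution: tuple = (200, 64)

    def __post_init__(self):
        vals = [self.length_mm, self.r_max_mm, self.taper_exponent,
                self.ellipse_ratio, self.axial_curvature_per_mm]
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError("spindle parameters must be finite")
        if self.length_mm <= 0 or self.r_max_mm <= 0 or self.taper_exponent <= 0:
            raise ParameterError("length, peak radius and taper exponent must be > 0")
        if not (0 < self.ellipse_ratio <= 1):
            raise ParameterError("ellipse_ratio must lie in (0, 1]")
        if self.axial_curvature_per_mm < 0:
            raise ParameterError("axial_curvature_per_mm must be >= 0")
        n_ax, n_circ = self.mesh_resolution
        if n_ax < 20 or n_circ < 12:
            raise ParameterError("mesh_resolution must be at least (20, 12)")


@dataclass(frozen=True)
class DeformationParams:
    """Post-surgical deformation applied to one limb's phantom.

    retraction_fraction
        fraction of arc length removed from the distal end (tip re-closed).
    regional_radial_scale
        (proximal, middle, distal) radius multipliers, blended smoothly
        (C1) across the 33%/66% arc-length boundaries.
    distal_offset_mm
        lateral translation of the distal tip, decaying smoothly to zero at
        33% arc length; ground-truth Hausdorff distance ~= this magnitude.
    surface_noise_sd_mm
        Gaussian vertex perturbation along normals.
    """

    retraction_fraction: float = 0.0
    regional_radial_scale: tuple = (1.0, 1.0, 1.0)
    distal_offset_mm: float = 0.0
    surface_noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.retraction_fraction < 1):
            raise ParameterError("retraction_fraction must lie in [0, 1)")
        if len(self.regional_radial_scale) != 3 or min(self.regional_radial_scale) <= 0:
            raise ParameterError("regional_radial_scale needs 3 positive values")
        if self.distal_offset_mm < 0 or self.surface_noise_sd_mm < 0:
            raise ParameterError("offset and noise must be non-negative")


@dataclass(frozen=True)
class DeformationSampler:
    """Distribution over DeformationParams for one cohort arm.

    When the tendon-regeneration flag is true the sampled severities
    (retraction, distal offset, and 1 - radial scale) are multiplied by
    ``regenerated_severity`` < 1: regeneration preserves muscle shape.
    """

    retraction_mean: float = 0.0
    retraction_sd: float = 0.0
    radial_scale_mean: tuple = (1.0, 1.0, 1.0)
    radial_scale_sd: float = 0.0
    distal_offset_mean_mm: float = 0.0
    distal_offset_sd_mm: float = 0.0
    surface_noise_sd_mm: float = 0.3
    regenerated_severity: float = 0.45

    def sample(self, rng: np.random.Generator, regenerated: bool) -> DeformationParams:
        sev = self.regenerated_severity if regenerated else 1.0
        retr = sev * np.clip(
            rng.normal(self.retraction_mean, self.retraction_sd), 0.0, 0.8)
        scales = np.clip(
            rng.normal(self.radial_scale_mean, self.radial_scale_sd), 0.3, 1.5)
        scales = 1.0 - sev * (1.0 - scales)
        offset = sev * max(0.0, rng.normal(self.distal_offset_mean_mm,
                                           self.distal_offset_sd_mm))
        return DeformationParams(
            retraction_fraction=float(retr),
            regional_radial_scale=tuple(float(v) for v in scales),
            distal_offset_mm=float(offset),
            surface_noise_sd_mm=self.surface_noise_sd_mm,
            seed=int(rng.integers(2 ** 31)),
        )


#: deformation of the surgical limb, calibrated so cohort means land near the
#: reported group outcomes (injured volume about half of contralateral,
#: length ratio about 0.68, distal deviation of a few cm).
ACLR_DEFORMATION = DeformationSampler(
    retraction_mean=0.32, retraction_sd=0.04,
    radial_scale_mean=(0.78, 0.72, 0.88), radial_scale_sd=0.05,
    distal_offset_mean_mm=14.0, distal_offset_sd_mm=4.0,
    surface_noise_sd_mm=0.3,
)

#: healthy limbs differ only by surface noise.
CONTROL_DEFORMATION = DeformationSampler(surface_noise_sd_mm=0.3)


@dataclass(frozen=True)
class CohortParams:
    """Two-arm study generator (healthy controls vs reconstructed)."""

    n_per_group: int = 18
    mass_kg_mean_sd: dict = field(default_factory=lambda: {
        "control": (69.0, 15.4), "aclr": (82.0, 15.6)})
    limb_length_m_mean_sd: dict = field(default_factory=lambda: {
        "control": (0.81, 0.05), "aclr": (0.83, 0.07)})
    control_deformation: DeformationSampler = CONTROL_DEFORMATION
    aclr_deformation: DeformationSampler = ACLR_DEFORMATION
    regeneration_probability: float = 0.39
    length_mm_mean_sd: tuple = (300.0, 25.0)
    r_max_mm_mean_sd: tuple = (20.0, 1.5)
    ellipse_ratio: float = 0.8
    taper_exponent: float = 0.6
    mesh_resolution: tuple = (120, 36)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if not (0 <= self.regeneration_probability <= 1):
            raise ParameterError("regeneration_probability must lie in [0, 1]")


# --------------------------------------------------------------------------- #
# spindle construction
# --------------------------------------------------------------------------- #

def _stations(n_axial: int) -> np.ndarray:
    """Interior axial stations in (0, 1), always containing the landmark
    stations 0.02 and 0.98 exactly."""
    t = np.linspace(0.0, 1.0, int(n_axial))[1:-1]
    t = np.union1d(t, [0.02, 0.98])
    return t


def make_spindle(params: SpindleParams):
    """Build the watertight phantom mesh and its six MTJ landmarks.

    Landmarks are three circumference points at 2% arc length (distal MTJ
    proxy) and three at 98% (proximal); they coincide with mesh vertices so
    they lie exactly on the surface.
    """
    L, rmax, q = params.length_mm, params.r_max_mm, params.taper_exponent
    n_ax, n_circ = params.mesh_resolution
    t = _stations(n_ax)
    theta = 2 * np.pi * np.arange(n_circ) / n_circ

    r = rmax * np.sin(np.pi * t) ** q
    z = t * L
    bow = 0.5 * params.axial_curvature_per_mm * z ** 2

    # vertex grid: rings (t-major) then the two apexes
    x = r[:, None] * np.cos(theta)[None, :] + bow[:, None]
    y = params.ellipse_ratio * r[:, None] * np.sin(theta)[None, :]
    zz = np.broadcast_to(z[:, None], x.shape)
    verts = np.column_stack([x.ravel(), y.ravel(), zz.ravel()])
    apex_distal = np.array([0.0, 0.0, 0.0])
    apex_proximal = np.array([0.5 * params.axial_curvature_per_mm * L ** 2, 0.0, L])
    verts = np.vstack([verts, apex_distal, apex_proximal])
    i_ap_d, i_ap_p = len(verts) - 2, len(verts) - 1

    n_rings = len(t)

    def ring(i):
        return np.arange(n_circ) + i * n_circ

    faces = []
    # distal fan (outward: normals point toward -z)
    r0 = ring(0)
    faces.extend([[i_ap_d, r0[(j + 1) % n_circ], r0[j]] for j in range(n_circ)])
    # side strips
    for i in range(n_rings - 1):
        a, b = ring(i), ring(i + 1)
        for j in range(n_circ):
            j2 = (j + 1) % n_circ
            faces.append([a[j], a[j2], b[j]])
            faces.append([a[j2], b[j2], b[j]])
    # proximal fan
    rn = ring(n_rings - 1)
    faces.extend([[i_ap_p, rn[j], rn[(j + 1) % n_circ]] for j in range(n_circ)])

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    mesh = require_watertight(mesh, "spindle phantom")

    j3 = [0, n_circ // 3, (2 * n_circ) // 3]
    i_d = int(np.searchsorted(t, 0.02))
    i_p = int(np.searchsorted(t, 0.98))
    prox = verts[[ring(i_p)[j] for j in j3]]
    dist = verts[[ring(i_d)[j] for j in j3]]
    lms = LandmarkSet(np.vstack([prox, dist]))
    return mesh, lms


# --------------------------------------------------------------------------- #
# deformation
# --------------------------------------------------------------------------- #

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _radial_scale_profile(s: np.ndarray, scales, width: float = 0.08) -> np.ndarray:
    """C1 blend of the (proximal, middle, distal) multipliers along s."""
    prox, mid, dist = scales
    out = np.full_like(s, float(dist))
    out += (mid - dist) * _smoothstep((s - (1 / 3 - width)) / (2 * width))
    out += (prox - mid) * _smoothstep((s - (2 / 3 - width)) / (2 * width))
    return out


def _deform_points(points, s, axis_xy, deform, s_cut):
    """Deterministic coordinate map shared by vertices and landmarks."""
    pts = np.array(points, float)
    rel = pts[:, :2] - axis_xy
    # regional radial scaling in the post-retraction arc coordinate
    s_new = np.clip((s - s_cut) / (1.0 - s_cut), 0.0, 1.0)
    sigma = _radial_scale_profile(s_new, deform.regional_radial_scale)
    pts[:, :2] = axis_xy + rel * sigma[:, None]
    # smooth lateral deviation of the distal tip (x direction)
    falloff = _smoothstep(1.0 - s_new / 0.33)
    pts[:, 0] += deform.distal_offset_mm * falloff
    return pts


def apply_deformation(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                      deform: DeformationParams):
    """Apply retraction, regional atrophy, tip deviation and noise.

    The map assumes the phantom convention (axis ~ z, distal end at minimal
    z). Retraction collapses everything distal to the cut station onto the
    rebuilt tip and shifts the kept part distally, so centerline length
    scales by exactly (1 - retraction_fraction) up to station spacing.
    Landmarks ride through the same deterministic map (noise excluded:
    MTJ picks are user selections, not surface jitter).
    """
    verts = np.array(mesh.vertices, float)
    z = verts[:, 2]
    z0, z1 = float(z.min()), float(z.max())
    if z1 - z0 <= 0:
        raise DegenerateGeometryError("mesh has no axial extent")
    s = (z - z0) / (z1 - z0)
    axis_xy = verts[:, :2].mean(axis=0)

    # retraction: snap the cut to the nearest existing station below it
    f = deform.retraction_fraction
    s_cut = 0.0
    if f > 0:
        below = np.unique(s[s <= f])
        s_cut = float(below.max()) if len(below) else 0.0

    new = _deform_points(verts, s, axis_xy, deform, s_cut)
    lm_z = landmarks.points[:, 2]
    lm_s = np.clip((lm_z - z0) / (z1 - z0), 0.0, 1.0)
    lm_new = _deform_points(landmarks.points, lm_s, axis_xy, deform, s_cut)

    # axial shift + tip collapse
    cut_z = z0 + s_cut * (z1 - z0)
    collapsed = s <= s_cut + 1e-12
    new[:, 2] = np.where(collapsed, z0, new[:, 2] - (cut_z - z0))
    if f > 0:
        tip = np.array([axis_xy[0] + deform.distal_offset_mm, axis_xy[1], z0])
        new[collapsed] = tip
    lm_collapsed = lm_s <= s_cut + 1e-12
    lm_new[:, 2] = np.where(lm_collapsed, z0, lm_new[:, 2] - (cut_z - z0))
    if f > 0:
        lm_new[lm_collapsed] = tip

    out = trimesh.Trimesh(vertices=new, faces=np.array(mesh.faces), process=True)
    out.update_faces(out.nondegenerate_faces())
    out.remove_unreferenced_vertices()

    if deform.surface_noise_sd_mm > 0:
        rng = np.random.default_rng(deform.seed)
        bump = rng.normal(0.0, deform.surface_noise_sd_mm, len(out.vertices))
        out = trimesh.Trimesh(
            vertices=out.vertices + bump[:, None] * out.vertex_normals,
            faces=out.faces, process=False)

    out = require_watertight(out, "deformed phantom")
    return out, LandmarkSet(lm_new)


# --------------------------------------------------------------------------- #
# cohort simulation
# --------------------------------------------------------------------------- #

def _noise_only(sampler: DeformationSampler, rng) -> DeformationParams:
    return DeformationParams(surface_noise_sd_mm=sampler.surface_noise_sd_mm,
                             seed=int(rng.integers(2 ** 31)))


def simulate_cohort(cohort: CohortParams,
                    metadata_only: bool = False) -> list[SubjectCase]:
    """Generate the two-arm study: n healthy controls and n reconstructed.

    Controls get two near-identical limbs (surface noise only); subjects in
    the surgical arm get one intact and one deformed limb, deformation
    severity reduced when the tendon-regeneration flag (Bernoulli with the
    configured probability) is true. Fully reproducible from the seed.
    ``metadata_only`` skips mesh construction (cases carry empty sides),
    for calibration studies of the samplers alone.
    """
    rng = np.random.default_rng(cohort.seed)
    cases: list[SubjectCase] = []
    for group in ("control", "aclr"):
        m_mu, m_sd = cohort.mass_kg_mean_sd[group]
        l_mu, l_sd = cohort.limb_length_m_mean_sd[group]
        for i in range(cohort.n_per_group):
            sid = f"{group}_{i + 1:02d}"
            mass = float(np.clip(rng.normal(m_mu, m_sd), 40.0, 140.0))
            limb = float(np.clip(rng.normal(l_mu, l_sd), 0.6, 1.1))
            regen = bool(rng.random() < cohort.regeneration_probability) \
                if group == "aclr" else False
            meta = SubjectMeta(subject_id=sid, group=group, mass_kg=mass,
                               limb_length_m=limb, regenerated=regen)

            base = SpindleParams(
                length_mm=float(np.clip(rng.normal(*cohort.length_mm_mean_sd),
                                        220.0, 450.0)),
                r_max_mm=float(np.clip(rng.normal(*cohort.r_max_mm_mean_sd),
                                       12.0, 30.0)),
                taper_exponent=cohort.taper_exponent,
                ellipse_ratio=cohort.ellipse_ratio,
                mesh_resolution=cohort.mesh_resolution,
            )
            if metadata_only:
                names = (("right", "left") if group == "control"
                         else ("uninjured", "injured"))
                cases.append(SubjectCase(
                    subject_id=sid, sides={n: None for n in names},
                    landmarks={n: None for n in names}, meta=meta,
                    reference_side=names[0]))
                continue
            mesh0, lms0 = make_spindle(base)

            if group == "control":
                sides, marks = {}, {}
                for side in ("right", "left"):
                    d = _noise_only(cohort.control_deformation, rng)
                    sides[side], marks[side] = apply_deformation(mesh0, lms0, d)
                ref, truth = "right", {"retraction_fraction": 0.0,
                                       "distal_offset_mm": 0.0,
                                       "volume_scale": 1.0}
            else:
                d_ok = _noise_only(cohort.aclr_deformation, rng)
                d_inj = cohort.aclr_deformation.sample(rng, regen)
                sides, marks = {}, {}
                sides["uninjured"], marks["uninjured"] = apply_deformation(
                    mesh0, lms0, d_ok)
                sides["injured"], marks["injured"] = apply_deformation(
                    mesh0, lms0, d_inj)
                ref = "uninjured"
                truth = {"retraction_fraction": d_inj.retraction_fraction,
                         "distal_offset_mm": d_inj.distal_offset_mm,
                         "volume_scale": float(
                             np.mean(np.square(d_inj.regional_radial_scale))
                             * (1 - d_inj.retraction_fraction))}
            cases.append(SubjectCase(subject_id=sid, sides=sides, landmarks=marks,
                                     meta=meta, reference_side=ref, truth=truth))
    return cases


def cohort_metadata(cases) -> "pd.DataFrame":
    """Tidy metadata table (subject_id, group, mass, limb length, regenerated)."""
    import pandas as pd
    rows = [{"subject_id": c.meta.subject_id, "group": c.meta.group,
             "mass_kg": c.meta.mass_kg, "limb_length_m": c.meta.limb_length_m,
             "regenerated": c.meta.regenerated,
             "reference_side": c.reference_side} for c in cases]
    return pd.DataFrame(rows)
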