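"""End-to-end per-subject and per-cohort orchestration.

Per subject: (volumes -> surfaces if needed) -> mirror the non-reference
limb -> scale it to the reference centerline length -> rigid-align on the
six MTJ landmarks -> similarity metrics + deviation heatmap; morphometry is
always computed on the original unmirrored, unscaled limbs (real lengths
and volumes are reported; scaling exists only to isolate shape in the
similarity branch). Per cohort: run every case, quarantine failures, and
hand tidy tables to the statistics layer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import trimesh

from .core import (
    CaseResult,
    LandmarkSet,
    MuscleMorphError,
    SubjectCase,
    SubjectMeta,
)
from .meshio import LabelVolume, MeshProcessingParams, extract_surface, read_inputs
from .morphometry import fit_centerline, normalize, regional_morphology
from .register import (
    apply_rigid,
    export_heatmap_ply,
    fit_rigid,
    mirror_and_scale,
    part_comparison,
)
from .similarity import compute_similarity
from . import stats as mstats

log = logging.getLogger("musclemorph")

__all__ = ["PipelineConfig", "run_case", "run_cohort", "tidy_frames",
           "load_manifest"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the per-case workflow (defaults in mm)."""

    voxel_size_mm: float = 1.0
    samples_per_surface: int = 50_000
    slice_spacing_mm: float = 1.0     # centerline slice pitch
    station_spacing_mm: float = 1.0   # CSA scan pitch
    mirror_plane: str = "x"
    scale_mode: str = "isotropic"
    mesh_params: MeshProcessingParams = field(default_factory=MeshProcessingParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mesh_params"] = asdict(self.mesh_params)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "mesh_params" in d:
            d["mesh_params"] = MeshProcessingParams(**d["mesh_params"])
        return cls(**d)


def _case_seed(config: PipelineConfig, subject_id: str) -> int:
    return (config.seed * 1_000_003 + zlib.crc32(subject_id.encode())) % (2 ** 31)


def _as_mesh(obj, config: PipelineConfig) -> trimesh.Trimesh:
    if isinstance(obj, LabelVolume):
        return extract_surface(obj, config.mesh_params)
    return obj


def run_case(case: SubjectCase, config: PipelineConfig = PipelineConfig(),
             return_geometry: bool = False):
    """Run the full workflow on one subject.

    Returns a :class:`CaseResult`; with ``return_geometry`` also a dict
    holding the aligned pair and the per-vertex signed heatmap distances.
    Stage failures re-raise with the stage name and subject id attached.
    """
    sid = case.subject_id
    seed = _case_seed(config, sid)
    stage = "input"
    try:
        meshes = {s: _as_mesh(m, config) for s, m in case.sides.items()}

        stage = "morphometry"
        centerlines, morph = {}, {}
        for side, mesh in meshes.items():
            cl = fit_centerline(mesh, config.slice_spacing_mm)
            rec = regional_morphology(mesh, cl, config.station_spacing_mm)
            morph[side] = normalize(rec, case.meta)
            centerlines[side] = cl
            log.info("%s/%s: length %.1f cm, volume %.1f cm3",
                     sid, side, rec.length_cm, rec.volume_cm3)

        ref, mov = case.reference_side, case.moving_side
        stage = "mirror_scale"
        fixed_len = centerlines[ref].total_length_mm
        moving_len = centerlines[mov].total_length_mm
        m_mesh, m_lms, factor = mirror_and_scale(
            meshes[mov], case.landmarks[mov], fixed_len,
            mirror_plane=config.mirror_plane, moving_length_mm=moving_len,
            scale_mode=config.scale_mode)

        stage = "rigid_registration"
        T = fit_rigid(m_lms, case.landmarks[ref])
        aligned = apply_rigid(m_mesh, T)
        log.info("%s: scale %.3f, registration RMS %.2f mm",
                 sid, factor, T.residual_rms_mm)

        stage = "similarity"
        report = compute_similarity(
            aligned, meshes[ref], voxel_size_mm=config.voxel_size_mm,
            samples_per_surface=config.samples_per_surface, seed=seed)
        station = centerlines[ref].station_of_point(report.hausdorff_location)
        region = centerlines[ref].region_of_station(station)

        result = CaseResult(
            subject_id=sid, similarity=report, morphology=morph,
            scale_factor=factor, registration_rms_mm=T.residual_rms_mm,
            hausdorff_region=region, reference_side=ref, moving_side=mov)
        if not return_geometry:
            return result
        stage = "part_comparison"
        scalars = part_comparison(aligned, meshes[ref])
        return result, {"aligned_moving": aligned, "reference": meshes[ref],
                        "heatmap_mm": scalars}
    except MuscleMorphError as exc:
        raise type(exc)(f"[{sid}/{stage}] {exc}") from exc


def tidy_frames(results, metas):
    """CaseResults + SubjectMetas -> (similarity, morphology, meta) tables.

    Morphology is long over limb_role (reference/moving) with the outcome
    columns the statistics layer expects.
    """
    meta_by_id = {m.subject_id: m for m in metas}
    sim_rows, morph_rows, meta_rows = [], [], []
    for r in results:
        m = meta_by_id[r.subject_id]
        row = r.similarity.to_row(r.subject_id)
        row["hausdorff_region"] = r.hausdorff_region
        row["scale_factor"] = r.scale_factor
        sim_rows.append(row)
        for side, rec in r.morphology.items():
            role = "reference" if side == r.reference_side else "moving"
            mr = rec.to_row(r.subject_id, side)
            mr["limb_role"] = role
            morph_rows.append(mr)
        meta_rows.append({"subject_id": m.subject_id, "group": m.group,
                          "mass_kg": m.mass_kg, "limb_length_m": m.limb_length_m,
                          "regenerated": m.regenerated})
    return (pd.DataFrame(sim_rows), pd.DataFrame(morph_rows),
            pd.DataFrame(meta_rows))


def load_manifest(path):
    """Manifest CSV -> SubjectCases.

    Columns: subject_id, group, mass_kg, limb_length_m, regenerated,
    reference_side, then per limb `<side>_mesh` and `<side>_landmarks`
    paths with sides named in `sides` (comma-separated pair).
    """
    df = pd.read_csv(path)
    base = Path(path).parent
    cases = []
    for _, row in df.iterrows():
        sides = [s.strip() for s in str(row["sides"]).split(",")]
        meshes, lms = {}, {}
        for s in sides:
            meshes[s] = read_inputs(base / row[f"{s}_mesh"],
                                    label_id=int(row.get("label_id", 1)))
            lms[s] = LandmarkSet.from_csv(base / row[f"{s}_landmarks"])
        meta = SubjectMeta(subject_id=str(row["subject_id"]),
                           group=str(row["group"]),
                           mass_kg=float(row["mass_kg"]),
                           limb_length_m=float(row["limb_length_m"]),
                           regenerated=bool(row["regenerated"]))
        cases.append(SubjectCase(subject_id=meta.subject_id, sides=meshes,
                                 landmarks=lms, meta=meta,
                                 reference_side=str(row["reference_side"])))
    return cases


def run_cohort(cases, config: PipelineConfig = PipelineConfig(),
               outdir=None, write_heatmaps: bool = False) -> dict:
    """Run every case, then the cohort statistics.

    Per-case failures are quarantined into an ``errors`` table and the
    statistics run on the survivors. With ``outdir``, writes per-case CSV,
    the comparison tables (CSV + JSON), optional heatmap PLYs, and a run
    log carrying the config (with hash and seed) for reproducibility.
    """
    if isinstance(cases, (str, Path)):
        cases = load_manifest(cases)
    results, errors = [], []
    metas = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        try:
            if write_heatmaps and outdir is not None:
                res, geo = run_case(case, config, return_geometry=True)
                export_heatmap_ply(geo["aligned_moving"], geo["heatmap_mm"],
                                   outdir / f"{case.subject_id}_heatmap.ply")
            else:
                res = run_case(case, config)
            results.append(res)
            metas.append(case.meta)
        except Exception as exc:  # quarantine, keep the cohort going
            log.error("case failed: %s", exc)
            errors.append({"subject_id": case.subject_id, "error": str(exc)})

    if not results:
        raise MuscleMorphError("all cases failed")
    sim, morph, meta = tidy_frames(results, metas)
    report = mstats.cohort_report(sim, morph, meta)
    bundle = {"similarity": sim, "morphology": morph, "meta": meta,
              "errors": pd.DataFrame(errors), **report}

    if outdir is not None:
        for name in ("similarity", "morphology", "meta", "errors",
                     "comparisons", "anova", "demographics",
                     "similarity_groups", "morphology_groups", "regeneration"):
            bundle[name].to_csv(outdir / f"{name}.csv", index=False)
        bundle["comparisons"].to_json(outdir / "comparisons.json",
                                      orient="records", indent=2)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump({"config": config.to_dict(),
                       "config_hash": config.config_hash(),
                       "n_cases": len(results),
                       "n_failed": len(errors)}, fh, indent=2)
    return bundle
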