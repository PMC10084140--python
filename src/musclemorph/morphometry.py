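"""Centerline-based discrete morphometry.

Muscle length is the arc length of the intercentroid pathway: per-slice
cross-section centroids linked in order (pass 1 slices along the principal
axis; pass 2 re-slices orthogonal to the local pathway tangent, which keeps
the length unbiased for obliquely oriented muscles). Cross-sectional areas
are measured on planes orthogonal to the pathway; the largest is the peak
CSA. Regions split the pathway at 33% and 66% of arc length, the distal
region anchored at arc length zero. Normalization divides length by limb
length (m) and peak CSA / volume by body mass x limb length (kg.m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .core import (
    DegenerateGeometryError,
    EmptySectionError,
    MorphologyRecord,
    ParameterError,
    RegionRecord,
    REGIONS,
    SubjectMeta,
)
from ._geometry import (
    cumulative_arc_length,
    section_area_centroid,
    section_polygons,
    slab_volume,
    unit,
)

__all__ = [
    "Centerline",
    "fit_centerline",
    "cross_section_area",
    "peak_csa",
    "regional_morphology",
    "normalize",
]


@dataclass
class Centerline:
    """Ordered intercentroid pathway with cumulative arc length (mm).

    Point 0 is the distal end by pipeline convention (phantoms put the
    distal tip at minimal z and the pathway is ordered along +z).
    """

    points: np.ndarray      # (n, 3)
    arc_length: np.ndarray  # (n,), strictly increasing from 0

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        self.arc_length = np.asarray(self.arc_length, float)
        if len(self.points) < 2 or len(self.points) != len(self.arc_length):
            raise ParameterError("centerline needs >= 2 points with arc lengths")
        if not np.all(np.diff(self.arc_length) > 0):
            raise ParameterError("arc lengths must be strictly increasing")

    @property
    def total_length_mm(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, station_mm: float) -> np.ndarray:
        s = np.clip(station_mm, 0.0, self.total_length_mm)
        return np.array([np.interp(s, self.arc_length, self.points[:, i])
                         for i in range(3)])

    def tangent_at(self, station_mm: float) -> np.ndarray:
        s = float(np.clip(station_mm, 0.0, self.total_length_mm))
        i = int(np.searchsorted(self.arc_length, s, side="right")) - 1
        i = np.clip(i, 0, len(self.points) - 2)
        return unit(self.points[i + 1] - self.points[i])

    def station_of_point(self, point: np.ndarray) -> float:
        """Arc length of the pathway point nearest to ``point`` (projection)."""
        p = np.asarray(point, float)
        a, b = self.points[:-1], self.points[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.maximum(denom, 1e-12), 0, 1)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1)
        i = int(np.argmin(d))
        return float(self.arc_length[i] + t[i] * np.sqrt(denom[i]))

    def region_of_station(self, station_mm: float) -> str:
        """Distal [0,33%), middle [33%,66%), proximal [66%,100%] of length."""
        frac = station_mm / self.total_length_mm
        if frac >= 0.66:
            return "proximal"
        if frac >= 0.33:
            return "middle"
        return "distal"


def _principal_axis(mesh: trimesh.Trimesh) -> np.ndarray:
    v = np.asarray(mesh.vertices, float)
    v0 = v - v.mean(axis=0)
    _, _, Vt = np.linalg.svd(v0, full_matrices=False)
    axis = Vt[0]
    # deterministic orientation: along +z if possible, else +y, else +x
    for k in (2, 1, 0):
        if abs(axis[k]) > 1e-9:
            return axis if axis[k] > 0 else -axis
    return axis


def _centroid_nearest(mesh, origin, normal, near_point):
    """Section centroid of the loop nearest to ``near_point`` (None if miss)."""
    got = section_polygons(mesh, origin, normal)
    if got is None:
        return None
    polys, to_3d = got
    best, best_d = None, np.inf
    for p in polys:
        c3 = (to_3d @ np.array([p.centroid.x, p.centroid.y, 0.0, 1.0]))[:3]
        d = np.linalg.norm(c3 - near_point)
        if d < best_d:
            best, best_d = c3, d
    return best


def fit_centerline(mesh: trimesh.Trimesh, slice_spacing_mm: float = 1.0,
                   axis: np.ndarray | None = None,
                   two_pass: bool = True) -> Centerline:
    """Intercentroid pathway of a watertight muscle surface.

    Pass 1 slices along the principal axis (area-weighted centroid of the
    largest loop per slice); pass 2 re-slices once orthogonal to the local
    pass-1 tangent, then both ends are extended along the end tangents to
    the surface extremes so tapered tips contribute their full length.
    """
    if slice_spacing_mm <= 0:
        raise ParameterError("slice_spacing_mm must be positive")
    v = np.asarray(mesh.vertices, float)
    extent = float(np.linalg.norm(v.max(0) - v.min(0)))
    if slice_spacing_mm > extent / 10:
        raise ParameterError("slice spacing too coarse for the mesh extent")

    ax = _principal_axis(mesh) if axis is None else unit(axis)
    h = v @ ax
    c0 = v.mean(axis=0)
    stations = np.arange(h.min() + slice_spacing_mm / 2, h.max(),
                         slice_spacing_mm)
    heights = stations - c0 @ ax
    sections = mesh.section_multiplane(plane_origin=c0, plane_normal=ax,
                                       heights=heights)

    pts = []
    warned = False
    for sec in sections:
        if sec is None or len(sec.entities) == 0:
            continue
        polys = list(sec.polygons_full)
        if not polys:
            continue
        if len(polys) > 1 and not warned:
            warnings.warn("disconnected cross-section: using largest component")
            warned = True
        p = max(polys, key=lambda q: q.area)
        to_3d = sec.metadata["to_3D"]
        pts.append((to_3d @ np.array([p.centroid.x, p.centroid.y, 0.0, 1.0]))[:3])
    if len(pts) < 3:
        raise DegenerateGeometryError("fewer than 3 non-empty slices")
    pts = np.asarray(pts)

    if two_pass:
        tangents = np.gradient(pts, axis=0)
        refined = []
        for p, t in zip(pts, tangents):
            c = _centroid_nearest(mesh, p, unit(t), p)
            refined.append(p if c is None else c)
        pts = np.asarray(refined)

    # drop any near-duplicate consecutive points, then extend to the tips
    keep = np.concatenate([[True],
                           np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    pts = pts[keep]
    t_start = unit(pts[0] - pts[1])
    ext = float(np.max((v - pts[0]) @ t_start))  # furthest surface point beyond

    if ext > 0:
        pts = np.vstack([pts[0] + t_start * ext, pts])
    t_end = unit(pts[-1] - pts[-2])
    ext = float(np.max((v - pts[-1]) @ t_end))
    if ext > 0:
        pts = np.vstack([pts, pts[-1] + t_end * ext])

    return Centerline(pts, cumulative_arc_length(pts))


def cross_section_area(mesh: trimesh.Trimesh, point, normal,
                       largest_only: bool = False) -> float:
    """Planar cross-section area in cm^2 (loops summed unless largest_only)."""
    got = section_area_centroid(mesh, point, normal, largest_only=largest_only)
    if got is None:
        raise EmptySectionError("plane does not intersect the surface")
    area_mm2, _ = got
    return area_mm2 / 100.0


def _station_areas(mesh, centerline: Centerline, station_spacing_mm: float):
    """Areas (cm^2) at stations every spacing along arc length; NaN on miss."""
    L = centerline.total_length_mm
    stations = np.arange(0.0, L + 1e-9, station_spacing_mm)
    areas = np.full(len(stations), np.nan)
    for i, s in enumerate(stations):
        got = section_area_centroid(mesh, centerline.point_at(s),
                                    centerline.tangent_at(s))
        if got is not None:
            areas[i] = got[0] / 100.0
    if len(areas) > 4 and np.isnan(areas[2:-2]).any():
        # misses right at the tapered tips are expected; interior ones are not
        warnings.warn("empty interior stations skipped in peak-CSA scan")
    return stations, areas


def _peak(stations, areas):
    """Max area with proximal-most tie-break (ties within 1e-9 relative)."""
    ok = ~np.isnan(areas)
    if not ok.any():
        raise EmptySectionError("no station intersects the surface")
    amax = np.nanmax(areas)
    tied = ok & (areas >= amax * (1 - 1e-9))
    idx = np.nonzero(tied)[0][-1]  # largest station = proximal-most
    return float(areas[idx]), float(stations[idx])


def peak_csa(mesh: trimesh.Trimesh, centerline: Centerline,
             station_spacing_mm: float = 1.0):
    """(peak CSA cm^2, its arc-length station mm) along the pathway."""
    if station_spacing_mm <= 0:
        raise ParameterError("station_spacing_mm must be positive")
    stations, areas = _station_areas(mesh, centerline, station_spacing_mm)
    return _peak(stations, areas)


def regional_morphology(mesh: trimesh.Trimesh, centerline: Centerline,
                        station_spacing_mm: float = 1.0) -> MorphologyRecord:
    """Whole-muscle and per-region length/peak CSA/volume (raw units).

    Total volume comes from the closed mesh (divergence theorem); regional
    volumes clip the mesh with planes orthogonal to the pathway at the 33%
    and 66% arc-length stations. Regional peaks restrict the station scan:
    distal [0,33%), middle [33%,66%), proximal [66%,100%] — a station
    exactly on a boundary belongs to the more proximal region.
    """
    L = centerline.total_length_mm
    total_vol_cm3 = float(mesh.volume) / 1000.0
    stations, areas = _station_areas(mesh, centerline, station_spacing_mm)
    peak_cm2, peak_station = _peak(stations, areas)

    b1, b2 = 0.33 * L, 0.66 * L
    p1, t1 = centerline.point_at(b1), centerline.tangent_at(b1)
    p2, t2 = centerline.point_at(b2), centerline.tangent_at(b2)
    vol = {
        "distal": slab_volume(mesh, [(p1, -t1)]) / 1000.0,
        "middle": slab_volume(mesh, [(p1, t1), (p2, -t2)]) / 1000.0,
        "proximal": slab_volume(mesh, [(p2, t2)]) / 1000.0,
    }
    resid = abs(sum(vol.values()) - total_vol_cm3) / max(total_vol_cm3, 1e-12)
    if resid > 0.01:
        warnings.warn(f"regional volumes sum off total by {resid:.1%} "
                      "(strongly curved pathway?)")

    masks = {
        "distal": stations < b1,
        "middle": (stations >= b1) & (stations < b2),
        "proximal": stations >= b2,
    }
    regions = {}
    for name in REGIONS:
        a, s = _peak(stations[masks[name]], areas[masks[name]])
        regions[name] = RegionRecord(peak_csa_cm2=a, volume_cm3=vol[name])

    return MorphologyRecord(
        length_cm=L / 10.0,
        peak_csa_cm2=peak_cm2,
        peak_csa_station_mm=peak_station,
        volume_cm3=total_vol_cm3,
        regions=regions,
    )


def normalize(record: MorphologyRecord, meta: SubjectMeta) -> MorphologyRecord:
    """Fill the body-size-normalized fields (length by limb length; peak CSA
    and volume by mass x limb length), totals and all regions."""
    kg_m = meta.mass_kg * meta.limb_length_m
    regions = {
        name: replace(
            reg,
            peak_csa_cm2_per_kg_m=reg.peak_csa_cm2 / kg_m,
            volume_cm3_per_kg_m=reg.volume_cm3 / kg_m,
        )
        for name, reg in record.regions.items()
    }
    return replace(
        record,
        regions=regions,
        length_cm_per_m=record.length_cm / meta.limb_length_m,
        peak_csa_cm2_per_kg_m=record.peak_csa_cm2 / kg_m,
        volume_cm3_per_kg_m=record.volume_cm3 / kg_m,
    )
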