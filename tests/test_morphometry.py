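"""Centerline, cross-sectional areas, regional partition, normalization."""

import numpy as np
import pytest
import trimesh
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from musclemorph.core import EmptySectionError, ParameterError, SubjectMeta
from musclemorph.morphometry import (
    Centerline,
    cross_section_area,
    fit_centerline,
    normalize,
    peak_csa,
    regional_morphology,
)
from musclemorph.similarity import voxelize


class TestCenterline:
    def test_straight_cylinder(self, cylinder):
        cl = fit_centerline(cylinder, slice_spacing_mm=2.0)
        assert cl.total_length_mm == pytest.approx(300.0, abs=1.0)
        assert np.abs(cl.points[:, :2]).max() < 0.1

    def test_tilted_cylinder_recovers_axis_length(self, cylinder):
        """45-degree tilt: refinement must return the axis length, not the
        oblique-slice length 300/cos(45)."""
        tilted = cylinder.copy()
        tilted.apply_transform(trimesh.transformations.rotation_matrix(
            np.pi / 4, [1.0, 0, 0]))
        cl = fit_centerline(tilted, slice_spacing_mm=2.0)
        assert cl.total_length_mm == pytest.approx(300.0, abs=2.0)

    def test_polyline_arc_length_arithmetic(self):
        pts = np.array([[0, 0, 0], [0, 0, 10], [0, 10, 20]], float)
        arc = np.array([0.0, 10.0, 10.0 + np.sqrt(200.0)])
        cl = Centerline(pts, arc)
        assert cl.total_length_mm == pytest.approx(10 + np.sqrt(200))

    def test_too_coarse_spacing_rejected(self, cylinder):
        with pytest.raises(ParameterError):
            fit_centerline(cylinder, slice_spacing_mm=100.0)


class TestCrossSectionArea:
    def test_cylinder_orthogonal(self, cylinder):
        a = cross_section_area(cylinder, [0, 0, 150.0], [0, 0, 1.0])
        assert a == pytest.approx(np.pi, rel=0.005)

    def test_cylinder_oblique_ellipse(self, cylinder):
        """45-degree plane cuts an ellipse of area pi r^2 sqrt(2)."""
        n = [0, np.sin(np.pi / 4), np.cos(np.pi / 4)]
        a = cross_section_area(cylinder, [0, 0, 150.0], n)
        assert a == pytest.approx(np.pi * np.sqrt(2), rel=0.01)

    def test_cube_midplane(self):
        cube = trimesh.creation.box(extents=[20.0] * 3)
        assert cross_section_area(cube, [0, 0, 0], [0, 0, 1.0]) == \
            pytest.approx(4.0, rel=0.005)

    def test_missing_plane_raises(self, cylinder):
        with pytest.raises(EmptySectionError):
            cross_section_area(cylinder, [0, 0, 1000.0], [0, 0, 1.0])


class TestPeakCsa:
    def test_cylinder_ties_resolve_proximal(self, cylinder):
        cl = fit_centerline(cylinder, slice_spacing_mm=2.0)
        a, station = peak_csa(cylinder, cl, station_spacing_mm=2.0)
        assert a == pytest.approx(np.pi, rel=0.005)
        assert station > 0.9 * cl.total_length_mm  # proximal-most tie

    def test_spindle_peak_at_midlength(self, spindle_q1):
        mesh, _ = spindle_q1
        cl = fit_centerline(mesh, slice_spacing_mm=2.0)
        a, station = peak_csa(mesh, cl, station_spacing_mm=2.0)
        assert a == pytest.approx(4 * np.pi, rel=0.01)
        assert station == pytest.approx(cl.total_length_mm / 2, abs=2.0)

    def test_station_refinement_converged(self, spindle_q1):
        mesh, _ = spindle_q1
        cl = fit_centerline(mesh, slice_spacing_mm=2.0)
        a2, _ = peak_csa(mesh, cl, station_spacing_mm=4.0)
        a1, _ = peak_csa(mesh, cl, station_spacing_mm=2.0)
        assert abs(a1 - a2) / a1 < 0.005


class TestRegionalMorphology:
    def test_cylinder_regions_proportional(self, cylinder):
        cl = fit_centerline(cylinder, slice_spacing_mm=2.0)
        rec = regional_morphology(cylinder, cl, station_spacing_mm=2.0)
        V = rec.volume_cm3
        assert rec.regions["proximal"].volume_cm3 == pytest.approx(0.34 * V, rel=0.01)
        assert rec.regions["middle"].volume_cm3 == pytest.approx(0.33 * V, rel=0.01)
        assert rec.regions["distal"].volume_cm3 == pytest.approx(0.33 * V, rel=0.01)

    def test_spindle_distal_fraction(self, spindle_q1):
        """q=1 spindle: distal 0-33% holds int(sin^2)/0.5 ~ 19.05% of volume."""
        mesh, _ = spindle_q1
        cl = fit_centerline(mesh, slice_spacing_mm=2.0)
        rec = regional_morphology(mesh, cl, station_spacing_mm=2.0)
        expected = quad(lambda t: np.sin(np.pi * t) ** 2, 0, 0.33)[0] / 0.5
        assert rec.regions["distal"].volume_cm3 / rec.volume_cm3 == \
            pytest.approx(expected, abs=0.01)

    def test_regional_volumes_conserved(self, spindle_q1, cylinder):
        for mesh in (spindle_q1[0], cylinder):
            cl = fit_centerline(mesh, slice_spacing_mm=2.0)
            rec = regional_morphology(mesh, cl, station_spacing_mm=2.0)
            total = sum(r.volume_cm3 for r in rec.regions.values())
            assert total == pytest.approx(rec.volume_cm3, rel=0.01)
            assert all(r.peak_csa_cm2 <= rec.peak_csa_cm2 + 1e-9
                       for r in rec.regions.values())

    def test_agrees_with_voxel_volume(self, spindle_q1):
        mesh, _ = spindle_q1
        occ = voxelize(mesh, 0.5)
        assert mesh.volume == pytest.approx(occ.volume_mm3(), rel=0.02)

    def test_rigid_invariance(self, spindle_q1):
        """Length, peak CSA, volume unchanged (<0.5%) under rigid motion."""
        mesh, _ = spindle_q1
        cl = fit_centerline(mesh, slice_spacing_mm=2.0)
        rec = regional_morphology(mesh, cl, station_spacing_mm=2.0)
        moved = mesh.copy()
        M = np.eye(4)
        M[:3, :3] = Rotation.from_euler("xyz", [25, -40, 65],
                                        degrees=True).as_matrix()
        M[:3, 3] = [40.0, -70.0, 25.0]
        moved.apply_transform(M)
        cl2 = fit_centerline(moved, slice_spacing_mm=2.0)
        rec2 = regional_morphology(moved, cl2, station_spacing_mm=2.0)
        assert rec2.length_cm == pytest.approx(rec.length_cm, rel=0.005)
        assert rec2.peak_csa_cm2 == pytest.approx(rec.peak_csa_cm2, rel=0.005)
        assert rec2.volume_cm3 == pytest.approx(rec.volume_cm3, rel=0.005)

    def test_scaling_covariance(self, spindle_q1):
        """Isotropic scale s: length x s, peak CSA x s^2, volume x s^3."""
        mesh, _ = spindle_q1
        s = 1.3
        scaled = mesh.copy()
        scaled.apply_scale(s)
        cl = fit_centerline(mesh, slice_spacing_mm=2.0)
        cl2 = fit_centerline(scaled, slice_spacing_mm=2.0 * s)
        r1 = regional_morphology(mesh, cl, station_spacing_mm=2.0)
        r2 = regional_morphology(scaled, cl2, station_spacing_mm=2.0 * s)
        assert r2.length_cm == pytest.approx(s * r1.length_cm, rel=0.01)
        assert r2.peak_csa_cm2 == pytest.approx(s ** 2 * r1.peak_csa_cm2, rel=0.01)
        assert r2.volume_cm3 == pytest.approx(s ** 3 * r1.volume_cm3, rel=0.01)


class TestNormalize:
    def test_worked_examples(self, spindle_q1):
        mesh, _ = spindle_q1
        cl = fit_centerline(mesh, slice_spacing_mm=2.0)
        rec = regional_morphology(mesh, cl, station_spacing_mm=2.0)
        # overwrite with round numbers for the arithmetic check
        from dataclasses import replace
        rec = replace(rec, length_cm=40.0, peak_csa_cm2=12.0, volume_cm3=160.0)
        meta = SubjectMeta("s1", "control", mass_kg=80.0, limb_length_m=0.8)
        out = normalize(rec, meta)
        assert out.length_cm_per_m == pytest.approx(50.0)
        assert out.peak_csa_cm2_per_kg_m == pytest.approx(0.1875)
        assert out.volume_cm3_per_kg_m == pytest.approx(2.5)

    def test_nonpositive_denominators_rejected(self):
        with pytest.raises(ParameterError):
            SubjectMeta("s", "control", mass_kg=0.0, limb_length_m=0.8)
        with pytest.raises(ParameterError):
            SubjectMeta("s", "control", mass_kg=80.0, limb_length_m=-1.0)
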