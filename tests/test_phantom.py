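"""Phantom geometry, voxelization oracles and ground truth."""

import numpy as np
import pytest

import phantomiq as pq
from phantomiq.phantom import (
    StenosisSpec,
    StentSpec,
    VesselGeometry,
    VesselSpec,
    occupancy_from_sdf,
    rasterize_tube,
)


class TestVesselSpecs:
    def test_centerline_must_increase(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 5.0]])
        with pytest.raises(ValueError):
            VesselSpec("v", pts, 2.0)

    def test_nominal_diameter_range(self):
        line = np.array([[0, 0, -5.0], [0, 0, 5.0]])
        with pytest.raises(ValueError):
            VesselSpec("v", line, 0.5)
        with pytest.raises(ValueError):
            VesselSpec("v", line, 5.0)

    def test_stenosis_severity_bounds(self):
        with pytest.raises(ValueError):
            StenosisSpec(s_center=5.0, severity=1.0)

    def test_truth_diameter_at_stenosis_center(self):
        line = np.array([[0, 0, -10.0], [0, 0, 10.0]])
        v = VesselSpec("v", line, 3.2, stenosis=StenosisSpec(10.0, 0.70, 4.0))
        g = VesselGeometry(v)
        # exactly (1 - severity) x reference at the lesion centre
        assert g.diameter_at(10.0) == pytest.approx(0.3 * 3.2)
        assert g.diameter_at(7.9) == pytest.approx(3.2)
        assert g.diameter_at(12.1) == pytest.approx(3.2)
        assert g.reference_diameter_at(10.0) == pytest.approx(3.2)


class TestRasterization:
    def test_cylinder_cross_section_matches_analytic(self):
        # 4.0 mm vessel on a 0.16 mm grid: per-slice occupancy area vs
        # pi r^2 within 1%, for both the fast and the oracle voxelizer
        g = pq.Grid.centered((48, 48, 5), (0.16, 0.16, 0.25))
        line = np.array([[0, 0, -2.0], [0, 0, 2.0]])
        for method in ("sdf", "supersample"):
            occ = rasterize_tube(line, 4.0, g, method=method)
            area = occ[:, :, 2].sum() * 0.16**2
            assert area == pytest.approx(np.pi * 2.0**2, rel=0.01)

    def test_sdf_matches_supersampled_oracle(self):
        g = pq.Grid.centered((40, 40, 9), (0.2, 0.2, 0.25))
        line = np.array([[0.3, -0.2, -2.0], [0.1, 0.4, 2.0]])
        a = rasterize_tube(line, 3.0, g, method="sdf")
        b = rasterize_tube(line, 3.0, g, method="supersample", supersample=5)
        assert np.abs(a - b).max() < 0.35  # boundary voxels only
        assert abs(a.sum() - b.sum()) / b.sum() < 0.005
        inside = b == 1.0
        assert np.array_equal(a == 1.0, inside) or (a[inside] > 0.99).all()

    def test_occupancy_bounded(self):
        g = pq.Grid.centered((32, 32, 5), (0.2, 0.2, 0.25))
        occ = rasterize_tube(np.array([[0, 0, -1], [0, 0, 1.0]]), 2.0, g)
        assert occ.min() >= 0.0 and occ.max() <= 1.0

    def test_axis_aligned_interior_fully_occupied(self):
        g = pq.Grid.centered((32, 32, 5), (0.2, 0.2, 0.25))
        occ = rasterize_tube(np.array([[0, 0, -2], [0, 0, 2.0]]), 2.0, g)
        X, Y, Z = g.meshgrid()
        half_diag = 0.5 * np.hypot(0.2, 0.2)
        deep = np.hypot(X, Y) + half_diag < 1.0
        deep = np.broadcast_to(deep, g.shape) & (np.abs(Z) < 0.5)
        assert np.all(occ[deep] == 1.0)

    def test_stenosis_reduces_occupancy_width(self):
        g = pq.Grid.centered((48, 48, 41), (0.16, 0.16, 0.25))
        line = np.array([[0, 0, -5.0], [0, 0, 5.0]])
        occ = rasterize_tube(line, 3.2, g, stenosis=StenosisSpec(5.0, 0.70, 4.0))
        area_mid = occ[:, :, 20].sum() * 0.16**2
        area_end = occ[:, :, 0].sum() * 0.16**2
        assert area_end == pytest.approx(np.pi * 1.6**2, rel=0.02)
        assert area_mid == pytest.approx(np.pi * (0.3 * 1.6) ** 2, rel=0.10)


class TestDigitalPhantom:
    def test_material_values_and_truth(self, mini_phantom):
        spec, grid, vol, truth = mini_phantom

        def at(x, y, z):
            i = np.round(grid.index_from_world([x, y, z])).astype(int)
            return vol.values[tuple(i)]

        assert at(0, 0, 0) == 424.0  # contrast-filled ventricle
        assert at(-24.7, 24.7, 0) == 40.0  # myocardium
        assert at(60, 0, 0) == -1000.0  # hollow lung
        assert at(0, -62, 0) == 700.0  # plaster vertebra
        assert at(35, 0, 0) == 424.0  # vessel lumen

    def test_pure_material_regions_are_single_valued(self, mini_phantom):
        spec, grid, vol, truth = mini_phantom
        X, Y, Z = grid.meshgrid()
        r = np.hypot(X, Y)
        core = np.broadcast_to(r < 10.0, grid.shape)
        assert np.unique(vol.values[core]).size == 1

    def test_vessel_outside_heart_rejected(self):
        bad = pq.VesselSpec(
            "far", np.array([[70.0, 0, -5], [70.0, 0, 5.0]]), 3.0
        )
        spec = pq.PhantomSpec(vessels=(bad,), stent=None)
        g = pq.Grid.centered((64, 64, 9), (0.625, 0.625, 0.5))
        with pytest.raises(ValueError, match="far"):
            pq.build_digital_phantom(spec, g)

    def test_coarse_grid_rejected(self):
        spec = pq.PhantomSpec(
            vessels=(pq.VesselSpec("v", np.array([[35.0, 0, -5], [35.0, 0, 5.0]]), 1.0),),
            stent=None,
        )
        g = pq.Grid.centered((64, 64, 9), (2.0, 2.0, 0.5))
        with pytest.raises(ValueError, match="coarser"):
            pq.build_digital_phantom(spec, g)

    def test_stent_requires_hu_above_contrast(self):
        vessels = (pq.VesselSpec("v", np.array([[35.0, 0, -8], [35.0, 0, 8.0]]), 3.0),)
        with pytest.raises(ValueError):
            pq.PhantomSpec(
                vessels=vessels,
                stent=StentSpec("v", 8.0, 10.0, 3.0, strut_hu=300.0),
            )

    def test_add_stent_only_changes_stent_region(self, mini_phantom):
        spec0, grid, vol, truth0 = mini_phantom
        vessels = (pq.VesselSpec("v", np.array([[35.0, 0, -8], [35.0, 0, 8.0]]), 3.0),)
        spec = pq.PhantomSpec(vessels=vessels,
                              stent=StentSpec("v", 8.0, 10.0, 3.0))
        g = pq.Grid.centered((256, 256, 33), (0.625, 0.625, 0.5))
        base, truth = pq.build_digital_phantom(spec, g, include_stent=False)
        stented = pq.add_stent(base, spec, truth)
        diff = np.nonzero(stented.values != base.values)
        assert diff[0].size > 0
        xs = g.axis_coords(0)[diff[0]]
        ys = g.axis_coords(1)[diff[1]]
        assert np.all(np.hypot(xs - 35.0, ys) < 2.0)

    def test_z_edge_slant_within_30_degrees(self, mini_phantom):
        *_, truth = mini_phantom
        edge = truth.z_edge()
        assert edge.geometry.tilt_deg <= 30.0 + 1e-9

    def test_default_spec_hu_ordering(self):
        spec = pq.default_phantom_spec()
        assert spec.contrast_hu > spec.myocardium_hu > spec.air_hu
        assert spec.stent.strut_hu > spec.contrast_hu
        assert spec.iodine_mg_per_ml == 18.0
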