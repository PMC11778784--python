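"""Heatmap unrolling, averaging and CSV export."""

import numpy as np
import pytest

from cardiomorph import (
    average_heatmaps,
    export_heatmap_csv,
    extend_centreline,
    read_heatmap_csv,
    unroll_heatmap,
)
from cardiomorph.unroll import Heatmap2D

DORSAL = np.array([0.0, 1.0, 0.0])


@pytest.fixture(scope="module")
def tube_assets(straight):
    """Extended centreline + external mesh of the straight tube."""
    cl = straight["cl"]
    return {
        "mesh": straight["ext_mesh"],
        "cl": cl,
        "ecl": extend_centreline(cl, 0.05 * cl.length),
    }


def split_scalar(mesh, cl, hi=10.0, lo=2.0):
    """Scalar field split by the tangent-dorsal plane: left half hi, right half lo."""
    from cardiomorph._geom import polyline_nearest

    _, _, foot, seg = polyline_nearest(mesh.vertices, cl.points)
    tang = np.diff(cl.points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    side = np.einsum("ij,ij->i", mesh.vertices - foot, np.cross(tang[seg], DORSAL))
    return mesh.with_scalar(np.where(side > 0, hi, lo), "thickness")


class TestUnroll:
    def test_constant_scalar_constant_matrix(self, tube_assets):
        mesh = tube_assets["mesh"].with_scalar(
            np.full(len(tube_assets["mesh"].vertices), 5.0), "thickness"
        )
        hm = unroll_heatmap(mesh, tube_assets["ecl"], DORSAL, n_planes=50, n_angle_bins=36)
        present = hm.present()
        assert present.any()
        np.testing.assert_allclose(hm.values[present], 5.0, rtol=1e-9)

    def test_interior_rows_fully_populated(self, tube_assets):
        """A straight cylinder leaves no spurious gaps away from the tube ends."""
        mesh = tube_assets["mesh"].with_scalar(
            np.ones(len(tube_assets["mesh"].vertices)), "thickness"
        )
        hm = unroll_heatmap(mesh, tube_assets["ecl"], DORSAL, n_planes=50, n_angle_bins=36)
        interior = hm.present()[5:-5]
        assert interior.all()

    def test_left_right_levels_in_half_planes(self, tube_assets):
        mesh = split_scalar(tube_assets["mesh"], tube_assets["cl"])
        hm = unroll_heatmap(mesh, tube_assets["ecl"], DORSAL, n_planes=50, n_angle_bins=36)
        rows = hm.values[10:40]
        left = rows[:, hm.angle_centres > 0]
        right = rows[:, hm.angle_centres < 0]
        assert np.nanmean(left) == pytest.approx(10.0, rel=0.10)
        assert np.nanmean(right) == pytest.approx(2.0, rel=0.10)

    def test_angle_axis_convention(self, tube_assets):
        hm = unroll_heatmap(
            tube_assets["mesh"].with_scalar(np.ones(len(tube_assets["mesh"].vertices)), "t"),
            tube_assets["ecl"],
            DORSAL,
            n_planes=10,
            n_angle_bins=72,
        )
        assert hm.angle_centres[0] == pytest.approx(-177.5)
        assert hm.angle_centres[-1] == pytest.approx(177.5)
        assert np.all(np.diff(hm.angle_centres) == pytest.approx(5.0))

    def test_bent_tube_keeps_gaps_unimputed(self, bent):
        """Any station/angle cell never intersected stays NaN (no interpolation)."""
        from cardiomorph import mask_to_mesh
        from cardiomorph.compartments import VoxelMask
        from cardiomorph.phantoms import OUTER

        b = bent(180.0)
        lib = b["lib"]
        mesh = mask_to_mesh(VoxelMask(lib.mask3d(OUTER, "filled_external"), lib.spacing, lib.origin))
        mesh = mesh.with_scalar(np.ones(len(mesh.vertices)), "t")
        ecl = extend_centreline(b["cl"], 0.05 * b["cl"].length)
        hm = unroll_heatmap(mesh, ecl, (1.0, 0.0, 0.0), n_planes=60, n_angle_bins=36)
        vals = hm.values
        assert np.isnan(vals).any()  # gaps exist
        assert np.all(np.isnan(vals) | (vals == 1.0))  # and are never filled in

    def test_rotation_equivariance(self, tube_assets):
        """Rotating mesh, centreline and dorsal_ref together gives the same matrix."""
        ang = np.radians(25.0)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(ang), -np.sin(ang)], [0, np.sin(ang), np.cos(ang)]]
        )
        mesh = split_scalar(tube_assets["mesh"], tube_assets["cl"])
        base = unroll_heatmap(mesh, tube_assets["ecl"], DORSAL, 30, 24)
        from cardiomorph import Centreline, SurfaceMesh

        rmesh = SurfaceMesh(mesh.vertices @ rot.T, mesh.faces, mesh.scalar, mesh.scalar_name)
        ecl = tube_assets["ecl"]
        rcl = Centreline(
            ecl.points @ rot.T,
            ecl.arclength,
            ecl.inscribed_radius,
            (rot @ ecl.anchors[0], rot @ ecl.anchors[1]),
        )
        rotated = unroll_heatmap(rmesh, rcl, rot @ DORSAL, 30, 24)
        p = base.present() & rotated.present()
        np.testing.assert_allclose(rotated.values[p], base.values[p], atol=0.6)
        # at most one bin's worth of cells may differ in presence
        assert (base.present() != rotated.present()).mean() < 0.05


class TestAverage:
    def make_map(self, values):
        v = np.asarray(values, dtype=float)
        return Heatmap2D(v, np.arange(v.shape[0]) + 0.5, np.linspace(-180, 180, v.shape[1] + 1)[:-1])

    def test_idempotent(self):
        m = self.make_map([[1.0, np.nan], [3.0, 4.0]])
        avg = average_heatmaps([m, m, m])
        np.testing.assert_array_equal(np.nan_to_num(avg.values), np.nan_to_num(m.values))
        assert avg.count[0, 1] == 0 and np.isnan(avg.values[0, 1])

    def test_mean_and_sample_sd(self):
        a = self.make_map([[4.0]])
        b = self.make_map([[6.0]])
        avg = average_heatmaps([a, b])
        assert avg.values[0, 0] == pytest.approx(5.0)
        assert avg.sd[0, 0] == pytest.approx(np.sqrt(2.0))  # sample (n-1) convention

    def test_partial_presence(self):
        maps = [
            self.make_map([[np.nan]]),
            self.make_map([[np.nan]]),
            self.make_map([[7.0]]),
        ]
        avg = average_heatmaps(maps)
        assert avg.values[0, 0] == pytest.approx(7.0)
        assert avg.count[0, 0] == 1
        assert np.isnan(avg.sd[0, 0])

    def test_mass_conservation(self):
        """Sum over specimens equals cell mean times contributor count."""
        rng = np.random.default_rng(5)
        maps = []
        for _ in range(4):
            v = rng.random((6, 8))
            v[rng.random((6, 8)) < 0.3] = np.nan
            maps.append(self.make_map(v))
        avg = average_heatmaps(maps)
        stack = np.stack([m.values for m in maps])
        total = np.nansum(stack, axis=0)
        np.testing.assert_allclose(
            np.nan_to_num(avg.values) * avg.count, total, rtol=1e-12, atol=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_heatmaps([self.make_map([[1.0]]), self.make_map([[1.0, 2.0]])])
        with pytest.raises(ValueError):
            average_heatmaps([])


class TestCsv:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(11)
        v = rng.random((8, 12))
        v[rng.random((8, 12)) < 0.25] = np.nan
        hm = Heatmap2D(v, (np.arange(8) + 0.5) * 3.7, np.linspace(-180, 180, 13)[:-1] + 15.0)
        export_heatmap_csv(hm, tmp_path / "h.csv")
        back = read_heatmap_csv(tmp_path / "h.csv")
        np.testing.assert_array_equal(back.present(), hm.present())
        assert np.array_equal(back.values[back.present()], hm.values[hm.present()])
        np.testing.assert_array_equal(back.arc_centres, hm.arc_centres)

    def test_missing_cells_are_empty_fields(self, tmp_path):
        hm = Heatmap2D(np.array([[1.0, np.nan]]), [0.5], [-90.0, 90.0])
        export_heatmap_csv(hm, tmp_path / "h.csv")
        lines = (tmp_path / "h.csv").read_text().splitlines()
        assert lines[1].endswith(",")  # trailing empty field, not 0
        assert "nan" not in lines[1].lower()

    def test_band_summary_reproducible_from_file(self, tmp_path):
        rng = np.random.default_rng(13)
        v = rng.random((10, 6))
        v[0, 0] = np.nan
        hm = Heatmap2D(v, (np.arange(10) + 0.5) * 10.0, np.linspace(-180, 180, 7)[:-1] + 30.0)
        bands = {"atrium": (0.0, 50.0), "ventricle": (50.0, 100.0)}
        export_heatmap_csv(hm, tmp_path / "h.csv")
        back = read_heatmap_csv(tmp_path / "h.csv")
        assert back.band_means(bands) == hm.band_means(bands)
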