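"""Round-trip and geometry-utility tests for the surface I/O layer."""
import numpy as np
import pytest

import surfmorph as sm
from surfmorph import surface_io
from surfmorph.errors import ConsistencyError, FormatError, ParseError

from conftest import make_grid_mesh, make_tetrahedron


class TestSurfaceRoundTrip:
    def test_tetrahedron_round_trip(self, tmp_path):
        mesh = make_tetrahedron()
        path = tmp_path / "tet.surf"
        surface_io.write_surface(path, mesh)
        back = surface_io.read_surface(path)
        assert back.n_vertices == 4 and back.n_faces == 4
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
        np.testing.assert_array_equal(back.faces, mesh.faces)

    def test_icosphere_round_trip_float32(self, tmp_path):
        mesh = sm.make_icosphere(3, 50.0)
        path = tmp_path / "ico.surf"
        surface_io.write_surface(path, mesh)
        back = surface_io.read_surface(path)
        assert np.max(np.abs(back.vertices - mesh.vertices)) < 1e-4

    def test_write_read_write_byte_stable(self, tmp_path):
        mesh = make_tetrahedron()
        p1, p2 = tmp_path / "a.surf", tmp_path / "b.surf"
        surface_io.write_surface(p1, mesh)
        surface_io.write_surface(p2, surface_io.read_surface(p1))
        # geometry payload after the (timestamped) comment line must agree
        b1, b2 = p1.read_bytes(), p2.read_bytes()
        assert b1[b1.index(b"\n\n"):] == b2[b2.index(b"\n\n"):]

    def test_wrong_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.surf"
        path.write_bytes(b"\x00\x01\x02 not a surface at all")
        with pytest.raises(FormatError):
            surface_io.read_surface(path)

    def test_truncated_file_rejected(self, tmp_path):
        mesh = make_tetrahedron()
        path = tmp_path / "trunc.surf"
        surface_io.write_surface(path, mesh)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) - 10])
        with pytest.raises(ParseError):
            surface_io.read_surface(path)

    def test_off_round_trip(self, tmp_path):
        mesh = make_grid_mesh(4)
        path = tmp_path / "grid.off"
        surface_io.write_off(path, mesh)
        back = surface_io.read_surface(path)  # dispatches on the OFF header
        np.testing.assert_allclose(back.vertices, mesh.vertices)
        np.testing.assert_array_equal(back.faces, mesh.faces)


class TestOverlayRoundTrip:
    def test_constant_overlay(self, tmp_path):
        mesh = make_tetrahedron()
        ov = sm.VertexOverlay("thickness", np.full(4, 2.5), "mm")
        path = tmp_path / "c.curv"
        surface_io.write_overlay(path, ov)
        back = surface_io.read_overlay(path, 4, "thickness")
        np.testing.assert_array_equal(back.values, 2.5)

    def test_random_overlay_float32_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=642)
        path = tmp_path / "r.curv"
        surface_io.write_overlay(path, sm.VertexOverlay("x", vals))
        back = surface_io.read_overlay(path, 642)
        assert np.max(np.abs(back.values - vals)) < 1e-6 * np.max(np.abs(vals))

    def test_length_mismatch(self, tmp_path):
        path = tmp_path / "short.curv"
        surface_io.write_overlay(path, sm.VertexOverlay("x", np.zeros(9)))
        with pytest.raises(ConsistencyError):
            surface_io.read_overlay(path, 10)


class TestLabelRoundTrip:
    @pytest.mark.parametrize("indices", [[0, 5, 9], []])
    def test_round_trip(self, tmp_path, indices):
        label = sm.LesionLabel(np.asarray(indices, dtype=int))
        path = tmp_path / "l.label"
        surface_io.write_label(path, label)
        back = surface_io.read_label(path, 10)
        assert back.as_set() == set(indices)

    def test_out_of_range_index(self, tmp_path):
        path = tmp_path / "l.label"
        surface_io.write_label(path, sm.LesionLabel(np.array([10])))
        with pytest.raises(ConsistencyError):
            surface_io.read_label(path, 10)

    def test_malformed_row(self, tmp_path):
        path = tmp_path / "bad.label"
        path.write_text("#!ascii label\n1\n3 0.0\n")
        with pytest.raises(ParseError):
            surface_io.read_label(path, 10)

    def test_duplicate_indices_rejected(self, tmp_path):
        path = tmp_path / "dup.label"
        path.write_text("#!ascii label\n2\n3 0 0 0 0\n3 0 0 0 0\n")
        with pytest.raises(ConsistencyError):
            surface_io.read_label(path, 10)


class TestVertexAreas:
    def test_sphere_total_area(self):
        mesh = sm.make_icosphere(4, 50.0)
        total = sm.vertex_areas(mesh).values.sum()
        assert abs(total - 4 * np.pi * 50**2) / (4 * np.pi * 50**2) < 0.01

    def test_sum_equals_triangle_area(self, ico3):
        np.testing.assert_allclose(
            sm.vertex_areas(ico3).values.sum(), ico3.total_area, rtol=1e-12)

    def test_single_equilateral_triangle(self):
        mesh = sm.TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]], [[0, 1, 2]])
        np.testing.assert_allclose(
            sm.vertex_areas(mesh).values, (np.sqrt(3) / 4) / 3, rtol=1e-12)

    def test_scaling_quadruples_areas(self, ico3):
        scaled = sm.TriangleMesh(ico3.vertices * 2, ico3.faces)
        np.testing.assert_allclose(
            sm.vertex_areas(scaled).values, 4 * sm.vertex_areas(ico3).values,
            rtol=1e-10)


class TestGeodesicDistance:
    def test_all_sources_zero(self, ico3):
        d = sm.geodesic_distance(ico3, set(range(ico3.n_vertices)))
        assert np.all(d.values == 0)

    def test_grid_axis_distance(self, grid41):
        d = sm.geodesic_distance(grid41, {0})
        assert d.values[10] == pytest.approx(10.0)  # 10 mm along a grid axis

    def test_never_below_euclidean_on_flat_patch(self, grid41):
        d = sm.geodesic_distance(grid41, {0}).values
        euclid = np.linalg.norm(grid41.vertices - grid41.vertices[0], axis=1)
        assert np.all(d >= euclid - 1e-9)

    def test_disconnected_component_infinite(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                          [10, 10, 0], [11, 10, 0], [10, 11, 0]], float)
        faces = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = sm.TriangleMesh(verts, faces)
        d = sm.geodesic_distance(mesh, {0}).values
        assert np.isinf(d[3:]).all() and np.isfinite(d[:3]).all()

    def test_empty_sources_rejected(self, ico3):
        with pytest.raises(ValueError):
            sm.geodesic_distance(ico3, set())


class TestVoxelProjection:
    def test_single_voxel_at_vertex(self, ico3):
        v = ico3.vertices[17]
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 1
        affine = np.eye(4)
        affine[:3, 3] = v - 1  # voxel (1,1,1) center lands exactly on vertex 17
        mask = sm.IntensityVolume(data, affine)
        label = surface_io.project_voxel_mask_to_label(ico3, mask)
        assert 17 in label.as_set()

    def test_empty_mask(self, ico3):
        mask = sm.IntensityVolume(np.zeros((4, 4, 4)))
        label = surface_io.project_voxel_mask_to_label(ico3, mask)
        assert len(label) == 0

    def test_matches_brute_force_nearest_vertex(self, ico3):
        # spherical voxel blob near the surface, compared to an O(V*N) oracle
        center = ico3.vertices[0]
        shape = (11, 11, 11)
        affine = np.eye(4)
        affine[:3, 3] = center - 5
        ii, jj, kk = np.mgrid[:11, :11, :11]
        pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
        mm = pts + (center - 5)
        data = (np.linalg.norm(mm - center, axis=1) <= 5).reshape(shape)
        vol = sm.IntensityVolume(data.astype(float), affine)
        label = surface_io.project_voxel_mask_to_label(ico3, vol, rings=1)

        centers = mm[data.ravel() > 0]
        d = np.linalg.norm(centers[:, None, :] - ico3.vertices[None], axis=2)
        nearest = np.array([row.argmin() for row in d])
        oracle = surface_io.close_label(
            ico3, sm.LesionLabel(np.unique(nearest), "projected"), rings=1)
        assert label.as_set() == oracle.as_set()


class TestCloseLabel:
    def _disc(self, mesh, radius=12.0, center=0):
        d = sm.geodesic_distance(mesh, {center}).values
        return np.flatnonzero(d <= radius)

    def test_fills_interior_hole(self, ico3):
        disc = self._disc(ico3)
        hole = int(ico3.neighbors(0)[0])  # interior vertex of the disc
        label = sm.LesionLabel(np.setdiff1d(disc, [hole]))
        closed = surface_io.close_label(ico3, label, rings=1)
        assert hole in closed.as_set()

    def test_full_mesh_fixed_point(self, ico3):
        label = sm.LesionLabel(np.arange(ico3.n_vertices))
        closed = surface_io.close_label(ico3, label)
        assert closed.as_set() == label.as_set()

    def test_empty_label(self, ico3):
        closed = surface_io.close_label(ico3, sm.LesionLabel(np.array([], int)))
        assert len(closed) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_and_idempotent(self, ico3, seed):
        rng = np.random.default_rng(seed)
        label = sm.LesionLabel(
            rng.choice(ico3.n_vertices, size=60, replace=False))
        once = surface_io.close_label(ico3, label, rings=1)
        twice = surface_io.close_label(ico3, once, rings=1)
        assert label.as_set() <= once.as_set()
        assert once.as_set() == twice.as_set()
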