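"""Per-tessera measures: axes, bounding-box sizes, plane area, curvature."""

import numpy as np
import pytest

from tesserakit import morphometry as mm
from tesserakit import rag as rg
from tesserakit import segmentation as seg
from tesserakit import synthetic as syn
from tesserakit.volumes import BinaryVolume, LabelVolume

from conftest import hex_interior_ids


def shoelace(xy):
    x, y = np.asarray(xy).T
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@pytest.fixture(scope="module")
def slab_signed(clean_phantom):
    fg = BinaryVolume(clean_phantom.truth_labels.data > 0,
                      clean_phantom.voxel_size)
    return seg.signed_distance_map(fg)


class TestOutwardAxis:
    def test_slab_tiles_point_up(self, clean_phantom, slab_signed):
        labels = clean_phantom.truth_labels
        for lab_id in labels.ids()[:10]:
            axis = mm.outward_axis(labels, slab_signed, int(lab_id))
            np.testing.assert_array_equal(axis, [0, 0, 1])

    def test_mirrored_volume_mirrors_axis(self, clean_phantom, slab_signed):
        labels = clean_phantom.truth_labels
        flipped = LabelVolume(labels.data[:, :, ::-1].copy(),
                              labels.voxel_size)
        sd_f = seg.signed_distance_map(
            BinaryVolume(flipped.data > 0, labels.voxel_size)
        )
        lab_id = int(labels.ids()[0])
        axis = mm.outward_axis(flipped, sd_f, lab_id)
        np.testing.assert_array_equal(axis, [0, 0, -1])

    def test_sphere_axis_within_quantization_cone(self):
        surf = syn.SurfaceSpec("sphere", radius=100.0)
        pts = syn.sample_hardcore_points(surf, 40, 25.0, seed=1)
        tess = syn.voronoi_tessellation(pts, surf)
        ph = syn.voxelize_shell(tess, 40.0, 0.0, 5.0, air_depth=150.0)
        fg = BinaryVolume(ph.truth_labels.data > 0, 5.0)
        sd = seg.signed_distance_map(fg)
        cents = rg.centroids(ph.truth_labels)
        half = ph.truth_labels.data.shape[0] * 5.0 / 2
        for lab_id in ph.truth_labels.ids():
            # ray cap of a few shell thicknesses: the hollow core otherwise
            # out-sums the outside air on inward rays
            axis = mm.outward_axis(ph.truth_labels, sd, int(lab_id),
                                   max_range=120.0)
            radial = cents[int(lab_id)] - half
            radial = radial / np.linalg.norm(radial)
            angle = np.degrees(np.arccos(np.clip(axis @ radial, -1, 1)))
            assert angle <= 55.0


class TestBoundingBoxMeasures:
    @pytest.fixture()
    def cuboid(self):
        data = np.zeros((16, 12, 24), dtype=np.int32)
        data[2:12, 2:8, 2:22] = 1  # 10 x 6 x 20 voxels
        return LabelVolume(data, 1.0)

    def test_thickness_along_axis(self, cuboid):
        assert mm.tessera_thickness(cuboid, 1, np.array([0, 0, 1])) == 20.0
        assert mm.tessera_thickness(cuboid, 1, np.array([1, 0, 0])) == 10.0

    def test_width_excludes_thickness_dimension(self, cuboid):
        # z is the thickness axis: width = max(10, 6) = 10
        assert mm.tessera_width(cuboid, 1, np.array([0, 0, 1])) == 10.0

    def test_columnar_tile_width_not_height(self):
        data = np.zeros((10, 10, 24), dtype=np.int32)
        data[2:8, 2:8, 2:22] = 1  # 6 x 6 x 20: taller than wide
        lv = LabelVolume(data, 1.0)
        assert mm.tessera_width(lv, 1, np.array([0, 0, 1])) == 6.0

    def test_one_voxel_tile(self):
        data = np.zeros((3, 3, 3), dtype=np.int32)
        data[1, 1, 1] = 1
        lv = LabelVolume(data, 4.0)
        assert mm.tessera_thickness(lv, 1, np.array([0, 0, 1])) == 4.0
        assert mm.tessera_volume(lv, 1) == 64.0

    def test_in_plane_translation_invariance(self, cuboid):
        shifted = LabelVolume(np.roll(cuboid.data, 2, axis=0), 1.0)
        ax = np.array([0, 0, 1])
        assert mm.tessera_thickness(cuboid, 1, ax) == \
            mm.tessera_thickness(shifted, 1, ax)
        assert mm.tessera_width(cuboid, 1, ax) == \
            mm.tessera_width(shifted, 1, ax)

    def test_volume_conservation(self, zero_gap_phantom):
        labels = zero_gap_phantom.truth_labels
        total = sum(mm.tessera_volume(labels, int(i)) for i in labels.ids())
        voxels = int(np.count_nonzero(labels.data))
        assert total == pytest.approx(voxels * labels.voxel_size**3)


class TestPlaneArea:
    def test_hexagonal_lattice_analytic_area(self, hex_tessellation, hex_graph):
        ids = hex_interior_ids(hex_tessellation, hex_graph)
        for i in ids[:25]:
            assert mm.plane_area(hex_graph, i) == pytest.approx(
                np.sqrt(3) / 2, rel=1e-6
            )

    def test_square_lattice_matches_shoelace_oracle(self):
        # 4-neighbour fan, spacing s: triangle centroids sit at (±s/3, ±s/3);
        # independent shoelace on those closed-form coordinates gives 4s²/9
        s = 1.0
        pts = np.array(
            [[x, y, 0.0] for y in range(5) for x in range(5)], dtype=float
        ) * s
        graph = rg.AdjacencyGraph()
        for idx, p in enumerate(pts):
            graph.add_node(idx + 1, p)
        for idx, p in enumerate(pts):
            x, y = int(p[0]), int(p[1])
            if x < 4:
                graph.add_edge(idx + 1, idx + 2)
            if y < 4:
                graph.add_edge(idx + 1, idx + 6)
        centre_id = 2 * 5 + 2 + 1  # lattice centre (2, 2)
        oracle = shoelace([(s / 3, s / 3), (-s / 3, s / 3),
                           (-s / 3, -s / 3), (s / 3, -s / 3)])
        assert oracle == pytest.approx(4 * s**2 / 9)
        assert mm.plane_area(graph, centre_id) == pytest.approx(oracle, rel=1e-9)

    def test_uniform_scaling_scales_area_quadratically(self, hex_tessellation,
                                                       hex_graph):
        i = hex_interior_ids(hex_tessellation, hex_graph)[0]
        base = mm.plane_area(hex_graph, i)
        scaled = rg.AdjacencyGraph()
        for n, d in hex_graph.g.nodes(data=True):
            scaled.add_node(n, 3.0 * d["centroid"])
        for a, b in hex_graph.g.edges:
            scaled.add_edge(a, b)
        assert mm.plane_area(scaled, i) == pytest.approx(9 * base, rel=1e-9)

    def test_rigid_rotation_invariance(self, hex_tessellation, hex_graph):
        i = hex_interior_ids(hex_tessellation, hex_graph)[0]
        base = mm.plane_area(hex_graph, i)
        # rotate all centroids by an arbitrary 3-D rotation
        theta, phi = 0.7, 0.4
        rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rx = np.array([[1, 0, 0], [0, np.cos(phi), -np.sin(phi)],
                       [0, np.sin(phi), np.cos(phi)]])
        rot = rx @ rz
        g2 = rg.AdjacencyGraph()
        for n, d in hex_graph.g.nodes(data=True):
            g2.add_node(n, rot @ d["centroid"])
        for a, b in hex_graph.g.edges:
            g2.add_edge(a, b)
        assert mm.plane_area(g2, i) == pytest.approx(base, rel=1e-6)

    def test_under_three_neighbors_undefined(self):
        graph = rg.AdjacencyGraph()
        graph.add_node(1, [0, 0, 0])
        graph.add_node(2, [1, 0, 0])
        graph.add_edge(1, 2)
        with pytest.raises(ValueError, match="<3 neighbours"):
            mm.plane_area(graph, 1)


class TestSmoothedSurface:
    def test_planar_rag_stays_coplanar(self, hex_graph):
        mesh = mm.smooth_surface_from_rag(hex_graph, iterations=10)
        assert np.abs(mesh.vertices[:, 2]).max() < 1e-9 * 14.0

    def test_sphere_vertices_near_radius(self, sphere_tessellation):
        graph = rg.graph_from_tessellation(sphere_tessellation)
        mesh = mm.smooth_surface_from_rag(graph, iterations=10)
        radii = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(radii / 500.0 - 1).max() < 0.05

    def test_zero_iterations_keeps_node_vertices(self, hex_graph):
        mesh = mm.smooth_surface_from_rag(hex_graph, iterations=0)
        node_pts = np.array(
            [hex_graph.centroid(n) for n in sorted(hex_graph.g.nodes)]
        )
        verts = mesh.vertices
        # original nodes are a subset of the subdivided vertex set
        for p in node_pts[:10]:
            assert np.min(np.linalg.norm(verts - p, axis=1)) < 1e-12

    def test_vertex_count_at_least_node_count(self, hex_graph):
        mesh = mm.smooth_surface_from_rag(hex_graph, iterations=3)
        assert len(mesh.vertices) >= hex_graph.g.number_of_nodes()


class TestCurvature:
    def test_sphere_curvatures(self, sphere_tessellation):
        tess = sphere_tessellation
        graph = rg.graph_from_tessellation(tess)
        mesh = mm.smooth_surface_from_rag(graph, iterations=10)
        K = []
        H = []
        for i in range(tess.n_cells):
            k, h = mm.tessera_curvature(mesh, tess.seeds[i])
            K.append(k)
            H.append(h)
        assert abs(np.median(K) * 500.0**2 - 1) < 0.15
        assert abs(np.median(H) * 500.0 - 1) < 0.10
        assert np.median(H) > 0  # convex sphere, outward normal

    def test_plane_curvatures_vanish(self, hex_tessellation, hex_graph):
        mesh = mm.smooth_surface_from_rag(hex_graph, iterations=10)
        interior = hex_interior_ids(hex_tessellation, hex_graph)
        for i in interior[:20]:
            K, H = mm.tessera_curvature(mesh, hex_graph.centroid(i))
            assert abs(K) < 1e-3 * (1 / 1.0) ** 2
            assert abs(H) < 1e-3 * (1 / 1.0)

    def test_cylinder_curvatures(self):
        surf = syn.SurfaceSpec("cylinder", extent=(2000.0,), radius=500.0)
        pts = syn.sample_hardcore_points(surf, 500, 40.0, seed=3)
        tess = syn.voronoi_tessellation(pts, surf)
        graph = rg.graph_from_tessellation(tess)
        mesh = mm.smooth_surface_from_rag(graph, iterations=10)
        K, H = [], []
        for i in range(tess.n_cells):
            if tess.boundary[i]:
                continue
            k, h = mm.tessera_curvature(mesh, tess.seeds[i])
            K.append(k)
            H.append(h)
        assert abs(np.median(K)) * 500.0**2 < 0.2  # K ~ 0 on a cylinder
        assert abs(np.median(H) * 2 * 500.0 - 1) < 0.15

    def test_empty_mesh_errors(self):
        import trimesh

        empty = mm.SurfaceMesh(
            trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3))),
            np.array([]), np.array([]),
        )
        with pytest.raises(ValueError):
            mm.tessera_curvature(empty, [0, 0, 0])


class TestMineralizedFraction:
    def test_labels_filling_mask_give_one(self):
        data = np.ones((4, 4, 4), dtype=np.int32)
        assert mm.mineralized_fraction(
            LabelVolume(data, 1.0), np.ones((4, 4, 4), bool)
        ) == 1.0

    def test_matches_generation_bookkeeping(self, zero_gap_phantom):
        ph = zero_gap_phantom
        frac = mm.mineralized_fraction(ph.truth_labels, ph.element_mask)
        labeled = int(np.count_nonzero(ph.truth_labels.data))
        assert frac == pytest.approx(labeled / ph.element_mask.sum(), abs=1e-12)

    def test_monotone_decreasing_in_gap_width(self):
        from tesserakit import pipeline as pl

        kw = dict(extent=(300.0, 300.0), n_seeds=15, seed=2,
                  lacunae=(0, 0.0), noise_sd=0.0, blur_sigma=0.0)
        narrow = pl.default_phantom(gap_width=5.0, **kw)
        wide = pl.default_phantom(gap_width=15.0, **kw)
        f_narrow = mm.mineralized_fraction(narrow.truth_labels,
                                           narrow.element_mask)
        f_wide = mm.mineralized_fraction(wide.truth_labels, wide.element_mask)
        assert f_wide < f_narrow

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            mm.mineralized_fraction(
                LabelVolume(np.zeros((2, 2, 2), np.int32), 1.0),
                np.zeros((2, 2, 2), bool),
            )
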