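"""Graph morphology vs brute-force oracles; discrete geometry vs analytics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tash import mesh
from tash.errors import ParameterError
from tash.types import TriangleSurface, VertexScalarField

import oracles


def random_blob(rng, n_total, size):
    return np.unique(rng.choice(n_total, size=size, replace=False))


class TestAdjacency:
    def test_single_triangle(self):
        s = TriangleSurface(coords=np.eye(3), faces=np.array([[0, 1, 2]]))
        g = mesh.build_adjacency(s)
        assert all(len(g.neighbors(v)) == 2 for v in range(3))

    def test_tetrahedron_complete(self, tetrahedron):
        g = mesh.build_adjacency(tetrahedron)
        assert all(len(g.neighbors(v)) == 3 for v in range(4))

    def test_grid_matches_edge_enumeration(self, grid12, grid12_graph):
        expected = oracles.neighbour_lists(grid12.n_vertices, grid12.faces)
        got = grid12_graph.neighbor_sets()
        assert got == expected
        degrees = grid12_graph.degree()
        # interior vertices of the triangulated grid have degree 6
        interior = np.setdiff1d(np.arange(grid12.n_vertices),
                                mesh.boundary_vertices(grid12))
        assert set(degrees[interior].tolist()) == {6}

    def test_symmetry(self, grid12_graph):
        m = grid12_graph.matrix
        assert (m != m.T).nnz == 0
        assert m.diagonal().sum() == 0


class TestConnectedComponents:
    def test_empty(self, grid12_graph):
        assert mesh.connected_components(np.array([], dtype=int),
                                         grid12_graph) == []

    def test_two_disjoint_triangles(self):
        s = TriangleSurface(
            coords=np.vstack([np.eye(3), np.eye(3) + 10]),
            faces=np.array([[0, 1, 2], [3, 4, 5]]))
        g = mesh.build_adjacency(s)
        comps = mesh.connected_components(np.arange(6), g)
        assert [c.tolist() for c in comps] == [[0, 1, 2], [3, 4, 5]]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_subsets_match_bfs_oracle(self, grid30, grid30_graph, seed):
        rng = np.random.default_rng(seed)
        members = random_blob(rng, grid30.n_vertices, 200)
        adj = oracles.neighbour_lists(grid30.n_vertices, grid30.faces)
        got = [c.tolist() for c in mesh.connected_components(members,
                                                             grid30_graph)]
        assert got == oracles.components_oracle(members, adj)


class TestMorphologicalOpen:
    def test_empty_set(self, grid12_graph):
        assert mesh.morphological_open(np.array([], dtype=int),
                                       grid12_graph, 3).size == 0

    def test_depth_zero_rejected(self, grid12_graph):
        with pytest.raises(ParameterError):
            mesh.morphological_open(np.array([0]), grid12_graph, 0)

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_width6_strip_removed_disk_kept(self, width):
        """A ≤6-vertex-wide strip attached to a large disk disappears; the
        disk interior survives the default-depth opening."""
        from conftest import grid_surface
        n = 40
        grid = grid_surface(n)
        g = mesh.build_adjacency(grid)
        idx = np.arange(n * n).reshape(n, n)
        dist_c = mesh.hop_distance(g, np.array([idx[20, 12]]))
        disk = np.flatnonzero(dist_c <= 10)
        r0 = 20 - width // 2
        strip = np.setdiff1d(idx[r0:r0 + width, 23:36].ravel(), disk)
        members = np.union1d(disk, strip)
        opened = mesh.morphological_open(members, g, depth=3)
        assert np.intersect1d(opened, strip).size == 0
        interior = np.flatnonzero(dist_c <= 7)
        assert np.isin(interior, opened).all()

    @pytest.mark.parametrize("depth", [1, 2, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_literal_oracle(self, grid30, grid30_graph, depth, seed):
        rng = np.random.default_rng(seed)
        members = random_blob(rng, grid30.n_vertices, 350)
        adj = oracles.neighbour_lists(grid30.n_vertices, grid30.faces)
        got = mesh.morphological_open(members, grid30_graph, depth).tolist()
        assert got == oracles.opening_oracle(members, adj, depth)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_lattice_properties(self, grid30, grid30_graph, seed):
        """Anti-extensive, increasing and idempotent."""
        rng = np.random.default_rng(seed)
        small = random_blob(rng, grid30.n_vertices, 300)
        extra = random_blob(rng, grid30.n_vertices, 150)
        big = np.union1d(small, extra)
        o_small = mesh.morphological_open(small, grid30_graph, 2)
        o_big = mesh.morphological_open(big, grid30_graph, 2)
        assert np.isin(o_small, small).all()            # anti-extensive
        assert np.isin(o_small, o_big).all()            # increasing
        again = mesh.morphological_open(o_small, grid30_graph, 2)
        np.testing.assert_array_equal(again, o_small)   # idempotent


    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(members=st.sets(st.integers(0, 143), max_size=100),
           depth=st.integers(1, 3))
    def test_opening_properties_hold_for_arbitrary_sets(self, grid12_graph,
                                                        members, depth):
        members = np.array(sorted(members), dtype=np.int64)
        opened = mesh.morphological_open(members, grid12_graph, depth)
        assert np.isin(opened, members).all()
        again = mesh.morphological_open(opened, grid12_graph, depth)
        np.testing.assert_array_equal(again, opened)


class TestRegionGrow:
    def test_empty_seeds(self, grid12_graph):
        out = mesh.region_grow(np.array([], dtype=int), np.arange(10),
                               grid12_graph)
        assert out.size == 0

    def test_seeds_equal_allowed_fixed_point(self, grid12_graph):
        allowed = np.arange(40)
        out = mesh.region_grow(allowed, allowed, grid12_graph)
        np.testing.assert_array_equal(out, allowed)

    def test_seeds_outside_allowed_rejected(self, grid12_graph):
        with pytest.raises(ParameterError):
            mesh.region_grow(np.array([100]), np.arange(10), grid12_graph)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_components_filter_oracle(self, grid30, grid30_graph, seed):
        rng = np.random.default_rng(seed + 10)
        allowed = random_blob(rng, grid30.n_vertices, 300)
        seeds = rng.choice(allowed, size=8, replace=False)
        adj = oracles.neighbour_lists(grid30.n_vertices, grid30.faces)
        got = mesh.region_grow(seeds, allowed, grid30_graph).tolist()
        assert got == oracles.region_grow_oracle(seeds, allowed, adj)

    def test_closed_under_adjacency(self, grid30, grid30_graph):
        rng = np.random.default_rng(99)
        allowed = random_blob(rng, grid30.n_vertices, 400)
        seeds = rng.choice(allowed, size=5, replace=False)
        grown = mesh.region_grow(seeds, allowed, grid30_graph)
        grown_set, allowed_set = set(grown.tolist()), set(allowed.tolist())
        assert set(seeds.tolist()) <= grown_set
        for v in grown:
            for w in grid30_graph.neighbors(v):
                if int(w) in allowed_set:
                    assert int(w) in grown_set


class TestVertexAreas:
    def test_single_right_triangle(self):
        s = TriangleSurface(
            coords=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            faces=np.array([[0, 1, 2]]))
        areas = mesh.vertex_areas(s).values
        np.testing.assert_allclose(areas, [1 / 6] * 3)
        assert areas.sum() == pytest.approx(0.5)

    def test_icosphere_total_area(self, icosphere10):
        total = mesh.vertex_areas(icosphere10).values.sum()
        assert total == pytest.approx(4 * np.pi * 100, rel=0.01)

    def test_conservation_on_random_mesh(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(40, 3))
        faces = np.column_stack([np.arange(38), np.arange(1, 39),
                                 np.arange(2, 40)])
        s = TriangleSurface(coords=coords, faces=faces)
        tri = coords[faces]
        tri_areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        assert mesh.vertex_areas(s).values.sum() == pytest.approx(
            tri_areas.sum())


class TestCurvature:
    def test_flat_grid_interior_zero(self, grid12):
        H, K = mesh.discrete_curvatures(grid12)
        interior = np.setdiff1d(np.arange(grid12.n_vertices),
                                mesh.boundary_vertices(grid12))
        np.testing.assert_allclose(H.values[interior], 0, atol=1e-10)
        np.testing.assert_allclose(K.values[interior], 0, atol=1e-10)

    def test_icosphere_signed_values(self, icosphere10):
        """Convex sphere r=10: H ≈ −0.1 (FreeSurfer sign), K ≈ +0.01."""
        H, K = mesh.discrete_curvatures(icosphere10)
        np.testing.assert_allclose(H.values, -0.1, rtol=0.05)
        np.testing.assert_allclose(K.values, 0.01, rtol=0.05)

    def test_gauss_bonnet_on_sphere(self, icosphere10):
        H, K = mesh.discrete_curvatures(icosphere10)
        areas = mesh.vertex_areas(icosphere10).values
        assert (K.values * areas).sum() == pytest.approx(4 * np.pi, rel=0.01)

    def test_ridge_crest_negative_valley_positive(self, fpd_subject):
        curv = fpd_subject.curv.values
        crest1 = fpd_subject.truth.crest[1]
        assert (curv[crest1] < 0).all()
        # valley floor midway between the two separated ridges
        Y = fpd_subject.white.coords[:, 1]
        X = fpd_subject.white.coords[:, 0]
        mid = np.flatnonzero((np.abs(Y - 0.268 * (X - 30)) < 0.3)
                             & (X > 10) & (X < 50))
        assert (curv[mid] > 0).mean() > 0.95

    def test_nonmanifold_edge_rejected(self):
        s = TriangleSurface(
            coords=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                             [1, 1, 1]]),
            faces=np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]]))
        with pytest.raises(Exception):
            mesh.discrete_curvatures(s)


class TestWeightedCentroid:
    def test_single_vertex(self, grid12):
        areas = mesh.vertex_areas(grid12)
        np.testing.assert_allclose(
            mesh.weighted_centroid(np.array([5]), grid12, areas),
            grid12.coords[5])

    def test_symmetric_patch(self, grid12):
        """Interior block symmetric about the grid centre → centroid there."""
        areas = mesh.vertex_areas(grid12)
        idx = np.arange(144).reshape(12, 12)[4:8, 4:8].ravel()
        c = mesh.weighted_centroid(idx, grid12, areas)
        np.testing.assert_allclose(c[:2], [5.5, 5.5])

    def test_matches_direct_summation(self, grid30):
        rng = np.random.default_rng(2)
        areas = mesh.vertex_areas(grid30)
        members = random_blob(rng, grid30.n_vertices, 50)
        w = areas.values[members]
        expected = (grid30.coords[members] * w[:, None]).sum(0) / w.sum()
        np.testing.assert_allclose(
            mesh.weighted_centroid(members, grid30, areas), expected)

    def test_empty_set_rejected(self, grid12):
        with pytest.raises(ParameterError):
            mesh.weighted_centroid(np.array([], dtype=int), grid12,
                                   mesh.vertex_areas(grid12))
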