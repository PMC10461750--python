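import networkx as nx
import numpy as np
import pytest

from smv import vessel_graph as vg


# ---------------------------------------------------------------- segmentation


class TestSegmentVessels:
    def test_uniform_image_gives_empty_mask(self):
        img = np.full((40, 40), 7.0)
        with pytest.warns(UserWarning):
            mask = vg.segment_vessels(img, block_size=11)
        assert not mask.grid.any()

    def test_dark_band_dark_foreground(self):
        # bright background with a dark 5-px band; local-mean threshold oracle
        img = np.full((41, 41), 10.0)
        img[18:23, :] = 2.0
        mask = vg.segment_vessels(img, block_size=11, dark_vessels=True)
        assert mask.grid[20].all()
        # brute-force check on an interior pixel: value below local mean
        r, c = 20, 20
        block = img[r - 5 : r + 6, c - 5 : c + 6]
        assert img[r, c] < block.mean()
        assert bool(mask.grid[r, c]) == (img[r, c] < block.mean())

    def test_checkerboard_matches_bruteforce(self):
        period = 16
        img = np.zeros((64, 64))
        for i in range(0, 64, period):
            for j in range(0, 64, period):
                if ((i + j) // period) % 2 == 0:
                    img[i : i + period, j : j + period] = 1.0
        bs = 5
        mask = vg.segment_vessels(img, block_size=bs, dark_vessels=True)
        # independent brute-force local-mean comparison away from borders
        half = bs // 2
        for r, c in [(8, 8), (8, 24), (24, 8), (30, 30)]:
            local = img[r - half : r + half + 1, c - half : c + half + 1].mean()
            assert bool(mask.grid[r, c]) == (img[r, c] < local)

    def test_even_block_size_rejected(self):
        with pytest.raises(ValueError):
            vg.segment_vessels(np.zeros((10, 10)), block_size=10)

    def test_rgb_rejected(self):
        with pytest.raises(ValueError):
            vg.segment_vessels(np.zeros((10, 10, 3)))


# -------------------------------------------------------------- skeletonization


class TestSkeletonize:
    def test_three_row_bar_centre_radius(self):
        grid = np.zeros((9, 30), dtype=bool)
        grid[3:6, :] = True
        sk = vg.skeletonize_mask(vg.VesselMask(grid=grid))
        rows = np.nonzero(sk.skeleton)[0]
        assert set(rows) == {4}
        centre = sk.radius[4, 15]
        assert centre == pytest.approx(2.0)

    def test_single_pixel(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        sk = vg.skeletonize_mask(vg.VesselMask(grid=grid))
        assert sk.skeleton[2, 2]
        assert sk.radius[2, 2] == pytest.approx(1.0)

    def test_plus_shape_has_junction(self):
        grid = np.zeros((21, 21), dtype=bool)
        grid[9:12, :] = True
        grid[:, 9:12] = True
        sk = vg.skeletonize_mask(vg.VesselMask(grid=grid))
        # some skeleton pixel must have >= 3 skeleton neighbours
        from smv.vessel_graph import _neighbor_count

        counts = _neighbor_count(sk.skeleton)
        assert (counts[sk.skeleton] >= 3).any()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            vg.skeletonize_mask(vg.VesselMask(grid=np.zeros((5, 5), dtype=bool)))

    def test_skeleton_subset_of_mask(self):
        mask = vg.synthetic_vessel_template(64, 64, n_trees=2, rng_seed=0)
        sk = vg.skeletonize_mask(mask)
        assert not (sk.skeleton & ~mask.grid).any()
        assert (sk.radius[sk.skeleton] > 0).all()


# ------------------------------------------------------------- graph building


def _line_skeleton(n=11):
    skel = np.zeros((5, n + 4), dtype=bool)
    skel[2, 2 : 2 + n] = True
    radius = np.where(skel, 1.5, 0.0)
    return vg.SkeletonMap(skeleton=skel, radius=radius)


class TestBuildGraph:
    def test_straight_line(self):
        g = vg.build_undirected_graph(_line_skeleton())
        assert len(g.edges) == 1
        assert len(g.vertices) == 2

    def test_y_shape(self):
        skel = np.zeros((21, 21), dtype=bool)
        skel[10, 2:11] = True  # horizontal arm into centre
        for i in range(1, 9):
            skel[10 - i, 10 + i] = True  # up-right arm
            skel[10 + i, 10 + i] = True  # down-right arm
        skel[10, 10] = True
        sk = vg.SkeletonMap(skeleton=skel, radius=np.where(skel, 2.0, 0.0))
        g = vg.build_undirected_graph(sk)
        assert len(g.edges) == 3
        assert len(g.vertices) == 4  # 3 endpoints + 1 junction

    def test_closed_ring_single_self_loop(self):
        # diamond ring: every pixel has exactly two 8-connected neighbours
        skel = np.zeros((15, 15), dtype=bool)
        for r in range(15):
            for c in range(15):
                if abs(r - 7) + abs(c - 7) == 5:
                    skel[r, c] = True
        sk = vg.SkeletonMap(skeleton=skel, radius=np.where(skel, 1.0, 0.0))
        g = vg.build_undirected_graph(sk)
        assert len(g.edges) == 1
        e = g.edges[0]
        assert e.u == e.v  # self loop

    def test_volume_sum_exact(self):
        mask = vg.synthetic_vessel_template(96, 96, n_trees=2, rng_seed=1)
        g = vg.build_undirected_graph(vg.skeletonize_mask(mask))
        assert g.total_volume == sum(e.volume for e in g.edges)
        assert all(e.volume > 0 for e in g.edges)


class TestOrientGraph:
    def test_path_directed_from_widest_endpoint(self):
        # path A-B-C, radius 5 at A end, 2 at C end
        skel = np.zeros((5, 21), dtype=bool)
        skel[2, 1:20] = True
        radius = np.where(skel, 0.0, 0.0).astype(float)
        radius[2, 1:20] = np.linspace(5, 2, 19)
        g = vg.build_undirected_graph(vg.SkeletonMap(skeleton=skel, radius=radius))
        og = vg.orient_graph(g)
        assert len(og.edges) == 1
        e = og.edges[0]
        assert e.u == (2, 1)  # widest endpoint is the source
        assert e.radii[0] == pytest.approx(5.0)

    def test_triangle_cycle_drops_one_edge(self):
        g = vg.VesselGraph(shape=(10, 10), directed=False)
        pts = [(1, 1), (1, 8), (8, 4)]
        for a, b in [(0, 1), (1, 2), (2, 0)]:
            path = np.array([pts[a], pts[b]])
            g.add_edge(vg.Edge(u=pts[a], v=pts[b], path=path, radii=np.array([1.0, 1.0])))
        og = vg.orient_graph(g)
        assert len(og.edges) == 2
        assert nx.is_directed_acyclic_graph(nx.DiGraph(og.graph))

    def test_oriented_forest_covers_all_vertices(self):
        mask = vg.synthetic_vessel_template(96, 96, n_trees=3, rng_seed=2)
        g = vg.build_undirected_graph(vg.skeletonize_mask(mask))
        og = vg.orient_graph(g)
        dg = nx.DiGraph(og.graph)
        assert nx.is_directed_acyclic_graph(dg)
        # every vertex has in-degree <= 1 in a forest of arborescences
        assert all(d <= 1 for _, d in dg.in_degree)
        assert set(dg.nodes) >= set(v for e in og.edges for v in (e.u, e.v))

    def test_y_edges_point_away_from_widest_source(self):
        skel = np.zeros((21, 21), dtype=bool)
        skel[10, 2:11] = True
        for i in range(1, 9):
            skel[10 - i, 10 + i] = True
            skel[10 + i, 10 + i] = True
        skel[10, 10] = True
        radius = np.where(skel, 1.0, 0.0)
        radius[10, 2] = 4.0  # widest endpoint: left end
        g = vg.build_undirected_graph(vg.SkeletonMap(skeleton=skel, radius=radius))
        og = vg.orient_graph(g)
        dg = nx.DiGraph(og.graph)
        src = (10, 2)
        for v in dg.nodes:
            if v != src:
                assert nx.has_path(dg, src, v)


# --------------------------------------------------------- velocity assignment


class TestRadiusVelocityTable:
    def test_single_vessel_pairs(self):
        vmap = np.zeros((20, 40))
        vmap[7:14, 2:38] = 8.0  # 7 rows: centre-row EDT radius is 4 px
        table = vg.build_radius_velocity_table(vmap)
        assert (table.velocities == 8.0).all()
        # away from the strip ends every medial-axis radius equals 4
        assert np.median(table.radii) == pytest.approx(4.0)

    def test_two_widths_sorted(self):
        vmap = np.zeros((40, 60))
        vmap[4:8, 5:55] = 3.0  # width 4
        vmap[20:32, 5:55] = 9.0  # width 12
        table = vg.build_radius_velocity_table(vmap)
        assert np.all(np.diff(table.radii) >= 0)
        # low-radius cluster carries velocity 3, high-radius cluster 9
        assert table.velocities[0] == 3.0
        assert table.velocities[-1] == 9.0

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            vg.build_radius_velocity_table(np.zeros((10, 10)))


class TestAssignReferenceVelocity:
    def _tube_graph(self):
        from tests.conftest import straight_tube_graph

        return straight_tube_graph(radius=3.0)

    def test_degenerate_window_exact(self):
        g = self._tube_graph()
        table = vg.RadiusVelocityTable(pairs=[[3.0, 10.0], [3.2, 10.0], [2.9, 10.0]])
        vg.assign_reference_velocity(g, table, rng_seed=0)
        assert g.edges[0].v_ref == pytest.approx(10.0)

    def test_window_statistics_monte_carlo(self):
        g = self._tube_graph()
        table = vg.RadiusVelocityTable(pairs=[[3.0, 8.0], [3.1, 12.0]])
        draws = []
        for seed in range(400):
            vg.assign_reference_velocity(g, table, rng_seed=seed)
            draws.append(g.edges[0].v_ref)
        # draws ~ N(10, 4): mean near 10, sd near 2
        assert np.mean(draws) == pytest.approx(10.0, abs=0.4)
        assert np.std(draws) == pytest.approx(2.0, abs=0.4)

    def test_out_of_range_radius_falls_back_to_nearest(self):
        g = self._tube_graph()  # mean radius 3
        table = vg.RadiusVelocityTable(pairs=[[20.0, 5.0], [30.0, 9.0]])
        vg.assign_reference_velocity(g, table, rng_seed=0)
        assert g.edges[0].v_ref == pytest.approx(5.0)  # nearest radius 20

    def test_sigma_zero_seed_independent(self):
        g = self._tube_graph()
        table = vg.RadiusVelocityTable(pairs=[[3.0, 6.0]])
        vals = set()
        for seed in (0, 1, 99):
            vg.assign_reference_velocity(g, table, rng_seed=seed)
            vals.add(g.edges[0].v_ref)
        assert vals == {6.0}

    def test_requires_oriented_graph(self):
        g = vg.VesselGraph(shape=(5, 5), directed=False)
        with pytest.raises(ValueError):
            vg.assign_reference_velocity(g, vg.RadiusVelocityTable(pairs=[[1, 1]]))


class TestAssignVelocityFromMap:
    def test_uniform_map(self, tube):
        vmap = np.full(tube.shape, 5.0)
        vg.assign_velocity_from_map(tube, vmap)
        assert tube.edges[0].v_ref == pytest.approx(5.0)

    def test_mean_of_nonzero(self, tube):
        vmap = np.zeros(tube.shape)
        vmap[:, :40] = 4.0
        vmap[:, 40:] = 8.0
        vg.assign_velocity_from_map(tube, vmap)
        # footprint covers equal lengths of 4 and 8 regions (within discretization)
        assert tube.edges[0].v_ref == pytest.approx(6.0, abs=0.4)

    def test_zero_footprint_falls_back(self, tube, default_table):
        vmap = np.zeros(tube.shape)
        vg.assign_velocity_from_map(tube, vmap, fallback_table=default_table)
        assert tube.edges[0].v_ref == pytest.approx(0.5 * 3.0, abs=0.2)

    def test_misaligned_shapes_raise(self, tube):
        with pytest.raises(ValueError):
            vg.assign_velocity_from_map(tube, np.zeros((3, 3)))


# ----------------------------------------------------------- synthetic masks


class TestSyntheticTemplate:
    def test_zero_trees_empty(self):
        mask = vg.synthetic_vessel_template(32, 32, n_trees=0, rng_seed=0)
        assert not mask.grid.any()

    def test_deterministic(self):
        a = vg.synthetic_vessel_template(64, 64, n_trees=2, rng_seed=5)
        b = vg.synthetic_vessel_template(64, 64, n_trees=2, rng_seed=5)
        assert np.array_equal(a.grid, b.grid)

    def test_skeleton_radii_in_range(self):
        mask = vg.synthetic_vessel_template(96, 96, n_trees=1, radius_range=(2, 6), rng_seed=3)
        sk = vg.skeletonize_mask(mask)
        radii = sk.radius[sk.skeleton]
        assert radii.min() >= 1.0  # 1-px discretization slack
        assert radii.max() <= 7.5

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValueError):
            vg.synthetic_vessel_template(20, 20, radius_range=(2, 10), rng_seed=0)

    def test_footprint_round_trip(self):
        # graph rasterized back must cover >= 90% of the source mask
        from smv.image_synth import rasterize_ground_truth

        mask = vg.synthetic_vessel_template(96, 96, n_trees=2, radius_range=(2.5, 5), rng_seed=4)
        g = vg.orient_graph(vg.build_undirected_graph(vg.skeletonize_mask(mask)))
        for e in g.edges:
            e.v_ref = 1.0
        vm = rasterize_ground_truth(g)
        covered = (vm.magnitude > 0) & mask.grid
        assert covered.sum() / mask.grid.sum() >= 0.90


# ------------------------------------------------------------- serialization


def test_graph_round_trip(tmp_path, tube):
    tube.edges[0].v_ref = 2.5
    gml = tmp_path / "g.graphml"
    sidecar = tmp_path / "g.json"
    vg.save_graph(tube, str(gml), str(sidecar))
    g2 = vg.load_graph(str(sidecar))
    assert g2.directed
    assert len(g2.edges) == 1
    e0, e1 = tube.edges[0], g2.edges[0]
    assert np.array_equal(e0.path, e1.path)
    assert np.allclose(e0.radii, e1.radii)
    assert e1.v_ref == 2.5
    assert gml.exists()
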