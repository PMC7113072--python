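"""Geometry oracles and the 77-statistic feature ledger."""

import numpy as np
import pytest

from histocompress import (FAMILY_COUNTS, FEATURE_FAMILIES, FEATURE_NAMES,
                           FeatureTable, compute_feature_table, graph_measures,
                           label_objects, nuclear_measures, stability_matrix,
                           subgraph_measures, summarize)
from histocompress.errors import DegenerateGeometryError, ParameterError


def lattice(n, spacing=1.0):
    yy, xx = np.mgrid[:n, :n]
    return np.column_stack([yy.ravel() * spacing, xx.ravel() * spacing])


class TestLabelObjects:
    def test_empty_mask(self):
        labels, cents = label_objects(np.zeros((10, 10), bool))
        assert labels.max() == 0 and len(cents) == 0

    def test_two_disjoint_squares(self):
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        labels, cents = label_objects(mask)
        assert labels.max() == 2
        np.testing.assert_allclose(sorted(map(tuple, cents)), [(2, 2), (7, 7)])

    def test_diagonal_touch_is_one_object(self):
        mask = np.zeros((6, 6), bool)
        mask[1:3, 1:3] = True
        mask[3:5, 3:5] = True  # touches (2,2)-(3,3) diagonally
        labels, _ = label_objects(mask)
        assert labels.max() == 1

    def test_min_area_filter(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True          # area 1
        mask[5:8, 5:8] = True      # area 9
        labels, cents = label_objects(mask, min_area=5)
        assert labels.max() == 1 and len(cents) == 1


class TestGraphMeasures:
    def test_unit_lattice_interior_voronoi_areas(self):
        """On a 5x5 unit lattice the 9 interior Voronoi cells are unit
        squares; edge cells clipped to bounds have area 0.5, corners 0.25."""
        pts = lattice(5)
        gm, skipped = graph_measures(pts, bounds=(4.0, 4.0))
        assert not skipped
        areas = np.sort(gm["voronoi"]["area"])
        assert len(areas) == 25
        np.testing.assert_allclose(areas[:4], 0.25, atol=1e-9)
        np.testing.assert_allclose(areas[4:16], 0.5, atol=1e-9)
        np.testing.assert_allclose(areas[16:], 1.0, atol=1e-9)

    def test_mst_has_n_minus_1_edges(self):
        rng = np.random.default_rng(2)
        for n in (2, 5, 17, 60):
            pts = rng.uniform(0, 100, (n, 2))
            gm, _ = graph_measures(pts, bounds=(100, 100))
            assert len(gm["mst"]["edge_length"]) == n - 1

    def test_collinear_triple_mst(self):
        """Points at x = 0, 1, 3 on a line: MST edges {1, 2}, mean 1.5;
        Voronoi/Delaunay are degenerate and skipped."""
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 3.0]])
        gm, skipped = graph_measures(pts, bounds=(4, 4))
        np.testing.assert_allclose(sorted(gm["mst"]["edge_length"]), [1.0, 2.0],
                                   atol=1e-9)
        assert "voronoi" in skipped and "delaunay" in skipped

    def test_scale_covariance(self):
        """Doubling coordinates doubles MST mean edge length and
        quadruples mean Voronoi cell area."""
        pts = lattice(6, spacing=2.0)
        g1, _ = graph_measures(pts, bounds=(10.0, 10.0))
        g2, _ = graph_measures(pts * 2.0, bounds=(20.0, 20.0))
        assert np.mean(g2["mst"]["edge_length"]) == pytest.approx(
            2.0 * np.mean(g1["mst"]["edge_length"]))
        assert np.mean(g2["voronoi"]["area"]) == pytest.approx(
            4.0 * np.mean(g1["voronoi"]["area"]))

    def test_single_point_raises(self):
        with pytest.raises(DegenerateGeometryError):
            graph_measures(np.array([[1.0, 1.0]]), bounds=(4, 4))


class TestNuclearMeasures:
    def test_disk_compact_and_circular(self):
        mask = np.zeros((40, 40), bool)
        yy, xx = np.mgrid[:40, :40]
        mask[(yy - 20) ** 2 + (xx - 20) ** 2 <= 100] = True
        labels, cents = label_objects(mask)
        nm = nuclear_measures(labels, cents)
        assert nm["eccentricity"][0] < 0.1
        assert nm["compactness"][0] > 0.85

    def test_elongated_rectangle_more_eccentric(self):
        mask = np.zeros((30, 30), np.int32)
        mask[2:4, 2:12] = 1    # 10 x 2
        mask[10:14, 2:7] = 2   # 5 x 4
        nm = nuclear_measures(mask, np.array([[2.5, 6.5], [11.5, 4.0]]))
        assert nm["eccentricity"][0] > nm["eccentricity"][1]

    def test_two_objects_symmetric_nn(self):
        mask = np.zeros((20, 20), np.int32)
        mask[2:5, 2:5] = 1
        mask[10:13, 10:13] = 2
        labels, cents = label_objects(mask > 0)
        nm = nuclear_measures(labels, cents)
        d = nm["knn_1"]
        assert d[0] == pytest.approx(d[1])
        assert nm["knn_3"] == []  # only 2 objects: 3-NN missing


class TestSubgraphMeasures:
    def test_all_far_apart_no_clusters(self):
        pts = np.array([[0, 0], [0, 50], [50, 0], [50, 50]], float)
        sg = subgraph_measures(pts, link_radius=10.0)
        assert sg["cluster_count"] == 0.0
        assert sg["nodes"] == []

    def test_square_forms_complete_graph(self):
        """4 nodes within a 10-px square, link radius 15: one cluster with
        all 6 edges and average degree 3."""
        pts = np.array([[0, 0], [0, 10], [10, 0], [10, 10]], float)
        sg = subgraph_measures(pts, link_radius=15.0)
        assert sg["cluster_count"] == 1.0
        assert sg["nodes"] == [4.0]
        assert sg["edges"] == [6.0]
        assert sg["degree"] == [3.0]
        assert sg["hull_area"] == [pytest.approx(100.0)]

    def test_two_triads(self):
        tri = np.array([[0, 0], [0, 5], [5, 0]], float)
        pts = np.vstack([tri, tri + 100.0])
        sg = subgraph_measures(pts, link_radius=20.0)
        assert sg["cluster_count"] == 2.0
        assert sg["nodes"] == [3.0, 3.0]
        assert sg["clustered_fraction"] == 1.0
        d = np.hypot(100, 95)  # closest pair: (0,5) <-> (100,100)
        assert sg["intercluster_distance"] == [pytest.approx(d), pytest.approx(d)]


class TestSummarize:
    def test_constant_list(self):
        s = summarize([2, 2, 2])
        assert s["std"] == 0.0
        assert s["disorder"] == 0.0
        assert s["minmax"] == 1.0

    def test_two_point_closed_form(self):
        """{1,3}: mu=2, population sigma=1, disorder = 1 - 1/1.5 = 1/3."""
        s = summarize([1, 3])
        assert s["mean"] == 2.0
        assert s["std"] == 1.0
        assert s["disorder"] == pytest.approx(1 / 3)
        assert s["minmax"] == pytest.approx(1 / 3)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        v = rng.random(20)
        a, b = summarize(v), summarize(v[::-1])
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_empty_gives_missing(self):
        assert all(np.isnan(x) for x in summarize([]).values())

    def test_zero_mean_disorder_missing(self):
        assert np.isnan(summarize([-1, 1])["disorder"])


class TestLedger:
    def test_exactly_77_features_partitioned_by_family(self):
        assert len(FEATURE_NAMES) == 77
        counts = {f: FEATURE_FAMILIES.count(f) for f in FAMILY_COUNTS}
        assert counts == {"voronoi": 12, "delaunay": 8, "mst": 4,
                          "nuclear": 27, "subgraph": 26}
        assert len(set(FEATURE_NAMES)) == 77

    def test_feature_table_from_segmentation(self):
        from histocompress import SceneParams, generate_scene
        s = generate_scene(SceneParams(seed=4))
        labels, cents = label_objects(s.label_mask > 0, min_area=5)
        t = compute_feature_table(labels, cents, link_radius=20.0)
        assert t.names == FEATURE_NAMES
        assert len(t.values) == 77
        # a dense scene populates every family's core statistics
        for fam in FAMILY_COUNTS:
            idx = [i for i, f in enumerate(t.families) if f == fam]
            assert np.isfinite(t.values[idx]).sum() > 0

    def test_degenerate_segmentation_gives_missing_not_error(self):
        t = compute_feature_table(np.zeros((32, 32), np.int32),
                                  np.empty((0, 2)), link_radius=10.0)
        assert len(t.values) == 77


def _table(values):
    return FeatureTable(names=("a", "b"), families=("mst", "subgraph"),
                        values=np.asarray(values, float))


class TestStabilityMatrix:
    def test_identical_tables_all_zero(self):
        tabs = {lv: [_table([1.0, 2.0])] for lv in (100.0, 30.0, 20.0)}
        sm = stability_matrix(tabs, lossless_level=100.0)
        assert np.all(sm.rel_diff == 0.0)

    def test_max_normalization(self):
        """Raw diffs {0, 1, 2} across levels normalize to {0, 0.5, 1}."""
        tabs = {100.0: [_table([5.0, 0.0])],
                30.0: [_table([6.0, 0.0])],
                20.0: [_table([7.0, 0.0])]}
        sm = stability_matrix(tabs, lossless_level=100.0)
        col = sm.rel_diff[:, 0]  # levels ascending: 20, 30, 100
        np.testing.assert_allclose(col, [1.0, 0.5, 0.0])
        np.testing.assert_allclose(sm.rel_diff[:, 1], 0.0)  # 0/0 -> 0

    def test_lossless_row_zero_and_columns_peak_at_one(self):
        rng = np.random.default_rng(3)
        tabs = {lv: [_table(rng.normal(0, 5, 2)) for _ in range(4)]
                for lv in (100.0, 40.0, 25.0, 18.0)}
        sm = stability_matrix(tabs, lossless_level=100.0)
        lossless_row = list(sm.levels).index(100.0)
        assert np.all(sm.rel_diff[lossless_row] == 0.0)
        for j in range(sm.rel_diff.shape[1]):
            col = sm.rel_diff[:, j]
            assert np.all((0.0 <= col) & (col <= 1.0))
            if np.any(col > 0):
                assert col.max() == pytest.approx(1.0)

    def test_missing_lossless_level_rejected(self):
        with pytest.raises(ParameterError):
            stability_matrix({30.0: [_table([1, 2])]}, lossless_level=100.0)

    def test_inconsistent_names_rejected(self):
        other = FeatureTable(names=("x", "y"), families=("mst", "mst"),
                             values=np.zeros(2))
        with pytest.raises(ParameterError):
            stability_matrix({100.0: [_table([1, 2])], 30.0: [other]},
                             lossless_level=100.0)
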