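"""The segregation order parameter δ, threshold sweeps and bootstrap null."""

import itertools

import numpy as np
import pytest

from colonymorph import (DEFAULT_THRESHOLDS, NeighborGraph, bootstrap_null,
                         classify_by_threshold, delaunay_graph,
                         segregation_parameter, segregation_profile,
                         threshold_sweep, triangular_lattice)
from colonymorph.segregation import UndefinedStatisticError

from oracles import brute_delta


def path_graph_4():
    """A–A–B–B path: N_c=4, edges AA, AB, BB."""
    pos = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.5]])
    edges = np.array([[0, 1], [1, 2], [2, 3]])
    return NeighborGraph(positions=pos, edges=edges, hull=np.array([0, 3]))


class TestClassifyByThreshold:
    def test_boundary_is_inclusive_on_large_side(self):
        labels = classify_by_threshold([150.0, 200.0, 250.0], 200.0)
        assert list(labels) == ["A", "B", "B"]

    def test_zero_threshold_all_large(self):
        assert set(classify_by_threshold([150.0, 250.0], 0.0)) == {"B"}

    def test_infinite_threshold_all_small(self):
        assert set(classify_by_threshold([150.0, 250.0], np.inf)) == {"A"}


class TestSegregationParameter:
    def test_path_graph_hand_evaluation(self):
        """δ = 1 − 4·1/(1.5·2·2) = 1/3, by hand and by edge enumeration."""
        g = path_graph_4()
        labels = np.array(["A", "A", "B", "B"])
        delta, counts = segregation_parameter(g, labels)
        assert delta == pytest.approx(1.0 / 3.0)
        assert (counts.n_a, counts.n_b, counts.n_ab) == (2, 2, 1)
        assert counts.mean_neighbors == pytest.approx(1.5)
        assert delta == pytest.approx(
            brute_delta(4, [(0, 1), (1, 2), (2, 3)], labels))

    def test_empty_class_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            segregation_parameter(path_graph_4(), np.array(["A"] * 4))

    def test_label_swap_symmetry(self, rng):
        """δ is invariant under exchanging the A and B roles."""
        pts = rng.uniform(0, 100, size=(40, 2))
        g = delaunay_graph(pts)
        labels = np.where(rng.uniform(size=40) < 0.4, "A", "B")
        swapped = np.where(labels == "A", "B", "A")
        d1, _ = segregation_parameter(g, labels)
        d2, _ = segregation_parameter(g, swapped)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_delta_below_one_on_connected_graphs(self, rng):
        pts = rng.uniform(0, 100, size=(60, 2))
        g = delaunay_graph(pts, prune="none")
        for _ in range(20):
            labels = np.where(rng.uniform(size=60) < 0.5, "A", "B")
            if len(set(labels)) < 2:
                continue
            delta, _ = segregation_parameter(g, labels)
            assert delta < 1.0

    def test_exhaustive_small_graphs_match_oracle_and_expectation(self, rng):
        """Over ALL labelings of small Delaunay graphs, δ matches the
        brute-force evaluation, and the mean over valid labelings is
        exactly −1/(N_c−1): at any fixed class split the expected mixed-edge
        count makes E[δ] composition-independent."""
        for n in (5, 8, 10, 12):
            pts = rng.uniform(0, 10, size=(n, 2))
            g = delaunay_graph(pts, prune="none")
            edge_list = [tuple(e) for e in g.edges]
            deltas = []
            for bits in itertools.product("AB", repeat=n):
                labels = np.array(bits)
                if len(set(bits)) < 2:
                    continue
                d, _ = segregation_parameter(g, labels)
                assert d == pytest.approx(
                    brute_delta(n, edge_list, labels), rel=1e-12)
                deltas.append(d)
            assert np.mean(deltas) == pytest.approx(-1.0 / (n - 1), abs=1e-12)

    def test_mixed_lattice_mean_near_zero(self, rng):
        """Random labels on a lattice colony: δ averages to ≈0."""
        pts = triangular_lattice(900, 1.0)
        g = delaunay_graph(pts)
        deltas = []
        for _ in range(50):
            labels = np.where(rng.uniform(size=900) < 0.5, "A", "B")
            d, _ = segregation_parameter(g, labels)
            deltas.append(d)
        assert abs(np.mean(deltas)) < 0.01

    def test_compact_cluster_strongly_segregated(self):
        from colonymorph import compact_disk_labels
        pts = triangular_lattice(2000, 1.0)
        g = delaunay_graph(pts)
        delta, _ = segregation_parameter(g, compact_disk_labels(pts, 200))
        assert delta > 0.8


class TestThresholdSweep:
    def test_default_grid_has_ten_points(self, mixed_colony, mixed_graph):
        colony, _ = mixed_colony
        prof = threshold_sweep(colony, mixed_graph)
        assert len(prof.thresholds) == 10
        assert prof.thresholds[0] == 100.0 and prof.thresholds[-1] == 325.0

    def test_unsplit_thresholds_are_missing(self, mixed_colony, mixed_graph):
        colony, _ = mixed_colony
        lo = colony.areas.min()
        prof = threshold_sweep(colony, mixed_graph, [lo / 4, lo / 2])
        assert np.isnan(prof.delta).all()
        assert (prof.n_a == 0).all()

    def test_counts_partition_the_colony(self, mixed_colony, mixed_graph):
        colony, _ = mixed_colony
        prof = threshold_sweep(colony, mixed_graph)
        assert np.all(prof.n_a + prof.n_b == colony.n_cells)
        assert np.all(prof.n_ab <= mixed_graph.n_edges)


class TestBootstrapNull:
    def test_reproducible_for_fixed_seed(self, mixed_colony, mixed_graph):
        colony, _ = mixed_colony
        a = bootstrap_null(colony, mixed_graph, n_boot=150, seed=5)
        b = bootstrap_null(colony, mixed_graph, n_boot=150, seed=5)
        for key in a:
            assert np.array_equal(a[key], b[key], equal_nan=True)

    def test_null_median_near_zero(self, mixed_colony, mixed_graph):
        """Permuting areas destroys any spatial structure, so the null δ
        is centred on the mixed-limit value ≈ 0."""
        colony, _ = mixed_colony
        null = bootstrap_null(colony, mixed_graph, n_boot=300, seed=1)
        mid = slice(2, 8)  # thresholds where both classes are populous
        assert np.all(np.abs(null["median"][mid]) < 0.02)

    def test_mixed_colony_within_band(self, mixed_colony, mixed_graph):
        """A colony with randomly placed sizes stays inside its own 95%
        null band at most thresholds."""
        colony, _ = mixed_colony
        prof = segregation_profile(colony, mixed_graph, n_boot=300, seed=2)
        ok = np.isfinite(prof.delta)
        inside = ((prof.delta[ok] >= prof.null_low[ok])
                  & (prof.delta[ok] <= prof.null_high[ok]))
        assert inside.mean() >= 0.8

    def test_clustered_colony_exceeds_band_at_small_thresholds(
            self, clustered_colony, clustered_graph):
        """Spatially clustered small cells push δ above the null band for
        thresholds at or below the median area."""
        colony, _ = clustered_colony
        prof = segregation_profile(colony, clustered_graph, n_boot=300,
                                   seed=3)
        med = np.median(colony.areas)
        at_small = prof.thresholds <= med
        assert np.all(prof.delta[at_small] > prof.null_high[at_small])

    def test_resample_mode_also_centred(self, mixed_colony, mixed_graph):
        colony, _ = mixed_colony
        null = bootstrap_null(colony, mixed_graph, n_boot=150, seed=9,
                              mode="resample")
        assert np.nanmax(np.abs(null["median"])) < 0.1

    def test_requires_enough_replicates(self, mixed_colony, mixed_graph):
        colony, _ = mixed_colony
        with pytest.raises(ValueError):
            bootstrap_null(colony, mixed_graph, n_boot=10, seed=0)
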