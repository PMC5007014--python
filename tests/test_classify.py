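import math

import networkx as nx
import numpy as np
import pytest

from brides import (
    AlgoParams,
    PathClass,
    STRATEGIES,
    brides,
    brides_ec,
    brides_y,
    brides_yc,
    build_candidate_list,
    classify_statuses,
    dijkstra_sssp,
    oracle_classify,
    validate_augmentation,
)

from conftest import F1_COUNTS, F1_LABELS, graph_from_edges, small_random_instance

INF = math.inf


class TestClassifyStatuses:
    @pytest.mark.parametrize(
        "d_x, d_y, expected",
        [
            (INF, 2, PathClass.BREAKTHROUGH),
            (2, INF, PathClass.ROADBLOCK),
            (INF, INF, PathClass.IMPASSE),
            (2, 3, PathClass.DETOUR),
            (3, 2, PathClass.SHORTCUT),
            (2, 2, PathClass.EQUAL),
            (0, 0, PathClass.EQUAL),
        ],
    )
    def test_table_mapping(self, d_x, d_y, expected):
        assert classify_statuses(d_x, d_y) is expected

    def test_tolerance_governs_equality(self):
        assert classify_statuses(1.0, 1.0 + 1e-12) is PathClass.EQUAL
        assert classify_statuses(1.0, 1.1, tol=1e-9) is PathClass.DETOUR
        assert classify_statuses(1.0, 1.1, tol=0.2) is PathClass.EQUAL


class TestCandidateList:
    def _dists(self, f1_pair, i, j):
        Y = f1_pair.augmented
        di, _ = dijkstra_sssp(Y, i)
        dj, _ = dijkstra_sssp(Y, j)
        return di, dj

    def test_f1_pair_1_4_strategy1(self, f1_pair):
        di, dj = self._dists(f1_pair, "1", "4")
        cl = build_candidate_list(("1", "4"), f1_pair, di, dj, AlgoParams())
        assert list(cl) == [("9", 1, 1), ("11", 1, 2)]  # node 10 unreachable

    def test_max_node_truncates(self, f1_pair):
        di, dj = self._dists(f1_pair, "1", "4")
        cl = build_candidate_list(
            ("1", "4"), f1_pair, di, dj, AlgoParams(max_node=1)
        )
        assert list(cl) == [("9", 1, 1)]

    def test_max_distance_filters(self, f1_pair):
        di, dj = self._dists(f1_pair, "1", "4")
        cl = build_candidate_list(
            ("1", "4"), f1_pair, di, dj, AlgoParams(max_distance=1)
        )
        assert list(cl) == [("9", 1, 1)]  # 11 excluded: d(11,4)=2

    def test_strategy2_orders_by_sum(self, f1_pair):
        di, dj = self._dists(f1_pair, "2", "3")
        p1 = build_candidate_list(("2", "3"), f1_pair, di, dj, AlgoParams(ordering_strategy=1))
        p2 = build_candidate_list(("2", "3"), f1_pair, di, dj, AlgoParams(ordering_strategy=2))
        # 9: d=(2,2) sum 4; 11: d=(2,1) sum 3 -> strategy 2 puts 11 first
        assert [k for k, *_ in p2] == ["11", "9"]
        assert [k for k, *_ in p1] == ["11", "9"]  # tie on max, sum breaks it


@pytest.mark.parametrize("strategy", sorted(STRATEGIES))
class TestFixtureClassification:
    def test_f1_counts(self, strategy, f1_pair):
        res = STRATEGIES[strategy](f1_pair)
        assert res.counts_row() == F1_COUNTS

    def test_f1_per_pair_labels(self, strategy, f1_pair):
        res = STRATEGIES[strategy](f1_pair)
        for rec in res.records:
            expected = F1_LABELS.get(rec.pair, "IMPASSE")
            assert rec.label.name == expected, rec.pair


class TestDegenerateInputs:
    def test_no_added_nodes_yields_only_roadblocks_and_impasses(self, recwarn):
        X = graph_from_edges([(1, 2)], nodes=[3])
        ap = validate_augmentation(X, X.copy())
        for fn in STRATEGIES.values():
            res = fn(ap)
            labels = {r.pair: r.label for r in res.records}
            assert labels[(1, 2)] is PathClass.ROADBLOCK
            assert labels[(1, 3)] is PathClass.IMPASSE
            assert labels[(2, 3)] is PathClass.IMPASSE

    def test_breakthrough_when_only_connection_is_added(self):
        X = graph_from_edges([], nodes=[2, 12])
        Y = graph_from_edges([(2, 15), (15, 12)])
        ap = validate_augmentation(X, Y)
        res = brides(ap)
        assert res.records[0].label is PathClass.BREAKTHROUGH


class TestBridesYFailureMode:
    """With max_path_number=1 only the single shortest path is inspected."""

    def _instance(self):
        X = graph_from_edges([(1, 2)])
        Y = graph_from_edges([(1, 2), (1, 3), (3, 2)])
        return validate_augmentation(X, Y)

    def test_truncation_misclassifies_detour_as_roadblock(self):
        ap = self._instance()
        res = brides_y(ap, AlgoParams(max_path_number=1))
        assert res.records[0].label is PathClass.ROADBLOCK
        truth = oracle_classify(ap, engine="dfs")
        assert truth.records[0].label is PathClass.DETOUR

    def test_larger_cap_recovers_truth(self):
        ap = self._instance()
        res = brides_y(ap, AlgoParams(max_path_number=10))
        assert res.records[0].label is PathClass.DETOUR


class TestBridesYcSecondYenPath:
    """The first Yen i->k path collides with j; the second one concatenates."""

    def _instance(self):
        X = graph_from_edges([(1, 4)], nodes=[3, 5])
        Y = graph_from_edges([(1, 4), (4, 9), (1, 3), (3, 5), (5, 9)])
        return validate_augmentation(X, Y)

    def test_witness_uses_longer_stored_path(self):
        ap = self._instance()
        res = brides_yc(ap)
        rec = {r.pair: r for r in res.records}[(1, 4)]
        assert rec.label is PathClass.DETOUR
        assert rec.witness.nodes == (1, 3, 5, 9, 4)
        assert rec.d_y_constrained == 4
        truth = oracle_classify(ap, engine="dfs")
        assert {r.pair: r.label for r in truth.records}[(1, 4)] is PathClass.DETOUR


class TestExhaustiveConcatenation:
    def _instance(self):
        """First candidate's witness is length 5, a later one's is 3; d_X = 4."""
        X = graph_from_edges(
            [(1, 3), (3, 4), (4, 5), (5, 2), (2, 6), (6, 7), (7, 8), (1, 9)]
        )
        Y = graph_from_edges(
            [(1, 3), (3, 4), (4, 5), (5, 2), (2, 6), (6, 7), (7, 8), (1, 9),
             (1, 2), (1, 10), (8, 10), (2, 11), (9, 11)]
        )
        return validate_augmentation(X, Y)

    def test_first_witness_vs_shortest_witness(self):
        ap = self._instance()
        rec_b = {r.pair: r for r in brides(ap).records}[(1, 2)]
        rec_ec = {r.pair: r for r in brides_ec(ap).records}[(1, 2)]
        assert rec_b.d_x == 4
        assert rec_b.d_y_constrained == 5
        assert rec_b.label is PathClass.DETOUR
        assert rec_ec.d_y_constrained == 3
        assert rec_ec.label is PathClass.SHORTCUT
        truth = {r.pair: r for r in oracle_classify(ap, engine="dfs").records}[(1, 2)]
        assert truth.label is PathClass.SHORTCUT

    @pytest.mark.parametrize("seed", range(20))
    def test_ec_witness_never_longer_than_brides(self, seed):
        ap = small_random_instance(seed)
        by_pair_b = {r.pair: r for r in brides(ap).records}
        for rec in brides_ec(ap).records:
            assert rec.d_y_constrained <= by_pair_b[rec.pair].d_y_constrained + 1e-9


class TestResultInvariants:
    @pytest.mark.parametrize("strategy", sorted(STRATEGIES))
    @pytest.mark.parametrize("seed", [0, 7])
    def test_counts_sum_and_witness_validity(self, strategy, seed):
        ap = small_random_instance(seed)
        res = STRATEGIES[strategy](ap)
        assert sum(res.counts.values()) == ap.n_pairs
        Y, added = ap.augmented, ap.added
        for rec in res.records:
            if rec.witness is None:
                continue
            w = rec.witness
            assert w.is_simple()
            assert any(v in added for v in w.nodes)
            assert {w.source, w.target} == set(rec.pair)
            for u, v in zip(w.nodes, w.nodes[1:]):
                assert Y.has_edge(u, v)

    @pytest.mark.parametrize("strategy", sorted(STRATEGIES))
    def test_relabeling_preserves_counts(self, strategy, f1_pair):
        mapping = {v: f"g{int(v) * 7 % 23}" for v in f1_pair.augmented.nodes}
        X2 = nx.relabel_nodes(f1_pair.original, mapping)
        Y2 = nx.relabel_nodes(f1_pair.augmented, mapping)
        ap2 = validate_augmentation(X2, Y2)
        res = STRATEGIES[strategy](ap2)
        assert res.counts_row() == F1_COUNTS

    def test_heuristic_distance_upper_bounds_exact(self):
        for seed in range(10):
            ap = small_random_instance(seed)
            exact = {r.pair: r.d_y_constrained for r in oracle_classify(ap, "flow").records}
            for rec in brides(ap).records:
                assert rec.d_y_constrained >= exact[rec.pair] - 1e-9

    def test_pairs_subset_restricts_output(self, f1_pair):
        sub = [("1", "4"), ("5", "6")]
        res = brides(f1_pair, pairs=sub)
        assert [r.pair for r in res.records] == sub
        assert sum(res.counts.values()) == 2
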