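"""Max-flow introspection: OR/AND ranges, labels, block graph, witnesses."""

import networkx as nx
import pytest

from quantrange.core_graph import EdgeSetQuery, SpliceGraph, path_to_query
from quantrange.fixtures import (
    and_predicate,
    enumerate_st_paths,
    oracle_flow_range,
    or_predicate,
    random_or_query,
    random_well_ordered_query,
)
from quantrange.subgraph_quant import (
    WellOrderingError,
    and_quant,
    build_block_graph,
    build_g_minus,
    build_g_plus,
    check_well_ordering,
    compute_reach_labels,
    decompose_flow,
    filter_edge_sets,
    max_flow,
    or_quant,
    prune_to_core,
    transcript_range_graph,
    witness_decomposition,
)

W_AND = EdgeSetQuery([{"S-A"}, {"M-C"}])


class TestMaxFlow:
    def test_single_path(self):
        g = SpliceGraph()
        g.add_edge("SA", "S", "A")
        g.add_edge("AT", "A", "T")
        value, flows = max_flow(g, {"SA": 5.0, "AT": 5.0})
        assert value == pytest.approx(5.0)
        assert flows["SA"] == pytest.approx(5.0)

    def test_parallel_paths_sum(self):
        g = SpliceGraph()
        g.add_edge("SA", "S", "A")
        g.add_edge("AT", "A", "T")
        g.add_edge("SB", "S", "B")
        g.add_edge("BT", "B", "T")
        value, _ = max_flow(g, {"SA": 3, "AT": 3, "SB": 7, "BT": 7})
        assert value == pytest.approx(10.0)

    def test_unreachable_sink_is_zero(self):
        g = SpliceGraph()
        g.add_edge("SA", "S", "A")
        g.add_vertex("T")
        value, _ = max_flow(g, {"SA": 5.0})
        assert value == 0.0


class TestAuxGraphs:
    def test_g_minus_identity_when_empty(self, w_graph):
        g = build_g_minus(w_graph.graph, set())
        assert g.edges == w_graph.graph.edges

    def test_g_minus_removes_s_outflow(self, w_graph):
        g = build_g_minus(w_graph.graph, {"S-A", "S-B"})
        value, _ = max_flow(g, w_graph.flow)
        assert value == 0.0

    def test_g_minus_w_example(self, w_graph):
        g = build_g_minus(w_graph.graph, {"S-A", "M-C"})
        value, _ = max_flow(g, w_graph.flow)
        assert value == pytest.approx(6.0)

    def test_g_plus_empty_query_unreachable(self, w_graph):
        g = build_g_plus(w_graph.graph, set())
        value, _ = max_flow(g, w_graph.flow)
        assert value == 0.0

    def test_g_plus_only_sink_edge(self):
        g = SpliceGraph()
        g.add_edge("SA", "S", "A")
        g.add_edge("AT", "A", "T")
        gp = build_g_plus(g, {"AT"})
        value, _ = max_flow(gp, {"SA": 5, "AT": 5})
        assert value == pytest.approx(5.0)
        assert gp.label("AT") == "T"  # origin label preserved

    def test_g_plus_w_example(self, w_graph):
        gp = build_g_plus(w_graph.graph, {"S-A", "M-C"})
        value, _ = max_flow(gp, w_graph.flow)
        assert value == pytest.approx(7.0)


class TestWellOrdering:
    def test_singletons_along_a_path_ok(self, w_graph):
        q = path_to_query(w_graph.graph, ("S-A", "A-M", "M-C", "C-T"))
        assert check_well_ordering(w_graph.graph, q) is None

    def test_reversed_sets_violate(self, w_graph):
        violation = check_well_ordering(
            w_graph.graph, EdgeSetQuery([{"M-C"}, {"S-A"}])
        )
        assert violation is not None
        assert (violation.i, violation.j) == (2, 1)
        assert violation.path[0] == "S" and violation.path[-1] == "T"

    def test_two_same_set_edges_on_one_path_violate(self, w_graph):
        violation = check_well_ordering(
            w_graph.graph, EdgeSetQuery([{"S-A", "M-C"}])
        )
        assert violation is not None
        assert (violation.i, violation.j) == (1, 1)

    def test_incomparable_same_set_edges_ok(self, w_graph):
        assert (
            check_well_ordering(w_graph.graph, EdgeSetQuery([{"M-C", "M-D"}]))
            is None
        )

    def test_and_quant_refuses_violations(self, w_graph):
        with pytest.raises(WellOrderingError):
            and_quant(
                w_graph.graph, w_graph.flow, EdgeSetQuery([{"M-C"}, {"S-A"}])
            )


class TestReachLabels:
    def test_w_graph_forward_labels(self, w_graph):
        core, _ = prune_to_core(w_graph.graph)
        labels = compute_reach_labels(core, W_AND)
        assert labels.s == {
            "S": 0, "A": 1, "B": 0, "M": 1, "C": 2, "D": 1, "T": 2,
        }

    def test_w_graph_backward_labels(self, w_graph):
        core, _ = prune_to_core(w_graph.graph)
        labels = compute_reach_labels(core, W_AND)
        assert labels.t == {
            "T": 3, "D": 3, "C": 3, "M": 2, "A": 2, "B": 2, "S": 1,
        }

    def test_empty_query_labels(self, w_graph):
        core, _ = prune_to_core(w_graph.graph)
        labels = compute_reach_labels(core, EdgeSetQuery([]))
        assert set(labels.s.values()) == {0}
        assert set(labels.t.values()) == {1}

    def test_labels_match_bruteforce_definition(self, battery):
        # s(v): largest i such that some S->v path hits E_1..E_i in order
        for f in battery[:60]:
            q = random_well_ordered_query(f, seed=f.seed + 2000)
            core, _ = prune_to_core(f.graph)
            reduced = EdgeSetQuery(
                [{e for e in es if core.has_edge(e)} for es in q.sets]
            )
            if any(not es for es in reduced.sets):
                continue
            labels = compute_reach_labels(core, reduced)
            paths = enumerate_st_paths(core)
            verts = set(core.vertices)
            best_s = {v: 0 for v in verts}
            best_t = {v: reduced.m + 1 for v in verts}
            for p in paths:
                seen: list[str] = []
                level = 0
                best_s["S"] = max(best_s["S"], 0)
                for eid in p:
                    for j in range(level + 1, reduced.m + 1):
                        if eid in reduced.sets[j - 1] and level == j - 1:
                            level = j
                            break
                    best_s[core.head(eid)] = max(best_s[core.head(eid)], level)
                level = reduced.m + 1
                for eid in reversed(p):
                    for j in range(reduced.m, 0, -1):
                        if eid in reduced.sets[j - 1] and level == j + 1:
                            level = j
                            break
                    best_t[core.tail(eid)] = min(best_t[core.tail(eid)], level)
            assert labels.s == best_s
            assert labels.t == best_t


class TestFilterAndBlockGraph:
    def test_w_query_edges_survive_filtering(self, w_graph):
        core, _ = prune_to_core(w_graph.graph)
        labels = compute_reach_labels(core, W_AND)
        filtered = filter_edge_sets(core, W_AND, labels)
        assert [set(s) for s in filtered.sets] == [{"S-A"}, {"M-C"}]

    def test_out_of_position_edge_dropped(self, w_graph):
        # extra branch S->X->C: X-C reaches the sink but no path through it
        # can have visited E_1 first, so the filter must drop it from E_2
        g = w_graph.graph.copy()
        g.add_edge("S-X", "S", "X")
        g.add_edge("X-C", "X", "C")
        core, _ = prune_to_core(g)
        q = EdgeSetQuery([{"S-A"}, {"M-C", "X-C"}])
        assert check_well_ordering(core, q) is None
        labels = compute_reach_labels(core, q)
        filtered = filter_edge_sets(core, q, labels)
        assert set(filtered.sets[1]) == {"M-C"}  # s(X)=0 != 1, X-C dropped

    def test_w_graph_block_graph(self, w_graph):
        core, _ = prune_to_core(w_graph.graph)
        labels = compute_reach_labels(core, W_AND)
        filtered = filter_edge_sets(core, W_AND, labels)
        gb = build_block_graph(core, filtered, labels)
        assert set(gb.edge_ids) == {"S-A", "A-M", "M-C", "C-T"}

    def test_empty_query_block_graph_is_whole_core(self, w_graph):
        core, _ = prune_to_core(w_graph.graph)
        q = EdgeSetQuery([])
        labels = compute_reach_labels(core, q)
        gb = build_block_graph(core, filter_edge_sets(core, q, labels), labels)
        assert set(gb.edge_ids) == set(core.edge_ids)

    def test_block_graph_equals_union_of_good_paths(self, battery):
        for f in battery:
            q = random_well_ordered_query(f, seed=f.seed + 2000)
            core, _ = prune_to_core(f.graph)
            reduced = EdgeSetQuery(
                [{e for e in es if core.has_edge(e)} for es in q.sets]
            )
            if any(not es for es in reduced.sets):
                continue
            labels = compute_reach_labels(core, reduced)
            filtered = filter_edge_sets(core, reduced, labels)
            good = [
                p
                for p in enumerate_st_paths(core)
                if all(set(p) & es for es in reduced.sets)
            ]
            union = set().union(*(set(p) for p in good)) if good else set()
            if any(not es for es in filtered.sets):
                assert not good
                continue
            gb = build_block_graph(core, filtered, labels)
            assert set(gb.edge_ids) == union

    def test_block_graph_matches_reachability_definition(self, battery):
        # Definition via start/end sets: a non-query edge (u, v) is a block
        # edge of level j iff some head of E_{j-1} reaches u and v reaches
        # some tail of E_j.
        for f in battery:
            q = random_well_ordered_query(f, seed=f.seed + 2000)
            core, _ = prune_to_core(f.graph)
            reduced = EdgeSetQuery(
                [{e for e in es if core.has_edge(e)} for es in q.sets]
            )
            if any(not es for es in reduced.sets):
                continue
            labels = compute_reach_labels(core, reduced)
            filtered = filter_edge_sets(core, reduced, labels)
            if any(not es for es in filtered.sets):
                continue
            gb = build_block_graph(core, filtered, labels)
            g = core.to_networkx()
            reach = {v: nx.descendants(g, v) | {v} for v in g.nodes}
            v_sets = {0: {core.source}}
            u_sets = {}
            for i, es in enumerate(filtered.sets, 1):
                u_sets[i] = {core.tail(e) for e in es}
                v_sets[i] = {core.head(e) for e in es}
            u_sets[filtered.m + 1] = {core.sink}
            query_edges = filtered.all_edges()
            expected = set(query_edges)
            for eid in core.edge_ids:
                if eid in query_edges:
                    continue
                u, v = core.endpoints(eid)
                for j in range(1, filtered.m + 2):
                    if any(u in reach[x] for x in v_sets[j - 1]) and any(
                        y in reach[v] for y in u_sets[j]
                    ):
                        expected.add(eid)
                        break
            assert set(gb.edge_ids) == expected


class TestOrQuant:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ({"M-C"}, (3, 3)),
            ({"S-A", "M-C"}, (4, 7)),
            (set(), (0, 0)),
        ],
    )
    def test_w_graph_examples(self, w_graph, edges, expected):
        rng = or_quant(w_graph.graph, w_graph.flow, edges)
        assert (rng.lo, rng.hi) == pytest.approx(expected, abs=1e-6)

    def test_all_edges_means_all_flow(self, w_graph):
        rng = or_quant(w_graph.graph, w_graph.flow, set(w_graph.graph.edge_ids))
        assert (rng.lo, rng.hi) == pytest.approx((10, 10), abs=1e-6)

    def test_matches_oracle_on_battery(self, battery):
        for f in battery:
            edges = random_or_query(f, seed=f.seed + 1000)
            got = or_quant(f.graph, f.flow, edges)
            exp = oracle_flow_range(f.graph, f.flow, or_predicate(edges))
            assert got.lo == pytest.approx(exp.lo, abs=1e-6)
            assert got.hi == pytest.approx(exp.hi, abs=1e-6)

    def test_bounds_within_total(self, battery):
        for f in battery[:60]:
            edges = random_or_query(f, seed=f.seed + 5000)
            rng = or_quant(f.graph, f.flow, edges)
            assert -1e-9 <= rng.lo <= rng.hi <= f.total + 1e-6


class TestAndQuant:
    def test_w_graph_two_level_query(self, w_graph):
        rng = and_quant(w_graph.graph, w_graph.flow, W_AND)
        assert (rng.lo, rng.hi) == pytest.approx((0, 3), abs=1e-6)

    def test_single_set_equals_edge_flow(self, w_graph):
        rng = and_quant(w_graph.graph, w_graph.flow, EdgeSetQuery([{"S-A"}]))
        assert (rng.lo, rng.hi) == pytest.approx((4, 4), abs=1e-6)

    @pytest.mark.parametrize(
        "path,expected",
        [
            (("S-A", "A-M", "M-C", "C-T"), (0, 3)),
            (("S-B", "B-M", "M-D", "D-T"), (3, 6)),
        ],
    )
    def test_transcript_paths(self, w_graph, path, expected):
        rng = transcript_range_graph(w_graph.graph, w_graph.flow, path)
        assert (rng.lo, rng.hi) == pytest.approx(expected, abs=1e-6)

    def test_single_path_graph_forced(self):
        g = SpliceGraph()
        g.add_edge("SA", "S", "A")
        g.add_edge("AT", "A", "T")
        flow = {"SA": 5.0, "AT": 5.0}
        rng = transcript_range_graph(g, flow, ("SA", "AT"))
        assert (rng.lo, rng.hi) == pytest.approx((5, 5), abs=1e-6)

    def test_infeasible_query_is_zero(self, w_graph):
        # S-B then M-C is a valid ordering but shares no flow constraint
        # problem; a set emptied by filtering instead:
        rng = and_quant(
            w_graph.graph, w_graph.flow, EdgeSetQuery([{"A-M"}, {"M-D"}, {"C-T"}])
        )
        assert (rng.lo, rng.hi) == (0.0, 0.0)

    def test_zero_flow_short_circuits(self, w_graph):
        zero = {e: 0.0 for e in w_graph.graph.edge_ids}
        rng = and_quant(w_graph.graph, zero, W_AND)
        assert (rng.lo, rng.hi) == (0.0, 0.0)

    def test_matches_oracle_on_battery(self, battery):
        for f in battery:
            q = random_well_ordered_query(f, seed=f.seed + 2000)
            got = and_quant(f.graph, f.flow, q)
            exp = oracle_flow_range(f.graph, f.flow, and_predicate(q))
            assert got.lo == pytest.approx(exp.lo, abs=1e-6)
            assert got.hi == pytest.approx(exp.hi, abs=1e-6)

    def test_complementarity_with_or_quant(self, battery, w_graph):
        # AND answer equals U-complemented OR answer on the block-graph
        # complement, by construction; spot-check structurally.
        core, core_flow = prune_to_core(w_graph.graph, w_graph.flow)
        labels = compute_reach_labels(core, W_AND)
        gb = build_block_graph(core, filter_edge_sets(core, W_AND, labels), labels)
        complement = set(core.edge_ids) - set(gb.edge_ids)
        inner = or_quant(core, core_flow, complement)
        outer = and_quant(w_graph.graph, w_graph.flow, W_AND)
        u = w_graph.total
        assert outer.lo == pytest.approx(u - inner.hi, abs=1e-6)
        assert outer.hi == pytest.approx(u - inner.lo, abs=1e-6)


class TestDecomposeFlow:
    def test_reproduces_edge_flows(self, battery):
        for f in battery[:60]:
            dec = decompose_flow(f.graph, f.flow)
            sums = dec.edge_sums()
            for eid in f.graph.edge_ids:
                assert sums.get(eid, 0.0) == pytest.approx(
                    f.flow.get(eid, 0.0), abs=1e-6 * max(1.0, f.total)
                )

    def test_path_count_bounded_by_edges(self, battery):
        for f in battery[:60]:
            dec = decompose_flow(f.graph, f.flow)
            assert len(dec.paths) <= f.graph.n_edges()


class TestWitnessDecomposition:
    def test_w_graph_max_endpoint(self, w_graph):
        edges = {"S-A", "M-C"}
        dec = witness_decomposition(w_graph.graph, w_graph.flow, edges, "max")
        good = dec.good_flow(lambda p: bool(set(p) & edges))
        assert good == pytest.approx(7.0, abs=1e-6)

    def test_w_graph_min_endpoint(self, w_graph):
        edges = {"S-A", "M-C"}
        dec = witness_decomposition(w_graph.graph, w_graph.flow, edges, "min")
        good = dec.good_flow(lambda p: bool(set(p) & edges))
        assert good == pytest.approx(4.0, abs=1e-6)

    def test_empty_query_any_target(self, w_graph):
        for target in ("min", "max"):
            dec = witness_decomposition(w_graph.graph, w_graph.flow, set(), target)
            assert dec.good_flow(lambda p: False) == 0.0
            sums = dec.edge_sums()
            for eid in w_graph.graph.edge_ids:
                assert sums.get(eid, 0.0) == pytest.approx(
                    w_graph.flow[eid], abs=1e-6
                )

    def test_tightness_on_battery(self, battery):
        for f in battery:
            edges = random_or_query(f, seed=f.seed + 1000)
            rng = or_quant(f.graph, f.flow, edges)
            tol = 1e-6 * max(1.0, f.total)
            for target, endpoint in (("min", rng.lo), ("max", rng.hi)):
                dec = witness_decomposition(f.graph, f.flow, edges, target)
                sums = dec.edge_sums()
                for eid in f.graph.edge_ids:
                    assert sums.get(eid, 0.0) == pytest.approx(
                        f.flow.get(eid, 0.0), abs=tol
                    )
                good = dec.good_flow(lambda p: bool(set(p) & edges))
                assert good == pytest.approx(endpoint, abs=tol)
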