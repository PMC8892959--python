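"""Ranges of optima under the incomplete-reference (splice-graph) model.

Given an optimal edge flow on a splice graph, the abundance of a
transcript (or any splicing pattern) varies across the equally optimal
flow decompositions.  Two query semantics are supported:

* OR semantics: a path is "good" if it uses *any* edge of a set E';
  the attainable total good flow over all decompositions is the interval
  ``[U - MaxFlow(G-), MaxFlow(G+)]`` where G- drops the E' edges and G+
  redirects them into an auxiliary sink.
* AND semantics: a path is good if it uses an edge of *every* set in an
  ordered, well-ordered list {E_k}.  This reduces to the OR problem by
  complementation through the *block graph* G_B, the subgraph containing
  exactly the good S-T paths.

The block graph is built in linear time from per-vertex reach labels
s(v)/t(v) computed by a DP over a topological order.  A constructive
witness routine recovers an explicit decomposition achieving either
endpoint, mirroring the inductive flow-reconstruction argument that
proves the max-flow bound tight.

All capacities are real-valued; endpoints are clamped to [0, U] to
absorb solver noise.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import networkx as nx
from networkx.algorithms.flow import shortest_augmenting_path

from .core_graph import (
    AUX_SINK,
    EPS_LP,
    AbundanceRange,
    Decomposition,
    EdgeSetQuery,
    GraphError,
    SpliceGraph,
    topological_order,
    path_to_query,
    total_flow,
)

__all__ = [
    "WellOrderingViolation",
    "WellOrderingError",
    "ReachLabels",
    "BlockGraph",
    "check_well_ordering",
    "prune_to_core",
    "build_g_minus",
    "build_g_plus",
    "max_flow",
    "or_quant",
    "compute_reach_labels",
    "filter_edge_sets",
    "build_block_graph",
    "and_quant",
    "transcript_range_graph",
    "decompose_flow",
    "witness_decomposition",
]


@dataclass(frozen=True)
class WellOrderingViolation:
    """A path visiting an edge of E_i and later an edge of E_j with i >= j.

    Set indices are 1-based; ``path`` is the witness vertex sequence.
    """

    i: int
    j: int
    path: tuple[str, ...]


class WellOrderingError(GraphError):
    def __init__(self, violation: WellOrderingViolation):
        self.violation = violation
        super().__init__(
            f"query violates well-ordering: a path visits E_{violation.i} "
            f"before E_{violation.j} (witness {' -> '.join(violation.path)})"
        )


@dataclass(frozen=True)
class ReachLabels:
    """Per-vertex query-progress labels.

    ``s[v]`` is the largest i such that some path from S reaches v using
    an edge of each E_1..E_i in order; ``t[v]`` is the smallest i such
    that some path from v reaches T using an edge of each E_i..E_m.
    """

    s: dict[str, int]
    t: dict[str, int]
    m: int


@dataclass(frozen=True)
class BlockGraph:
    """Subgraph containing exactly the good S-T paths.

    ``edge_ids`` is the union of the (filtered) query edges and the
    block edges; ``blocks[i]`` holds the block edges allocated between
    levels i-1 and i (1-based, up to m+1).
    """

    edge_ids: frozenset[str]
    blocks: dict[int, frozenset[str]]


# ---------------------------------------------------------------------
# pruning and well-ordering
# ---------------------------------------------------------------------

def prune_to_core(
    graph: SpliceGraph, flow: Mapping[str, float] | None = None
) -> tuple[SpliceGraph, dict[str, float]]:
    """Restrict to edges lying on at least one S-T path.

    Two breadth-first searches (from S forward, from T backward) mark
    the usable vertices; an edge survives iff its tail is reachable from
    S and its head reaches T.  The input graph is never mutated.  Edges
    dropped here carry zero flow in any valid flow on a DAG.
    """
    g = graph.to_networkx()
    from_s = {graph.source}
    if graph.source in g:
        from_s |= nx.descendants(g, graph.source)
    to_t = {graph.sink}
    if graph.sink in g:
        to_t |= nx.ancestors(g, graph.sink)
    core = SpliceGraph(graph.source, graph.sink)
    kept_flow: dict[str, float] = {}
    for eid in graph.edge_ids:
        u, v = graph.endpoints(eid)
        if u in from_s and v in to_t:
            core.add_edge(eid, u, v, graph.label(eid))
            if flow is not None:
                kept_flow[eid] = flow.get(eid, 0.0)
    return core, kept_flow


def _reachability(graph: SpliceGraph) -> dict[str, set[str]]:
    """v -> set of vertices reachable from v (including v)."""
    g = graph.to_networkx()
    return {v: nx.descendants(g, v) | {v} for v in g.nodes}


def check_well_ordering(
    graph: SpliceGraph, query: EdgeSetQuery
) -> WellOrderingViolation | None:
    """Check the well-ordering property; return a witness on failure.

    An ordered pair (a in E_i, b in E_j, i >= j) violates the property
    iff some S-T path uses a strictly before b, i.e. head(a) reaches
    tail(b) within the S-T-connected core of the graph.
    """
    for k, s in enumerate(query.sets, 1):
        for eid in s:
            if not graph.has_edge(eid):
                raise GraphError(f"query set E_{k} references unknown edge {eid!r}")
    core, _ = prune_to_core(graph)
    reach = _reachability(core)
    g = core.to_networkx()
    for i in range(query.m, 0, -1):
        for j in range(1, i + 1):
            for a in sorted(query.sets[i - 1]):
                if not core.has_edge(a):
                    continue
                for b in sorted(query.sets[j - 1]):
                    if a == b or not core.has_edge(b):
                        continue
                    ha, tb = core.head(a), core.tail(b)
                    if tb in reach.get(ha, set()):
                        mid = nx.shortest_path(g, ha, tb)
                        pre = nx.shortest_path(g, core.source, core.tail(a))
                        post = nx.shortest_path(g, core.head(b), core.sink)
                        witness = tuple(pre + mid + post)
                        return WellOrderingViolation(i, j, witness)
    return None


# ---------------------------------------------------------------------
# auxiliary graphs and max-flow
# ---------------------------------------------------------------------

def build_g_minus(graph: SpliceGraph, query_edges: set[str]) -> SpliceGraph:
    """Copy of the graph without the query edges (bad paths live here)."""
    g = graph.copy()
    for eid in sorted(query_edges):
        if g.has_edge(eid):
            g.remove_edge(eid)
    return g


def build_g_plus(graph: SpliceGraph, query_edges: set[str]) -> SpliceGraph:
    """Copy with auxiliary sink: each query edge redirected into T'.

    Each redirected edge keeps its id and remembers its original
    destination in the edge label, so witness construction can map
    truncated paths back onto the input graph.  T' replaces T as the
    sink.
    """
    g = SpliceGraph(graph.source, AUX_SINK)
    for v in graph.vertices:
        g.add_vertex(v)
    g.add_vertex(AUX_SINK)
    for eid in graph.edge_ids:
        u, v = graph.endpoints(eid)
        if eid in query_edges:
            g.add_edge(eid, u, AUX_SINK, label=v)
        else:
            g.add_edge(eid, u, v)
    return g


def _edge_expanded_nx(
    graph: SpliceGraph, capacities: Mapping[str, float]
) -> nx.DiGraph:
    """Vertex graph with one splitter node per edge.

    Keeps parallel edges distinct and yields per-edge-id flows directly
    (flow on the splitter's incoming arc).
    """
    g = nx.DiGraph()
    g.add_nodes_from(sorted(graph.vertices))
    for eid in graph.edge_ids:
        u, v = graph.endpoints(eid)
        cap = max(0.0, capacities.get(eid, 0.0))
        node = ("e", eid)
        g.add_edge(u, node, capacity=cap)
        g.add_edge(node, v, capacity=cap)
    return g


def max_flow(
    graph: SpliceGraph,
    capacities: Mapping[str, float],
    source: str | None = None,
    sink: str | None = None,
) -> tuple[float, dict[str, float]]:
    """Maximum s-t flow with real capacities; returns value and witness.

    Deterministic given the graph's edge insertion order.  An
    unreachable sink yields value 0.
    """
    source = graph.source if source is None else source
    sink = graph.sink if sink is None else sink
    if source == sink:
        return 0.0, {eid: 0.0 for eid in graph.edge_ids}
    g = _edge_expanded_nx(graph, capacities)
    if source not in g or sink not in g or not nx.has_path(g, source, sink):
        return 0.0, {eid: 0.0 for eid in graph.edge_ids}
    value, flow_dict = nx.maximum_flow(
        g, source, sink, flow_func=shortest_augmenting_path
    )
    per_edge = {
        eid: flow_dict[graph.tail(eid)].get(("e", eid), 0.0)
        for eid in graph.edge_ids
    }
    return value, per_edge


def _limited_max_flow(
    graph: SpliceGraph,
    capacities: Mapping[str, float],
    source: str,
    sink: str,
    limit: float,
) -> tuple[float, dict[str, float]]:
    """Max flow from source to sink capped at ``limit`` total."""
    g = _edge_expanded_nx(graph, capacities)
    aux = ("aux_source",)
    g.add_edge(aux, source, capacity=max(0.0, limit))
    if sink not in g or not nx.has_path(g, aux, sink):
        return 0.0, {eid: 0.0 for eid in graph.edge_ids}
    value, flow_dict = nx.maximum_flow(
        g, aux, sink, flow_func=shortest_augmenting_path
    )
    per_edge = {
        eid: flow_dict[graph.tail(eid)].get(("e", eid), 0.0)
        for eid in graph.edge_ids
    }
    return value, per_edge


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


# ---------------------------------------------------------------------
# OR semantics
# ---------------------------------------------------------------------

def or_quant(
    graph: SpliceGraph, flow: Mapping[str, float], query_edges: set[str]
) -> AbundanceRange:
    """Range of total flow on paths intersecting any edge of E'.

    The minimum is ``U - MaxFlow(G-)`` (everything the bad paths cannot
    carry must be good) and the maximum is ``MaxFlow(G+)`` (good-path
    prefixes truncated into the auxiliary sink).
    """
    u = total_flow(graph, flow)
    for eid in query_edges:
        if not graph.has_edge(eid):
            raise GraphError(f"query references unknown edge {eid!r}")
    if u <= EPS_LP:
        return AbundanceRange(0.0, 0.0)
    mf_minus, _ = max_flow(build_g_minus(graph, query_edges), flow)
    mf_plus, _ = max_flow(build_g_plus(graph, query_edges), flow)
    lo = _clamp(u - mf_minus, 0.0, u)
    hi = _clamp(mf_plus, 0.0, u)
    if lo > hi:  # solver noise only; endpoints are provably ordered
        lo = hi = (lo + hi) / 2.0
    return AbundanceRange(lo, hi)


# ---------------------------------------------------------------------
# reach labels, filtering, block graph
# ---------------------------------------------------------------------

def compute_reach_labels(graph: SpliceGraph, query: EdgeSetQuery) -> ReachLabels:
    """Forward/backward DP for query-progress labels.

    Assumes the graph is pruned to its S-T core.  Refuses queries that
    violate well-ordering (labels would be ill-defined).

    The forward pass initializes s(v) as the largest s(u) over
    predecessors, then lets every query edge (u, v) in E_j with
    s(u) = j - 1 advance s(v) to j; the backward pass is symmetric with
    t(T) = m + 1.
    """
    violation = check_well_ordering(graph, query)
    if violation is not None:
        raise WellOrderingError(violation)
    m = query.m
    membership: dict[str, list[int]] = {}
    for k, es in enumerate(query.sets, 1):
        for eid in es:
            membership.setdefault(eid, []).append(k)
    order = topological_order(graph)
    s: dict[str, int] = {graph.source: 0}
    for v in order:
        if v == graph.source:
            continue
        best = 0
        for eid in graph.in_edges(v):
            su = s.get(graph.tail(eid), 0)
            best = max(best, su)
            for j in membership.get(eid, ()):
                if su == j - 1:
                    best = max(best, j)
        s[v] = best
    t: dict[str, int] = {graph.sink: m + 1}
    for v in reversed(order):
        if v == graph.sink:
            continue
        best = m + 1
        for eid in graph.out_edges(v):
            tv = t.get(graph.head(eid), m + 1)
            best = min(best, tv)
            for j in membership.get(eid, ()):
                if tv == j + 1:
                    best = min(best, j)
        t[v] = best
    return ReachLabels(s=s, t=t, m=m)


def filter_edge_sets(
    graph: SpliceGraph, query: EdgeSetQuery, labels: ReachLabels
) -> EdgeSetQuery:
    """Keep (u, v) in E_i iff s(u) = i - 1 and t(v) = i + 1.

    Surviving edges are exactly those on at least one good S-T path;
    dropping the rest provably leaves the AND answer unchanged.  A set
    left empty means no good path exists at all.
    """
    filtered = []
    for i, es in enumerate(query.sets, 1):
        kept = {
            eid
            for eid in es
            if graph.has_edge(eid)
            and labels.s.get(graph.tail(eid)) == i - 1
            and labels.t.get(graph.head(eid)) == i + 1
        }
        filtered.append(kept)
    return EdgeSetQuery(filtered)


def build_block_graph(
    graph: SpliceGraph, filtered_query: EdgeSetQuery, labels: ReachLabels
) -> BlockGraph:
    """Union of the filtered query edges and the block edges.

    A non-query edge (u, v) belongs to block B_k iff s(u) + 1 = t(v) = k:
    it then sits between consecutive query levels k-1 and k on some good
    path.
    """
    query_edges = filtered_query.all_edges()
    blocks: dict[int, set[str]] = {}
    keep = set(query_edges)
    for eid in graph.edge_ids:
        if eid in query_edges:
            continue
        u, v = graph.endpoints(eid)
        su, tv = labels.s.get(u), labels.t.get(v)
        if su is not None and tv is not None and su + 1 == tv:
            blocks.setdefault(tv, set()).add(eid)
            keep.add(eid)
    return BlockGraph(
        edge_ids=frozenset(keep),
        blocks={k: frozenset(v) for k, v in blocks.items()},
    )


# ---------------------------------------------------------------------
# AND semantics
# ---------------------------------------------------------------------

def and_quant(
    graph: SpliceGraph, flow: Mapping[str, float], query: EdgeSetQuery
) -> AbundanceRange:
    """Range of total flow on paths intersecting every query set.

    Builds the block graph G_B, runs the OR problem on its complement
    E - G_B (the bad-path witnesses) and complements the result with the
    total flow U.
    """
    u = total_flow(graph, flow)
    if u <= EPS_LP:
        return AbundanceRange(0.0, 0.0)
    core, core_flow = prune_to_core(graph, flow)
    violation = check_well_ordering(core, query)
    if violation is not None:
        raise WellOrderingError(violation)
    # query edges pruned out of the core lie on no S-T path at all
    reduced = EdgeSetQuery(
        [{e for e in es if core.has_edge(e)} for es in query.sets]
    )
    if any(not es for es in reduced.sets):
        return AbundanceRange(0.0, 0.0)
    labels = compute_reach_labels(core, reduced)
    filtered = filter_edge_sets(core, reduced, labels)
    if any(not es for es in filtered.sets):
        return AbundanceRange(0.0, 0.0)
    gb = build_block_graph(core, filtered, labels)
    complement = set(core.edge_ids) - set(gb.edge_ids)
    inner = or_quant(core, core_flow, complement)
    lo = _clamp(u - inner.hi, 0.0, u)
    hi = _clamp(u - inner.lo, 0.0, u)
    return AbundanceRange(min(lo, hi), max(lo, hi))


def transcript_range_graph(
    graph: SpliceGraph, flow: Mapping[str, float], path: Sequence[str]
) -> AbundanceRange:
    """Abundance range of a full transcript given as an S-T edge path."""
    return and_quant(graph, flow, path_to_query(graph, path))


# ---------------------------------------------------------------------
# flow decomposition and endpoint witnesses
# ---------------------------------------------------------------------

def decompose_flow(
    graph: SpliceGraph,
    flow: Mapping[str, float],
    source: str | None = None,
    sink: str | None = None,
    tol: float | None = None,
) -> Decomposition:
    """Greedy path decomposition of a balanced flow.

    Repeatedly walks from source to sink following the widest remaining
    edge (ascending edge id on ties) and peels off the bottleneck
    weight; each iteration zeroes at least one edge, so at most |E|
    paths are produced.  Residuals below ``tol`` are treated as zero.
    """
    source = graph.source if source is None else source
    sink = graph.sink if sink is None else sink
    rem = {eid: max(0.0, flow.get(eid, 0.0)) for eid in graph.edge_ids}
    scale = max(1.0, sum(rem.get(e, 0.0) for e in graph.out_edges(source)))
    if tol is None:
        tol = 1e-9 * scale
    paths = Decomposition()
    for _ in range(4 * graph.n_edges() + 8):
        out = sum(rem[e] for e in graph.out_edges(source))
        if out <= tol:
            break
        path: list[str] = []
        v = source
        stuck = False
        while v != sink:
            candidates = [e for e in graph.out_edges(v) if rem[e] > tol]
            if not candidates:
                stuck = True
                break
            best = max(candidates, key=lambda e: (rem[e], e))
            # deterministic: widest edge, ascending id on exact ties
            ties = [e for e in candidates if rem[e] == rem[best]]
            best = min(ties)
            path.append(best)
            v = graph.head(best)
        if stuck or not path:
            break
        c = min(rem[e] for e in path)
        for e in path:
            rem[e] -= c
        paths.paths.append((tuple(path), c))
    return paths


def _good_or(path: Sequence[str], query_edges: set[str]) -> bool:
    return any(e in query_edges for e in path)


def witness_decomposition(
    graph: SpliceGraph,
    flow: Mapping[str, float],
    query_edges: set[str],
    target: str,
) -> Decomposition:
    """Full decomposition achieving an OR-range endpoint.

    ``target="min"``: decompose a maximum flow of G- into bad paths and
    the residual into good paths.  ``target="max"``: decompose the
    maximum flow into the auxiliary sink into truncated good prefixes,
    then complete each prefix to T by the inductive reconstruction
    (always completing the prefix whose truncation vertex is
    topologically latest), and finally decompose the residual into bad
    paths.  Raises if the achieved good flow disagrees with the
    corresponding endpoint — that would indicate an implementation bug.
    """
    if target not in ("min", "max"):
        raise ValueError("target must be 'min' or 'max'")
    u = total_flow(graph, flow)
    rng = or_quant(graph, flow, query_edges)
    expect = rng.lo if target == "min" else rng.hi
    tol = EPS_LP * max(1.0, u)

    result = Decomposition()
    if target == "min":
        gminus = build_g_minus(graph, query_edges)
        _, f_minus = max_flow(gminus, flow)
        bad = decompose_flow(gminus, f_minus)
        result.paths.extend(bad.paths)
        residual = {
            eid: max(0.0, flow.get(eid, 0.0) - f_minus.get(eid, 0.0))
            for eid in graph.edge_ids
        }
        good = decompose_flow(graph, residual)
        result.paths.extend(good.paths)
    else:
        gplus = build_g_plus(graph, query_edges)
        _, f_star = max_flow(gplus, flow)
        truncated = decompose_flow(gplus, f_star, sink=AUX_SINK)
        topo_pos = {v: i for i, v in enumerate(topological_order(graph))}
        rem = {eid: max(0.0, flow.get(eid, 0.0)) for eid in graph.edge_ids}
        pending = list(truncated.paths)
        while pending:
            # complete the prefix whose truncation vertex is latest;
            # ties broken by ascending position in the pending list
            idx = max(
                range(len(pending)),
                key=lambda k: topo_pos[graph.tail(pending[k][0][-1])],
            )
            best_pos = topo_pos[graph.tail(pending[idx][0][-1])]
            idx = next(
                k
                for k in range(len(pending))
                if topo_pos[graph.tail(pending[k][0][-1])] == best_pos
            )
            prefix, c = pending.pop(idx)
            last = prefix[-1]
            v = graph.label(last) if graph.label(last) is not None else graph.head(last)
            if c <= tol:
                continue
            for e in prefix:
                rem[e] = max(0.0, rem[e] - c)
            if v == graph.sink:
                result.paths.append((tuple(prefix), c))
                continue
            got, tail_flow = _limited_max_flow(graph, rem, v, graph.sink, c)
            if got < c - tol:
                raise RuntimeError(
                    f"witness reconstruction failed: needed {c:g} flow from "
                    f"{v!r} to sink, found {got:g}"
                )
            tails = decompose_flow(graph, tail_flow, source=v)
            for tail_path, w in tails.paths:
                for e in tail_path:
                    rem[e] = max(0.0, rem[e] - w)
                result.paths.append((tuple(prefix) + tail_path, w))
        bad = decompose_flow(graph, rem)
        result.paths.extend(bad.paths)

    achieved = result.good_flow(lambda p: _good_or(p, query_edges))
    if abs(achieved - expect) > 1e3 * tol:
        raise RuntimeError(
            f"witness decomposition inconsistent: good flow {achieved:g} "
            f"!= {target} endpoint {expect:g}"
        )
    return result
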