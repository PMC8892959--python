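"""Splice-graph and flow data model shared by all range computations.

A splice graph is a DAG with a distinguished source ``S`` (transcript
start) and sink ``T`` (transcript termination); every other vertex is a
(partial) exon and every edge a splice junction.  Transcripts are S-T
paths.  An edge *flow* assigns a non-negative abundance to every
junction, balanced at every internal vertex; a *decomposition* expresses
a flow as a weighted set of S-T paths, i.e. a quantified transcript set.

Vertices and edges carry opaque string ids so that graphs can be copied,
pruned and redirected (auxiliary-sink constructions) without losing
identity.  Flows are plain ``{edge_id: weight}`` mappings; they are
real-valued throughout — quantifier output is fractional and no
integrality is assumed anywhere.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx

#: Relative tolerance for flow-balance checks (scaled by max(1, U)).
EPS_BALANCE = 1e-9
#: Absolute tolerance for LP / max-flow endpoint comparisons.
EPS_LP = 1e-6
#: Reserved name of the auxiliary sink used when query edges are redirected.
AUX_SINK = "T_prime"


class GraphError(ValueError):
    """Structural problem: unknown ids, cycles, malformed paths."""


class CycleError(GraphError):
    """Raised when a supposed DAG contains a cycle; carries a witness."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = tuple(cycle)
        super().__init__(f"graph contains a cycle: {' -> '.join(self.cycle)}")


@dataclass(frozen=True)
class AbundanceRange:
    """Closed interval [lo, hi] of optimal abundance for one query.

    Units follow whatever the flow / abundance table was expressed in
    (TPM, fragments, normalized flow).
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.hi < self.lo - EPS_LP:
            raise ValueError(f"invalid range: lo={self.lo} > hi={self.hi}")

    @property
    def width(self) -> float:
        return max(0.0, self.hi - self.lo)

    def contains(self, value: float, eps: float = EPS_LP) -> bool:
        return self.lo - eps <= value <= self.hi + eps

    def intersects(self, other: "AbundanceRange", eps: float = 0.0) -> bool:
        """Closed-interval intersection test (points on the boundary count)."""
        return self.lo <= other.hi + eps and other.lo <= self.hi + eps

    def intersection_length(self, other: "AbundanceRange") -> float:
        return max(0.0, min(self.hi, other.hi) - max(self.lo, other.lo))

    def is_point(self, eps: float = EPS_LP) -> bool:
        return self.width <= eps


@dataclass(frozen=True)
class EdgeSetQuery:
    """Ordered list of edge sets E_1 ... E_m defining "good" S-T paths.

    A path is good when it intersects every set, and the list must be
    well-ordered: no path may visit an edge of E_i and later an edge of
    E_j with i >= j.  Virtual boundary sets (an edge ending at S, an
    edge starting at T) are implicit.
    """

    sets: tuple[frozenset[str], ...]

    def __init__(self, sets: Iterable[Iterable[str]]):
        object.__setattr__(
            self, "sets", tuple(frozenset(s) for s in sets)
        )

    @property
    def m(self) -> int:
        return len(self.sets)

    def all_edges(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.sets:
            out |= s
        return out


@dataclass
class Decomposition:
    """Weighted set of S-T paths {(T_i, c_i)} realizing (part of) a flow.

    Paths are stored as edge-id sequences; weights are non-negative.
    """

    paths: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    def total(self) -> float:
        return sum(c for _, c in self.paths)

    def edge_sums(self) -> dict[str, float]:
        sums: dict[str, float] = {}
        for path, c in self.paths:
            for eid in path:
                sums[eid] = sums.get(eid, 0.0) + c
        return sums

    def good_flow(self, predicate) -> float:
        """Total weight of paths for which ``predicate(path)`` is true."""
        return sum(c for path, c in self.paths if predicate(path))


class SpliceGraph:
    """DAG with distinguished source/sink and stable string edge ids.

    Parallel edges are permitted (needed for auxiliary graphs where
    several query edges are redirected into the auxiliary sink); each
    edge may carry a label remembering its original destination.
    """

    def __init__(self, source: str = "S", sink: str = "T"):
        self.source = source
        self.sink = sink
        self._edges: dict[str, tuple[str, str]] = {}
        self._labels: dict[str, str] = {}
        self._out: dict[str, list[str]] = {source: [], sink: []}
        self._in: dict[str, list[str]] = {source: [], sink: []}

    # -- construction -------------------------------------------------
    def add_vertex(self, v: str) -> None:
        self._out.setdefault(v, [])
        self._in.setdefault(v, [])

    def add_edge(self, eid: str, u: str, v: str, label: str | None = None) -> None:
        if eid in self._edges:
            raise GraphError(f"duplicate edge id {eid!r}")
        self.add_vertex(u)
        self.add_vertex(v)
        self._edges[eid] = (u, v)
        self._out[u].append(eid)
        self._in[v].append(eid)
        if label is not None:
            self._labels[eid] = label

    def remove_edge(self, eid: str) -> None:
        u, v = self._edges.pop(eid)
        self._out[u].remove(eid)
        self._in[v].remove(eid)
        self._labels.pop(eid, None)

    def copy(self) -> "SpliceGraph":
        g = SpliceGraph(self.source, self.sink)
        for v in self._out:
            g.add_vertex(v)
        for eid, (u, v) in self._edges.items():
            g.add_edge(eid, u, v, self._labels.get(eid))
        return g

    # -- queries ------------------------------------------------------
    @property
    def vertices(self) -> list[str]:
        return list(self._out)

    @property
    def edges(self) -> dict[str, tuple[str, str]]:
        return dict(self._edges)

    @property
    def edge_ids(self) -> list[str]:
        return list(self._edges)

    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, eid: str) -> bool:
        return eid in self._edges

    def endpoints(self, eid: str) -> tuple[str, str]:
        try:
            return self._edges[eid]
        except KeyError:
            raise GraphError(f"unknown edge id {eid!r}") from None

    def tail(self, eid: str) -> str:
        return self.endpoints(eid)[0]

    def head(self, eid: str) -> str:
        return self.endpoints(eid)[1]

    def label(self, eid: str) -> str | None:
        return self._labels.get(eid)

    def out_edges(self, v: str) -> list[str]:
        return sorted(self._out.get(v, []))

    def in_edges(self, v: str) -> list[str]:
        return sorted(self._in.get(v, []))

    def to_networkx(self) -> nx.DiGraph:
        """Vertex-level adjacency view (parallel edges collapse)."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self._out))
        for u, v in self._edges.values():
            g.add_edge(u, v)
        return g


@dataclass(frozen=True)
class FlowViolation:
    """One validation failure: a named vertex/edge and its residual."""

    kind: str  # "negative_weight" | "balance" | "total"
    where: str
    residual: float

    def __str__(self) -> str:
        return f"{self.kind} at {self.where}: residual {self.residual:g}"


def total_flow(graph: SpliceGraph, flow: Mapping[str, float]) -> float:
    """Total abundance U: the outflow of the source.

    Refuses an invalid flow (the value would be meaningless otherwise).
    """
    report = validate_flow(graph, flow)
    if report:
        raise ValueError(
            "invalid flow: " + "; ".join(str(v) for v in report[:5])
        )
    return sum(flow.get(e, 0.0) for e in graph.out_edges(graph.source))


def validate_flow(
    graph: SpliceGraph, flow: Mapping[str, float]
) -> list[FlowViolation]:
    """Check non-negativity on every edge and balance at every internal vertex.

    Returns an empty list iff the flow invariants hold within
    ``EPS_BALANCE`` scaled by max(1, U).  Unknown edge ids are a
    structural error (``GraphError``), not a numeric violation.
    """
    for eid in flow:
        if not graph.has_edge(eid):
            raise GraphError(f"flow references unknown edge id {eid!r}")
    u_out = sum(flow.get(e, 0.0) for e in graph.out_edges(graph.source))
    tol = EPS_BALANCE * max(1.0, abs(u_out))
    report: list[FlowViolation] = []
    for eid in graph.edge_ids:
        w = flow.get(eid, 0.0)
        if w < -tol:
            report.append(FlowViolation("negative_weight", eid, w))
    for v in graph.vertices:
        if v in (graph.source, graph.sink):
            continue
        inflow = sum(flow.get(e, 0.0) for e in graph.in_edges(v))
        outflow = sum(flow.get(e, 0.0) for e in graph.out_edges(v))
        if not math.isclose(inflow, outflow, abs_tol=tol, rel_tol=0.0):
            report.append(FlowViolation("balance", v, inflow - outflow))
    t_in = sum(flow.get(e, 0.0) for e in graph.in_edges(graph.sink))
    if not math.isclose(u_out, t_in, abs_tol=tol, rel_tol=0.0):
        report.append(FlowViolation("total", graph.sink, u_out - t_in))
    return report


def topological_order(graph: SpliceGraph) -> list[str]:
    """Topological order of the vertices, ascending-id tie-break.

    Raises :class:`CycleError` with a cycle witness if the graph is not
    acyclic.
    """
    g = graph.to_networkx()
    try:
        return list(nx.lexicographical_topological_sort(g, key=str))
    except nx.NetworkXUnfeasible:
        cycle_edges = nx.find_cycle(g)
        witness = [u for u, _ in cycle_edges] + [cycle_edges[-1][1]]
        raise CycleError(witness) from None


def path_vertices(graph: SpliceGraph, path: Sequence[str]) -> list[str]:
    """Vertex sequence of a contiguous edge-id path; validates contiguity."""
    if not path:
        raise GraphError("empty path")
    verts = [graph.tail(path[0])]
    for eid in path:
        u, v = graph.endpoints(eid)
        if u != verts[-1]:
            raise GraphError(
                f"path not contiguous at edge {eid!r}: expected tail "
                f"{verts[-1]!r}, found {u!r}"
            )
        verts.append(v)
    return verts


def path_to_query(graph: SpliceGraph, path: Sequence[str]) -> EdgeSetQuery:
    """Singleton edge-set query for a full transcript (one set per junction).

    The path must be a contiguous S-T path; the resulting query is
    well-ordered by construction on a DAG.
    """
    verts = path_vertices(graph, path)
    if verts[0] != graph.source or verts[-1] != graph.sink:
        raise GraphError(
            f"path must run from {graph.source!r} to {graph.sink!r}, "
            f"got {verts[0]!r}..{verts[-1]!r}"
        )
    return EdgeSetQuery([{eid} for eid in path])


# -- plain-text interchange -------------------------------------------

def write_edge_list(graph: SpliceGraph, flow: Mapping[str, float]) -> str:
    """Serialize graph+flow to the tab-separated edge-list format.

    One line per edge ``edge_id<TAB>u<TAB>v<TAB>flow`` preceded by
    ``#source``/``#sink`` headers.  ``repr`` of the float is used so the
    round-trip is bit-exact.
    """
    lines = [f"#source\t{graph.source}", f"#sink\t{graph.sink}"]
    for eid in graph.edge_ids:
        u, v = graph.endpoints(eid)
        lines.append(f"{eid}\t{u}\t{v}\t{flow.get(eid, 0.0)!r}")
    return "\n".join(lines) + "\n"


def read_edge_list(text: str) -> tuple[SpliceGraph, dict[str, float]]:
    """Parse the edge-list format back into a graph and flow."""
    source, sink = "S", "T"
    rows: list[tuple[str, str, str, float]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if len(parts) == 2 and parts[0] == "source":
                source = parts[1]
            elif len(parts) == 2 and parts[0] == "sink":
                sink = parts[1]
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise GraphError(f"line {lineno}: expected 4 fields, got {len(parts)}")
        eid, u, v, w = parts
        rows.append((eid, u, v, float(w)))
    graph = SpliceGraph(source, sink)
    flow: dict[str, float] = {}
    for eid, u, v, w in rows:
        graph.add_edge(eid, u, v)
        flow[eid] = w
    return graph, flow
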