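"""Synthetic instances and brute-force oracles.

Every algorithmic claim in this package is checked against exhaustive
ground truth on small instances:

* :func:`random_flow_dag` draws a flow-carrying DAG whose flow is built
  as a sum of explicit path weights, so a valid witness decomposition is
  known by construction (any flow on a finite DAG is decomposable, but
  constructing it this way hands the tests an exact witness);
* :func:`oracle_flow_range` solves the good-flow min/max directly as an
  LP over *all* enumerated S-T paths — an independent route to the same
  quantities the max-flow reductions compute;
* :func:`synthetic_transcriptome` emulates the quantifier layer: genes
  with alternative isoforms, ground-truth abundances and exact junction
  totals, emitted both as in-memory objects and in the common
  quantifier table / GTF dialects.

No read-level simulation is performed: the tools audited here consume
quantification output, so the generator emulates exactly that layer.
"""

from __future__ import annotations

import itertools
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core_graph import (
    AbundanceRange,
    Decomposition,
    EdgeSetQuery,
    SpliceGraph,
)

#: Hard cap on enumerated S-T paths before the oracle refuses.
PATH_GUARD = 10**5


@dataclass
class FlowFixture:
    """Random flow DAG with a known witness decomposition."""

    graph: SpliceGraph
    flow: dict[str, float]
    witness: Decomposition
    seed: int

    @property
    def total(self) -> float:
        return sum(
            self.flow.get(e, 0.0) for e in self.graph.out_edges(self.graph.source)
        )


@dataclass
class GeneFixture:
    """One synthetic gene: graph, isoform paths and ground truth."""

    gene_id: str
    graph: SpliceGraph
    transcript_paths: dict[str, tuple[str, ...]]  # tid -> S-T edge path
    abundances: dict[str, float]
    junction_totals: dict[str, float]  # edge id -> summed abundance
    exon_lengths: dict[str, int] = field(default_factory=dict)


@dataclass
class TranscriptomeFixture:
    """Collection of synthetic genes plus quantifier-dialect outputs."""

    genes: dict[str, GeneFixture]
    quant_table: pd.DataFrame  # Name/Length/EffectiveLength/TPM/NumReads
    gtf_text: str
    seed: int


# ---------------------------------------------------------------------
# random flow DAGs
# ---------------------------------------------------------------------

def random_flow_dag(
    n_vertices: int = 8,
    edge_density: float = 0.35,
    n_paths: int = 4,
    max_weight: float = 10.0,
    seed: int = 0,
) -> FlowFixture:
    """Random DAG with a flow assembled from random weighted S-T paths.

    Vertices are laid out along a random-free topological order with S
    first and T last; forward edges appear independently with
    probability ``edge_density`` on top of a random backbone S-T path
    that guarantees connectivity.  ``n_paths`` random S-T walks with
    weights uniform on [0.5, max_weight] are summed into the flow and
    kept as the witness.  Deterministic given ``seed``.
    """
    if n_vertices < 3:
        raise ValueError("need at least 3 vertices (S, one exon, T)")
    rng = np.random.default_rng(seed)
    inner = [f"v{i}" for i in range(1, n_vertices - 1)]
    order = ["S", *inner, "T"]
    pos = {v: i for i, v in enumerate(order)}

    edges: set[tuple[str, str]] = set()
    # backbone guarantees S-T connectivity
    k = int(rng.integers(0, len(inner) + 1))
    backbone_idx = sorted(rng.choice(len(inner), size=k, replace=False)) if k else []
    backbone = ["S", *[inner[i] for i in backbone_idx], "T"]
    edges.update(zip(backbone[:-1], backbone[1:]))
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if rng.random() < edge_density:
                edges.add((u, v))

    graph = SpliceGraph()
    for u, v in sorted(edges, key=lambda e: (pos[e[0]], pos[e[1]])):
        graph.add_edge(f"{u}-{v}", u, v)

    # vertices that can still reach T (for dead-end-free walks)
    import networkx as nx

    g = graph.to_networkx()
    reaches_t = nx.ancestors(g, "T") | {"T"}

    flow = {eid: 0.0 for eid in graph.edge_ids}
    witness = Decomposition()
    for _ in range(n_paths):
        path: list[str] = []
        v = "S"
        while v != "T":
            options = [
                e for e in graph.out_edges(v) if graph.head(e) in reaches_t
            ]
            e = options[int(rng.integers(len(options)))]
            path.append(e)
            v = graph.head(e)
        w = float(rng.uniform(0.5, max_weight))
        witness.paths.append((tuple(path), w))
        for e in path:
            flow[e] += w
    return FlowFixture(graph=graph, flow=flow, witness=witness, seed=seed)


def random_or_query(fixture: FlowFixture, seed: int, max_edges: int = 4) -> set[str]:
    """Random edge subset E' for the OR problem (possibly empty)."""
    rng = np.random.default_rng(seed)
    eids = fixture.graph.edge_ids
    n = int(rng.integers(0, min(max_edges, len(eids)) + 1))
    if n == 0:
        return set()
    picked = rng.choice(len(eids), size=n, replace=False)
    return {eids[i] for i in sorted(picked)}


def random_well_ordered_query(
    fixture: FlowFixture, seed: int, max_sets: int = 3
) -> EdgeSetQuery:
    """Random well-ordered query built from singleton cuts along a path.

    Samples one S-T path of the graph, then picks up to ``max_sets``
    of its edges in path order as singleton sets — singleton sets taken
    in order along a DAG path are always well-ordered (a reversed visit
    would close a cycle).
    """
    rng = np.random.default_rng(seed)
    paths = enumerate_st_paths(fixture.graph)
    path = paths[int(rng.integers(len(paths)))]
    m = int(rng.integers(1, min(max_sets, len(path)) + 1))
    picked = sorted(rng.choice(len(path), size=m, replace=False))
    return EdgeSetQuery([{path[i]} for i in picked])


# ---------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------

def enumerate_st_paths(
    graph: SpliceGraph, guard: int = PATH_GUARD
) -> list[tuple[str, ...]]:
    """All S-T paths as edge-id tuples, duplicate-free, sorted.

    Refuses graphs with more than ``guard`` paths; the oracle is meant
    for small instances only.
    """
    out: list[tuple[str, ...]] = []

    def walk(v: str, acc: list[str]) -> None:
        if v == graph.sink:
            out.append(tuple(acc))
            if len(out) > guard:
                raise RuntimeError(
                    f"more than {guard} S-T paths; use a smaller instance"
                )
            return
        for e in graph.out_edges(v):
            acc.append(e)
            walk(graph.head(e), acc)
            acc.pop()

    walk(graph.source, [])
    return sorted(set(out))


def oracle_flow_range(
    graph: SpliceGraph,
    flow: Mapping[str, float],
    good: Callable[[Sequence[str]], bool],
) -> AbundanceRange:
    """Ground-truth good-flow range by LP over all enumerated paths.

    Variables are per-path weights x_p >= 0; equality constraints force
    the per-edge sums to reproduce the flow; the objective is the total
    weight of paths satisfying ``good``.  Exact (to solver precision)
    and completely independent of the max-flow reductions.
    """
    paths = enumerate_st_paths(graph)
    eids = [e for e in graph.edge_ids]
    e_index = {e: i for i, e in enumerate(eids)}
    a_eq = np.zeros((len(eids), len(paths)))
    for j, p in enumerate(paths):
        for e in p:
            a_eq[e_index[e], j] = 1.0
    b_eq = np.array([flow.get(e, 0.0) for e in eids])
    c = np.array([1.0 if good(p) else 0.0 for p in paths])
    lo_res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    hi_res = linprog(-c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not (lo_res.success and hi_res.success):
        raise RuntimeError(
            "oracle LP failed (flow not decomposable?): "
            f"{lo_res.message} / {hi_res.message}"
        )
    lo = max(0.0, float(lo_res.fun))
    hi = max(lo, float(-hi_res.fun))
    return AbundanceRange(lo, hi)


def or_predicate(query_edges: set[str]) -> Callable[[Sequence[str]], bool]:
    return lambda p: any(e in query_edges for e in p)


def and_predicate(query: EdgeSetQuery) -> Callable[[Sequence[str]], bool]:
    def good(p: Sequence[str]) -> bool:
        used = set(p)
        return all(used & es for es in query.sets)

    return good


# ---------------------------------------------------------------------
# synthetic transcriptomes
# ---------------------------------------------------------------------

def w_graph_fixture() -> FlowFixture:
    """The canonical two-choice ("W") worked example.

    Vertices S, A, B, M, C, D, T; flows S->A=4, S->B=6, A->M=4, B->M=6,
    M->C=3, M->D=7, C->T=3, D->T=7; total 10.  Decompositions are
    parameterized by the weight w in [0, 3] on path S-A-M-C-T.
    """
    graph = SpliceGraph()
    weights = {
        ("S", "A"): 4.0,
        ("S", "B"): 6.0,
        ("A", "M"): 4.0,
        ("B", "M"): 6.0,
        ("M", "C"): 3.0,
        ("M", "D"): 7.0,
        ("C", "T"): 3.0,
        ("D", "T"): 7.0,
    }
    flow: dict[str, float] = {}
    for (u, v), w in weights.items():
        eid = f"{u}-{v}"
        graph.add_edge(eid, u, v)
        flow[eid] = w
    witness = Decomposition(
        paths=[
            (("S-A", "A-M", "M-C", "C-T"), 3.0),
            (("S-A", "A-M", "M-D", "D-T"), 1.0),
            (("S-B", "B-M", "M-D", "D-T"), 6.0),
        ]
    )
    return FlowFixture(graph=graph, flow=flow, witness=witness, seed=-1)


def _random_isoforms(
    rng: np.random.Generator, n_exons: int, n_isoforms: int
) -> list[tuple[int, ...]]:
    """Distinct increasing exon index tuples of length >= 2."""
    chosen: set[tuple[int, ...]] = set()
    attempts = 0
    while len(chosen) < n_isoforms and attempts < 200:
        attempts += 1
        size = int(rng.integers(2, n_exons + 1))
        idx = tuple(sorted(rng.choice(n_exons, size=size, replace=False)))
        chosen.add(idx)
    return sorted(chosen)


def _paired_event_isoforms(
    rng: np.random.Generator, n_exons: int
) -> list[tuple[int, ...]]:
    """Four isoforms from two independent exon-skipping events.

    Two distinct interior exons are each independently included or
    skipped; the four product isoforms share all junctions pairwise, so
    single-junction evidence cannot pin the individual abundances —
    the canonical nonidentifiable configuration.
    """
    interior = rng.choice(range(1, n_exons - 1), size=2, replace=False)
    a, b = sorted(int(x) for x in interior)
    base = [k for k in range(n_exons) if k not in (a, b)]
    out = []
    for use_a, use_b in itertools.product((True, False), repeat=2):
        idx = sorted(base + ([a] if use_a else []) + ([b] if use_b else []))
        out.append(tuple(idx))
    return sorted(out)


def synthetic_transcriptome(
    n_genes: int = 10,
    isoforms_per_gene: int = 3,
    seed: int = 0,
    p_paired_event: float = 0.5,
) -> TranscriptomeFixture:
    """Genes with alternative isoforms and exact junction totals.

    Each gene is a chain of 3-8 exons.  With probability
    ``p_paired_event`` (and whenever ``isoforms_per_gene`` >= 2) a gene
    carries two independent exon-skipping events whose four product
    isoforms are mutually nonidentifiable from junction counts; other
    genes use ``isoforms_per_gene`` distinct increasing exon subsets of
    length >= 2 (every transcript spans at least one junction), which
    are usually identifiable.  Ground-truth abundances are log-uniform
    over three orders of magnitude, emulating the dynamic range of TPM
    estimates.  Junction totals g_i are computed exactly from the truth,
    and the quantifier-table / GTF dialects are emitted for IO tests.
    """
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneFixture] = {}
    gtf_lines: list[str] = []
    rows = []
    offset = 1000
    exon_len = 150
    gap = 100

    for gi in range(n_genes):
        gene_id = f"G{gi:04d}"
        paired = isoforms_per_gene >= 2 and rng.random() < p_paired_event
        n_exons = int(rng.integers(5 if paired else 3, 9))
        if paired:
            iso_idx = _paired_event_isoforms(rng, n_exons)
        else:
            iso_idx = _random_isoforms(rng, n_exons, isoforms_per_gene)
        graph = SpliceGraph()
        paths: dict[str, tuple[str, ...]] = {}
        abundances: dict[str, float] = {}
        exon_id = lambda k: f"{gene_id}.E{k}"  # noqa: E731
        exon_start = {
            k: offset + k * (exon_len + gap) for k in range(n_exons)
        }
        for ti, idx in enumerate(iso_idx):
            tid = f"{gene_id}.T{ti}"
            nodes = ["S", *[exon_id(k) for k in idx], "T"]
            path = []
            for u, v in zip(nodes[:-1], nodes[1:]):
                eid = f"{u}|{v}"
                if not graph.has_edge(eid):
                    graph.add_edge(eid, u, v)
                path.append(eid)
            paths[tid] = tuple(path)
            abundances[tid] = float(10 ** rng.uniform(0.0, 3.0))
            for k in idx:
                s = exon_start[k]
                gtf_lines.append(
                    "\t".join(
                        [
                            "chr1",
                            "sim",
                            "exon",
                            str(s),
                            str(s + exon_len - 1),
                            ".",
                            "+",
                            ".",
                            f'gene_id "{gene_id}"; transcript_id "{tid}";',
                        ]
                    )
                )
        totals: dict[str, float] = {}
        for tid, path in paths.items():
            for eid in path:
                totals[eid] = totals.get(eid, 0.0) + abundances[tid]
        genes[gene_id] = GeneFixture(
            gene_id=gene_id,
            graph=graph,
            transcript_paths=paths,
            abundances=abundances,
            junction_totals=totals,
            exon_lengths={exon_id(k): exon_len for k in range(n_exons)},
        )
        for tid, path in paths.items():
            length = (len(path) - 1) * exon_len
            rows.append((tid, length, max(1.0, length - 100.0), abundances[tid]))
        offset += n_exons * (exon_len + gap) + 10_000

    total_ab = sum(a for _, _, _, a in rows) or 1.0
    quant = pd.DataFrame(
        {
            "Name": [r[0] for r in rows],
            "Length": [r[1] for r in rows],
            "EffectiveLength": [r[2] for r in rows],
            "TPM": [r[3] * 1e6 / total_ab for r in rows],
            "NumReads": [r[3] for r in rows],
        }
    )
    return TranscriptomeFixture(
        genes=genes,
        quant_table=quant,
        gtf_text="\n".join(gtf_lines) + "\n",
        seed=seed,
    )
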