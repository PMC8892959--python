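# quantrange

Ranges of equally optimal transcript abundance estimates under
nonidentifiability.

RNA-seq expression quantification is nonidentifiable: because reads
multimap across isoforms that share exons, many different abundance
vectors explain the observed fragments with exactly the same likelihood,
and no amount of sequencing depth resolves the tie.  A point estimate
from a quantifier (Salmon-style output, or an edge flow on a splice
graph) is therefore one arbitrary member of a whole polytope of
co-optimal solutions.  `quantrange` computes, for each transcript or
splicing pattern, the closed interval `[lo, hi]` of abundances it can
take across *all* co-optimal solutions — the confidence range of
expression due to nonidentifiability — and uses these intervals to
audit downstream conclusions: whether within-gene isoform rankings are
conclusive, and whether differential-expression (DE) calls survive the
estimation ambiguity.

It is aimed at people who already run a quantifier and want to know
which of its numbers are actually pinned down by the data.

## The model

Three assumptions about reference completeness are supported.

**Complete reference (LP ranges).**  With transcripts `T_1..T_n` and an
optimal solution `c`, any `c'` is equally optimal iff for every phasing
path `J_i` (the junctions co-occurring in one fragment)

```
Σ_{j : J_i ⊆ T_j} c'_j  =  g_i  :=  Σ_{j : J_i ⊆ T_j} c_j ,    c' ≥ 0.
```

Minimizing and maximizing `c'_j` subject to this linear system gives the
range of transcript `j`; every value in between is attained by some
co-optimal solution (the feasible set is convex).  By default the
phasing paths are all single junctions.

**Incomplete reference (graph ranges).**  Here the optimum is an edge
flow `F` (total `U`) on the splice graph and transcripts are the S–T
paths; co-optimal solutions are the flow decompositions of `F`.  For an
edge set `E'`, OR-Quant asks for the attainable total weight of paths
touching *any* edge of `E'`:

```
OR-Quant(G, E') = [ U − MaxFlow(G⁻),  MaxFlow(G⁺) ]
```

where `G⁻` deletes `E'` and `G⁺` redirects `E'` into an auxiliary sink.
AND-Quant (paths touching *every* set of an ordered, well-ordered list
`{E_k}` — in particular a full transcript path) reduces to OR-Quant by
complementation through the *block graph* `G_B`, the subgraph containing
exactly the good paths, built in linear time from per-vertex reach
labels `s(v)`, `t(v)`.  A constructive witness routine returns an
explicit decomposition achieving either endpoint.

**Hybrid (λ ranges).**  With λ the assumed fraction of expression from
unannotated splice-graph paths,

```
[l_λ, u_λ] = [ λ·l¹ + (1−λ)·l⁰ ,  λ·u¹ + (1−λ)·u⁰ ].
```

Downstream audits: a transcript's ranking against a sibling isoform is
*inconclusive* when their ranges overlap; a DE call is *questionable* at
λ when the group-mean ranges of the two conditions overlap by more than
a threshold fraction (intersection over the smaller range, default
0.25).

## Worked example

The classic two-choice gene: vertices `S, A, B, M, C, D, T`, edge flows
`S→A=4, S→B=6, A→M=4, B→M=6, M→C=3, M→D=7, C→T=3, D→T=7` (total 10).
Decompositions are parameterized by the weight `w ∈ [0, 3]` placed on
the path S-A-M-C-T.

```python
from quantrange import (or_quant, transcript_range_graph,
                        build_linear_system, transcript_range_lp,
                        interpolate_range)
from quantrange.fixtures import w_graph_fixture
from quantrange.lp_ranges import TranscriptModel

fx = w_graph_fixture()
graph_range = transcript_range_graph(fx.graph, fx.flow,
                                     ("S-A", "A-M", "M-C", "C-T"))
or_range = or_quant(fx.graph, fx.flow, {"S-A", "M-C"})

transcripts = [
    TranscriptModel("T1", "g", ("SA", "AM", "MC", "CT")),
    TranscriptModel("T2", "g", ("SA", "AM", "MD", "DT")),
    TranscriptModel("T3", "g", ("SB", "BM", "MC", "CT")),
    TranscriptModel("T4", "g", ("SB", "BM", "MD", "DT")),
]
abund = {"T1": 3.0, "T2": 1.0, "T3": 0.0, "T4": 6.0}
system = build_linear_system(
    transcripts, abund, [(j,) for t in transcripts for j in t.junctions])
lp_range = transcript_range_lp(system, "T1")
blend = interpolate_range(lp_range, graph_range, 0.5)
```

This prints (via the tuples `(lo, hi)`):

```
graph range of S-A-M-C-T: (0.0, 3.0)
OR range of {S->A, M->C}: (4.0, 7.0)
LP range of T1: (0.0, 3.0)
lambda=0.5 blend: (0.0, 3.0)
```

Meaning: the quantifier may report any abundance between 0 and 3 for
the isoform S-A-M-C-T without changing the likelihood — its expression
is nonidentifiable — while the *combined* expression of patterns using
`S→A` or `M→C` is pinned between 4 and 7.  The input optimum `c_T1 = 3`
sits inside its LP range, as it must.

## Command line

```
quantrange simulate     --kind transcriptome --seed 1 --out sim/
quantrange lp-range     --gtf sim/annotation.gtf --quant sim/quant.sf --out lp.tsv
quantrange graph-range  --graph sim/graphs/G0000.tsv \
                        --query sim/graphs/G0000.queries.json --out gr.tsv
quantrange interpolate  --lp lp.tsv --graph gr.tsv --lam 0.5 --out combined.tsv
quantrange de-audit     --group-a a1.tsv --group-a a2.tsv \
                        --group-b b1.tsv --group-b b2.tsv --out audit.tsv
quantrange sibling-rank --ranges lp.tsv --out rank.tsv
```

## Documentation

See `docs/methods.md` for the model assumptions, generator design,
numerical choices and known limitations.
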