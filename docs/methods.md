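# Methods

## Problem setting

A splice graph is a DAG whose vertices are (partial) exons plus a
virtual source `S` and sink `T`; edges are splice junctions and each
transcript is an S–T path.  Quantifiers return either per-transcript
abundances (complete-reference models) or an edge flow on the splice
graph (graph quantification, which lets unannotated paths express
reads).  Both model families are nonidentifiable: distinct parameter
settings induce the identical fragment distribution.  This package does
no inference of its own — it consumes one optimal solution and
characterizes the whole set of equally optimal ones by the interval of
values each transcript (or splicing pattern) can take over that set.

## Complete-reference ranges (LP)

Two quantified transcript sets are indistinguishable iff for every
phasing path the total abundance of transcripts containing it in full
agrees.  The co-optimal set is therefore the polytope
`{c' ≥ 0 : M c' = M c}` where `M` is the phasing-path membership matrix
(containment = contiguous subsequence of the junction list).  Ranges
are per-coordinate LP minima/maxima (HiGHS via
`scipy.optimize.linprog`); convexity makes the projection of the
polytope onto one coordinate an interval, so every interior value is
attainable — the test suite verifies this by feasibility probes.

Choices worth noting:

* **Default phasing paths are the single junctions.**  Deriving longer
  phasing paths requires alignments, which are out of scope; longer
  paths supplied by the caller only shrink the ranges (tested as a
  monotonicity property).
* **`g_i` comes from the supplied optimum, not raw counts** — the input
  is assumed optimal, so its junction totals are the sufficient
  statistics.
* **Zero-abundance transcripts keep variables**: co-optimal solutions
  may assign them positive abundance (and often do).
* **Junction-free (single-exon) transcripts** are unconstrained by
  junction evidence.  They are reported as `[0, gene total]` with a
  warning rather than silently pinned or silently dropped.
* Ranges are reported in the units of the input abundance column (TPM
  by default, `NumReads` selectable).

## Incomplete-reference ranges (max-flow introspection)

Given a flow `F` (total `U`), the co-optimal solutions are its path
decompositions.  Queries come in two semantics:

* **OR** — good paths touch any edge of `E'`.  The minimum good flow is
  `U − MaxFlow(G⁻)` (`G⁻` = graph without `E'`; whatever the bad paths
  cannot absorb must be good) and the maximum is `MaxFlow(G⁺)` (`G⁺`
  redirects every `E'` edge into an auxiliary sink `T'`, measuring how
  much flow can be pushed through good-path prefixes).
* **AND** — good paths touch every set of an ordered list `{E_k}` with
  the well-ordering property (no path meets a later set before an
  earlier one).  The block graph `G_B` — the query edges plus every
  edge lying between consecutive query levels on some good path —
  contains exactly the good S–T paths, so
  `AND = [U − r, U − l]` with `[l, r] = OR(G, E − G_B)`.

`G_B` is built in linear time: after pruning vertices that are not on
any S–T path (two BFS passes, always on a copy), a forward DP over a
topological order computes `s(v)` (query progress achievable on the way
to `v`) and a backward DP computes `t(v)`; an edge of `E_i` survives
filtering iff `s(u) = i−1` and `t(v) = i+1`, and a non-query edge is a
block edge iff `s(u) + 1 = t(v)`.  The implementation checks
well-ordering explicitly (pairwise reachability between query-edge
endpoints) and refuses violating queries with a path witness; this
check is quadratic in the query size, which is deliberate — correctness
and diagnosability, not asymptotics, are the contract at the problem
sizes this tool sees.

**Witness decompositions.**  For either OR endpoint an explicit full
decomposition is constructed: for the minimum, a maximum flow of `G⁻`
is peeled into bad paths and the residual into good paths; for the
maximum, the `G⁺` max-flow is peeled into truncated good prefixes which
are completed to `T` one at a time — always the prefix whose truncation
vertex is topologically latest, completed by a capacity-limited
max-flow on the remaining capacities (ties broken by list position for
determinism) — and the residual becomes bad paths.  The routine
re-evaluates its own good flow and raises if it disagrees with the
endpoint; that condition indicates an implementation bug, never a data
property, so it fails loudly.

**Max-flow subroutine.**  networkx `maximum_flow` with
`shortest_augmenting_path` on an edge-splitter expansion (one node per
edge id).  The expansion keeps parallel edges into `T'` distinct,
yields per-edge witness flows directly, and is deterministic given the
insertion order (sorted edge ids).  Capacities are real-valued
throughout; no integrality is assumed.

**Path peeling** follows the widest remaining out-edge (ascending edge
id on exact ties); each peel zeroes at least one edge, bounding the
decomposition size by `|E|`.

## Hybrid ranges and audits

`[l_λ, u_λ] = [λl¹+(1−λ)l⁰, λu¹+(1−λ)u⁰]` with λ the assumed fraction
of expression from unannotated paths.  Both endpoints are affine in λ,
so interpolating per replicate and averaging across replicates commutes
(asserted to 1e−12 in tests).  The default λ grid is 0.0–1.0 in steps
of 0.1.

**Sibling ranking** within a gene is inconclusive for a transcript iff
its range intersects (closed intervals) the range of at least one other
isoform of the same gene.

**DE reliability**: for a transcript already called DE by an external
pipeline, the group-mean ranges of the two conditions are compared at
each λ.  The primary rule flags the call as questionable when the
overlap fraction — intersection length over the smaller range's length
— strictly exceeds 0.25.  An alternative gap rule (group A assumed
overexpressed; questionable when B's mean upper bound exceeds A's mean
lower bound by more than a configurable gap) is available but makes no
default claim.  When the smaller range is a point the overlap ratio is
undefined; the convention here is conservative: a point inside the
closed other range counts as full overlap, two points overlap iff equal
within tolerance.  Before cross-sample comparison LP ranges should be
in TPM and graph ranges scaled so each sample's total flow is 1e6
(`interpolate --normalize-graph`); the audit itself is
scale-convention-agnostic.

DE detection (fold change, FDR) is out of scope by design: the audit
only consumes direction-known calls.

## Synthetic data generator

`random_flow_dag` places vertices on a random topological order with a
backbone S–T path for connectivity, adds forward edges independently
(density 0.35 by default), and builds the flow as a sum of `n_paths`
random S–T walks with weights uniform on [0.5, 10].  The witness
decomposition is stored, so tests get an exact ground-truth
decomposition for free; any balanced flow is decomposable, but
constructing flows this way avoids pathological balanced-but-awkward
inputs while remaining fully general for the algorithms under test
(they never see the witness).

`synthetic_transcriptome` emulates the quantifier layer only (no reads,
no error model — the tools audited consume quantification output).
Genes are chains of 3–8 exons (150 bp, standard exon scale).  Half the
genes (by default) carry two independent exon-skipping events whose
four product isoforms are mutually nonidentifiable from single-junction
counts — the canonical configuration that creates ranges of optima in
real annotations, where independent alternative events multiply;
the remaining genes use random distinct exon subsets (length ≥ 2, so
every transcript spans a junction) and are usually identifiable.
Ground-truth abundances are log-uniform over three orders of magnitude,
matching the dynamic range of observed TPM values.  Junction totals are
computed exactly from the truth, so the generated "optimum" is exactly
optimal — which is the model's assumption, not an idealization of it.

What passing tests on these fixtures do *not* show: behavior under
quantifier estimation noise, fragment-length/bias effects on `g_i`,
phasing paths longer than single junctions derived from real
alignments, or annotation errors.  The ranges are conditional on the
supplied optimum being optimal.

## Oracles

Every range algorithm is cross-checked against an independent route:
an LP over all enumerated S–T paths (variables per path, equality
constraints per edge), with a 10^5-path guard.  The LP/grid-probe
oracle for transcript ranges and the path-enumeration oracle for flow
ranges share no code with the implementations they check.  The random
battery is 200 instances (≤ 10 vertices), seeds 0–199 in the test
suite and seed-derived in the acceptance script.

## Numerical choices

* Flow balance tolerance `1e−9 × max(1, U)` (relative; solver noise on
  doubles).
* LP / max-flow comparison tolerance `1e−6` absolute.
* Range endpoints clamped to `[0, U]` after complementation.
* Zero-total flows short-circuit to `[0, 0]`.
* Topological-order and decomposition tie-breaks: ascending id /
  list position, for reproducible output.
* Interval invariant `lo ≤ hi` enforced at construction (within
  tolerance), midpoint-collapsed if solver noise inverts endpoints.

## Known limitations

* Graph ranges require the flow to live on whatever DAG the caller
  supplies; the supergraph construction that folds multi-junction
  phasing reads into graph quantification is not built here, so
  edge-set queries for "local quantification" on such supergraphs must
  be provided pre-converted and well-ordered.
* The per-transcript ranges are marginals: picking one value per
  transcript independently need not yield a jointly optimal solution,
  so overlap-based flags are (slightly) conservative upper bounds on
  true indecision.
* Single-exon transcripts are flagged, not ranged (see above).
* Cyclic graphs are rejected outright.
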