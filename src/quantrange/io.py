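"""Annotation / quantification readers and splice-graph construction.

The splice graph for a gene is built the standard way: exon intervals
of all the gene's transcripts are split at every transcript boundary
coordinate into *partial exons*, which become the vertices; edges are
the observed adjacencies between consecutive partial exons within each
transcript, plus a virtual source edge into each transcript's first
segment and a virtual sink edge out of its last.  Each annotated
transcript then maps to a unique S-T path.

GTF coordinates are 1-based inclusive and converted to half-open at
the reader boundary.  Minus-strand transcripts are reversed so that
every path runs source-to-sink in transcription order.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import gffutils
import pandas as pd

from .core_graph import GraphError, SpliceGraph
from .lp_ranges import TranscriptModel


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # half-open
    end: int
    strand: str


@dataclass
class AnnotationRecord:
    """One transcript: gene id plus its ordered exon intervals."""

    gene_id: str
    transcript_id: str
    exons: list[Exon]


@dataclass(frozen=True)
class LineIssue:
    lineno: int
    message: str


def read_gtf(path: str) -> tuple[list[AnnotationRecord], list[LineIssue]]:
    """Parse exon features of a GTF into per-transcript records.

    Malformed lines (wrong field count, bad coordinates, missing
    gene_id/transcript_id) are reported with their line number and
    skipped; parsing continues.  Records are grouped by gene then
    transcript, in file order.
    """
    issues: list[LineIssue] = []
    by_tid: dict[str, AnnotationRecord] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                issues.append(
                    LineIssue(lineno, f"expected 9 fields, got {len(fields)}")
                )
                continue
            if fields[2] != "exon":
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
                start, end = int(fields[3]), int(fields[4])
            except Exception as exc:
                issues.append(LineIssue(lineno, f"unparseable: {exc}"))
                continue
            if start > end:
                issues.append(LineIssue(lineno, f"start {start} > end {end}"))
                continue
            attrs = feat.attributes
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                issues.append(
                    LineIssue(lineno, "missing gene_id or transcript_id attribute")
                )
                continue
            gid = attrs["gene_id"][0]
            tid = attrs["transcript_id"][0]
            exon = Exon(fields[0], start - 1, end, feat.strand)
            rec = by_tid.setdefault(tid, AnnotationRecord(gid, tid, []))
            rec.exons.append(exon)
    records = list(by_tid.values())
    for rec in records:
        rec.exons.sort(key=lambda e: (e.start, e.end))
    return records, issues


def _split_exon(exon: Exon, cuts: Sequence[int]) -> list[tuple[int, int]]:
    bounds = [exon.start]
    bounds += [c for c in cuts if exon.start < c < exon.end]
    bounds.append(exon.end)
    return list(zip(bounds[:-1], bounds[1:]))


def build_splice_graph(
    records: Iterable[AnnotationRecord],
) -> tuple[SpliceGraph, dict[str, tuple[str, ...]]]:
    """Splice graph of one gene plus the transcript -> S-T path map.

    Vertices are partial exons named ``chrom:start-end`` (half-open);
    edge ids are ``u|v``.  Transcripts with exons on mixed strands are
    rejected.
    """
    records = list(records)
    if not records:
        raise GraphError("no annotation records for gene")
    strands = set()
    for rec in records:
        strands |= {e.strand for e in rec.exons}
    if len(strands) > 1:
        raise GraphError(
            f"mixed strands {sorted(strands)} within one gene/transcript set"
        )
    strand = strands.pop() if strands else "+"
    cuts = sorted(
        {e.start for rec in records for e in rec.exons}
        | {e.end for rec in records for e in rec.exons}
    )
    graph = SpliceGraph()
    paths: dict[str, tuple[str, ...]] = {}
    for rec in records:
        segs: list[str] = []
        for exon in rec.exons:
            for s, t in _split_exon(exon, cuts):
                segs.append(f"{exon.chrom}:{s}-{t}")
        if strand == "-":
            segs = segs[::-1]
        nodes = ["S", *segs, "T"]
        path = []
        for u, v in zip(nodes[:-1], nodes[1:]):
            eid = f"{u}|{v}"
            if not graph.has_edge(eid):
                graph.add_edge(eid, u, v)
            path.append(eid)
        if rec.transcript_id in paths and paths[rec.transcript_id] != tuple(path):
            raise GraphError(f"duplicate transcript id {rec.transcript_id!r}")
        paths[rec.transcript_id] = tuple(path)
    return graph, paths


def transcript_models(
    records_by_gene: dict[str, list[AnnotationRecord]],
) -> tuple[dict[str, SpliceGraph], list[TranscriptModel]]:
    """Per-gene graphs and the flat transcript-model list for the LP."""
    graphs: dict[str, SpliceGraph] = {}
    models: list[TranscriptModel] = []
    for gene_id, records in records_by_gene.items():
        graph, paths = build_splice_graph(records)
        graphs[gene_id] = graph
        for tid, path in paths.items():
            models.append(TranscriptModel(tid, gene_id, tuple(path)))
    return graphs, models


def group_by_gene(
    records: Iterable[AnnotationRecord],
) -> dict[str, list[AnnotationRecord]]:
    out: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        out.setdefault(rec.gene_id, []).append(rec)
    return out


def read_quant_table(
    path: str, abundance_col: str = "TPM"
) -> tuple[pd.Series, list[str]]:
    """Per-transcript abundances from a quantifier output table.

    The table is TSV with a header containing ``Name`` and the selected
    abundance column (``TPM`` by default; ``NumReads`` is the common
    alternative).  Rows with negative abundance are rejected and
    reported.  Returns the abundance series indexed by transcript name
    plus a list of human-readable issues.
    """
    df = pd.read_csv(path, sep="\t")
    if "Name" not in df.columns:
        raise ValueError(f"no 'Name' column; available: {list(df.columns)}")
    if abundance_col not in df.columns:
        raise ValueError(
            f"no {abundance_col!r} column; available: {list(df.columns)}"
        )
    issues: list[str] = []
    values = pd.to_numeric(df[abundance_col], errors="coerce")
    bad = values.isna() | (values < 0)
    for name in df.loc[bad, "Name"]:
        issues.append(f"rejected row for {name!r}: invalid {abundance_col}")
    kept = df.loc[~bad]
    series = pd.Series(
        values.loc[~bad].to_numpy(dtype=float),
        index=kept["Name"].astype(str),
        name=abundance_col,
    )
    dup = series.index.duplicated()
    if dup.any():
        issues.append(f"{int(dup.sum())} duplicate names collapsed (first kept)")
        series = series[~dup]
    return series, issues
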