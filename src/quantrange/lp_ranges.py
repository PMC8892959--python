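"""Ranges of optima under the complete-reference assumption.

With a complete reference, two quantified transcript sets are
indistinguishable to the fragment model whenever, for every phasing
path (the junctions co-occurring in one fragment), the total abundance
of transcripts containing that path in full is identical.  Starting
from one optimal solution {c_j} — produced by any standard quantifier —
the set of co-optimal solutions is therefore the polytope

    sum_{j : path_i in T_j} c'_j = g_i   for every phasing path i,
    c'_j >= 0,

where g_i is evaluated at the input optimum.  Per-transcript min/max
LPs over this polytope give a closed interval of attainable abundance:
for every value in between there is a co-optimal solution assigning it
(the feasible set is convex, so the projection onto one coordinate is
an interval).

The default phasing-path set is every single junction of every
transcript, matching the base fragment model in which each fragment
spans exactly one junction; longer phasing paths, when supplied, only
tighten the ranges.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core_graph import EPS_LP, AbundanceRange

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as its ordered junction (edge-id) list."""

    transcript_id: str
    gene_id: str
    junctions: tuple[str, ...]


@dataclass
class LinearSystem:
    """Phasing-path equality system over per-transcript variables."""

    transcript_ids: list[str]
    phasing_paths: list[tuple[str, ...]]
    membership: np.ndarray  # (n_paths, n_transcripts), 0/1
    g: np.ndarray  # right-hand sides, evaluated at the input optimum
    abundances: np.ndarray  # the input optimum itself

    def index_of(self, transcript_id: str) -> int:
        try:
            return self.transcript_ids.index(transcript_id)
        except ValueError:
            raise KeyError(f"unknown transcript {transcript_id!r}") from None


def contains_contiguous(
    junctions: Sequence[str], path: Sequence[str]
) -> bool:
    """True iff ``path`` appears as a contiguous run inside ``junctions``."""
    n, m = len(junctions), len(path)
    if m == 0 or m > n:
        return False
    target = tuple(path)
    return any(tuple(junctions[i : i + m]) == target for i in range(n - m + 1))


def build_linear_system(
    transcripts: Sequence[TranscriptModel],
    abundances: Mapping[str, float],
    phasing_paths: Sequence[Sequence[str]],
) -> LinearSystem:
    """Assemble the equality system; one constraint per phasing path.

    Duplicate phasing paths are merged.  A path contained in no
    transcript signals malformed input (its constraint would say
    nothing) and raises ``ValueError``.
    """
    tids = [t.transcript_id for t in transcripts]
    ab = np.array([float(abundances[t]) for t in tids])
    if (ab < 0).any():
        bad = tids[int(np.argmin(ab))]
        raise ValueError(f"negative abundance for {bad!r}")
    seen: dict[tuple[str, ...], None] = {}
    for p in phasing_paths:
        seen.setdefault(tuple(p), None)
    paths = list(seen)
    membership = np.zeros((len(paths), len(tids)))
    for i, p in enumerate(paths):
        for j, t in enumerate(transcripts):
            if contains_contiguous(t.junctions, p):
                membership[i, j] = 1.0
        if membership[i].sum() == 0:
            raise ValueError(
                f"phasing path {p!r} is contained in no transcript"
            )
    g = membership @ ab
    return LinearSystem(
        transcript_ids=tids,
        phasing_paths=paths,
        membership=membership,
        g=g,
        abundances=ab,
    )


def _solve(system: LinearSystem, c: np.ndarray) -> float:
    res = linprog(
        c,
        A_eq=system.membership,
        b_eq=system.g,
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LP failed unexpectedly: {res.message}")
    return float(res.fun)


def transcript_range_lp(
    system: LinearSystem, transcript_id: str
) -> AbundanceRange:
    """Min/max attainable abundance of one transcript over all co-optima."""
    j = system.index_of(transcript_id)
    c = np.zeros(len(system.transcript_ids))
    c[j] = 1.0
    lo = max(0.0, _solve(system, c))
    hi = max(lo, -_solve(system, -c))
    return AbundanceRange(lo, hi)


def probe_feasible(
    system: LinearSystem, transcript_id: str, value: float
) -> bool:
    """Is there a co-optimal solution assigning ``value`` to the transcript?"""
    j = system.index_of(transcript_id)
    if value < 0:
        return False  # abundances are non-negative by definition
    bounds = [(0.0, None)] * len(system.transcript_ids)
    bounds[j] = (value, value)
    res = linprog(
        np.zeros(len(system.transcript_ids)),
        A_eq=system.membership,
        b_eq=system.g,
        bounds=bounds,
        method="highs",
    )
    return bool(res.success)


@dataclass(frozen=True)
class GeneFailure:
    gene_id: str
    message: str


def all_ranges_lp(
    transcripts: Sequence[TranscriptModel],
    abundances: Mapping[str, float],
    phasing_paths: Mapping[str, Sequence[Sequence[str]]] | None = None,
) -> tuple[pd.DataFrame, list[GeneFailure]]:
    """Per-transcript ranges, genes solved independently.

    ``phasing_paths`` maps gene id to extra phasing paths; when absent,
    the single junctions of the gene's transcripts are used.  Junction-
    free (single-exon) transcripts are unconstrained by junction
    evidence: they are reported as [0, total gene abundance] with a
    warning rather than silently pinned.

    Returns the range table and a list of per-gene failures (other
    genes are still solved).
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    rows = []
    failures: list[GeneFailure] = []
    for gene_id in by_gene:
        members = by_gene[gene_id]
        try:
            gene_total = sum(float(abundances[t.transcript_id]) for t in members)
            with_junctions = [t for t in members if t.junctions]
            for t in members:
                if not t.junctions:
                    logger.warning(
                        "transcript %s has no junctions; range defaults to "
                        "[0, gene total]",
                        t.transcript_id,
                    )
                    rows.append(
                        (
                            t.transcript_id,
                            gene_id,
                            float(abundances[t.transcript_id]),
                            0.0,
                            gene_total,
                        )
                    )
            if with_junctions:
                paths: list[Sequence[str]] = []
                for t in with_junctions:
                    paths.extend((j,) for j in t.junctions)
                if phasing_paths and gene_id in phasing_paths:
                    paths.extend(tuple(p) for p in phasing_paths[gene_id])
                system = build_linear_system(with_junctions, abundances, paths)
                for t in with_junctions:
                    rng = transcript_range_lp(system, t.transcript_id)
                    rows.append(
                        (
                            t.transcript_id,
                            gene_id,
                            float(abundances[t.transcript_id]),
                            rng.lo,
                            rng.hi,
                        )
                    )
        except Exception as exc:  # keep other genes alive
            failures.append(GeneFailure(gene_id, str(exc)))
    df = pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "abundance", "lo", "hi"]
    )
    df["identifiable"] = (df["hi"] - df["lo"] <= EPS_LP).astype(int)
    return df, failures
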