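"""Hybrid-assumption ranges and reliability classifiers.

The two range computations sit at opposite extremes: the LP ranges
assume every fragment comes from an annotated transcript, the graph
ranges let any splice-graph path express reads.  Reality is in between,
so both are blended with a mixing parameter λ — the assumed fraction of
expression arising from unannotated paths:

    [l_λ, u_λ] = [λ l¹ + (1-λ) l⁰,  λ u¹ + (1-λ) u⁰]

λ=0 reproduces the complete-reference range, λ=1 the pure graph range,
and both endpoints are affine in λ.

Two downstream audits consume these ranges:

* sibling-isoform ranking — within one gene, a transcript whose range
  overlaps a sibling's range has an inconclusive expression ranking;
* differential-expression reliability — a transcript already called DE
  between two replicate groups is *questionable* at a given λ when the
  group-mean ranges overlap by more than a threshold fraction (default
  0.25, intersection length over the smaller range's length).

Detection itself (fold changes, FDR) is external input; this module
only audits calls whose direction is already known.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .core_graph import EPS_LP, AbundanceRange

#: Default λ grid: 0.0, 0.1, ..., 1.0.
DEFAULT_LAMBDA_GRID = tuple(round(0.1 * k, 10) for k in range(11))
#: Default overlap fraction above which a DE call is questionable.
DEFAULT_OVERLAP_THRESHOLD = 0.25


def interpolate_range(
    range0: AbundanceRange, range1: AbundanceRange, lam: float
) -> AbundanceRange:
    """Affine blend of the complete-reference and graph ranges."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return AbundanceRange(
        lam * range1.lo + (1.0 - lam) * range0.lo,
        lam * range1.hi + (1.0 - lam) * range0.hi,
    )


def overlap_fraction(
    a: AbundanceRange, b: AbundanceRange, eps: float = EPS_LP
) -> float:
    """Intersection length over the smaller range's length, in [0, 1].

    The ratio is undefined when the smaller range is a point, so the
    convention is maximally conservative: a point inside the closed
    other range overlaps fully (1), outside not at all (0); two points
    overlap iff equal within ``eps``.
    """
    wa, wb = a.width, b.width
    small = min(wa, wb)
    if small <= eps:
        point, other = (a, b) if wa <= wb else (b, a)
        mid = (point.lo + point.hi) / 2.0
        if other.width <= eps:
            return 1.0 if abs(mid - (other.lo + other.hi) / 2.0) <= eps else 0.0
        return 1.0 if other.lo - eps <= mid <= other.hi + eps else 0.0
    return a.intersection_length(b) / small


def mean_range(ranges: Sequence[AbundanceRange]) -> AbundanceRange:
    """Coordinate-wise arithmetic mean across replicates."""
    if not ranges:
        raise ValueError("mean_range of an empty list")
    return AbundanceRange(
        float(np.mean([r.lo for r in ranges])),
        float(np.mean([r.hi for r in ranges])),
    )


def scale_range(r: AbundanceRange, factor: float) -> AbundanceRange:
    return AbundanceRange(r.lo * factor, r.hi * factor)


@dataclass(frozen=True)
class ReplicateRanges:
    """One sample's pair of extreme-assumption ranges for one transcript."""

    range0: AbundanceRange  # complete-reference (LP)
    range1: AbundanceRange  # incomplete-reference (graph)

    def at(self, lam: float) -> AbundanceRange:
        return interpolate_range(self.range0, self.range1, lam)


@dataclass
class DEGroupRanges:
    """Replicate ranges for one transcript under two conditions."""

    group_a: list[ReplicateRanges]
    group_b: list[ReplicateRanges]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both groups need at least one replicate")


@dataclass
class ReliabilityVerdict:
    """Per-λ overlap audit of one DE call.

    ``lambda_star`` is the smallest grid λ at which the call turns
    questionable (None if never); ``lambda_touch`` the smallest grid λ
    at which the mean ranges first intersect at all.
    """

    lambdas: tuple[float, ...]
    overlaps: tuple[float, ...]
    questionable: tuple[bool, ...]
    lambda_star: float | None
    lambda_touch: float | None
    threshold: float = DEFAULT_OVERLAP_THRESHOLD
    mode: str = "overlap"


def classify_de_call(
    groups: DEGroupRanges,
    lambdas: Sequence[float] = DEFAULT_LAMBDA_GRID,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    mode: str = "overlap",
    gap: float = 0.0,
) -> ReliabilityVerdict:
    """Audit one direction-known DE call across a λ grid.

    ``mode="overlap"`` (primary rule): questionable at λ iff the overlap
    fraction of the group-mean ranges strictly exceeds ``threshold``.
    ``mode="gap"`` (alternative): the call assumes group A is the
    overexpressed one; questionable iff mean lower bound of A falls
    below mean upper bound of B by more than ``gap`` (i.e.
    mean_u_B - mean_l_A > gap).

    Interpolation per replicate followed by averaging equals averaging
    followed by interpolation — both operations are affine — so the
    order is immaterial.
    """
    if mode not in ("overlap", "gap"):
        raise ValueError(f"unknown mode {mode!r}")
    overlaps: list[float] = []
    flags: list[bool] = []
    lambda_star: float | None = None
    lambda_touch: float | None = None
    for lam in lambdas:
        mean_a = mean_range([r.at(lam) for r in groups.group_a])
        mean_b = mean_range([r.at(lam) for r in groups.group_b])
        frac = overlap_fraction(mean_a, mean_b)
        overlaps.append(frac)
        if mode == "overlap":
            bad = frac > threshold
        else:
            bad = (mean_b.hi - mean_a.lo) > gap
        flags.append(bad)
        if bad and lambda_star is None:
            lambda_star = lam
        if lambda_touch is None and mean_a.intersects(mean_b):
            lambda_touch = lam
    return ReliabilityVerdict(
        lambdas=tuple(lambdas),
        overlaps=tuple(overlaps),
        questionable=tuple(flags),
        lambda_star=lambda_star,
        lambda_touch=lambda_touch,
        threshold=threshold,
        mode=mode,
    )


def sibling_ranking_inconclusive(
    ranges: dict[str, AbundanceRange],
) -> dict[str, bool]:
    """Flag transcripts whose range overlaps a sibling's range.

    ``ranges`` maps each transcript of *one* gene to its range.  An
    overlap (closed intervals; points on the boundary count) with at
    least one sibling means the expression ranking between the two
    isoforms cannot be determined from the data.  A single-isoform gene
    is never flagged.
    """
    tids = list(ranges)
    flags = {tid: False for tid in tids}
    for i, a in enumerate(tids):
        for b in tids[i + 1 :]:
            if ranges[a].intersects(ranges[b]):
                flags[a] = True
                flags[b] = True
    return flags
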