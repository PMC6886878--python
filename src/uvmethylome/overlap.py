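"""Interval-overlap statistics linking DMRs, photolesions and chromatin states.

The overlap rule follows bedtools ``-f`` semantics: a query interval counts
as overlapping when at least ``min_frac`` (default 50%) of its OWN length
intersects the union of the subject set.  Significance of an overlap between
two region sets is expressed as the representation factor R (observed /
expected overlap in a finite universe of N region slots) with a
hypergeometric tail p.  Methylation changes can extend beyond the damaged
interval itself; the spreading analysis measures those 5' and 3' extensions
and the "corrected" overlap recounts damaged regions after widening them by
the mean spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome import GenomeAnnotation, GenomicInterval
from .stats import RepresentationFactor, TestResult, chi_square_gof, representation_factor

__all__ = [
    "OverlapResult",
    "SpreadingSummary",
    "overlap_regions",
    "overlap_with_significance",
    "spreading_lengths",
    "corrected_overlap",
    "state_composition_of_regions",
]


@dataclass(frozen=True)
class OverlapResult:
    n_query: int
    n_subject: int
    n_overlapping: int
    percentage: float
    representation: RepresentationFactor | None
    universe_N: int | None

    @property
    def R(self) -> float | None:
        return self.representation.R if self.representation else None

    @property
    def p_hypergeometric(self) -> float | None:
        return self.representation.p_value if self.representation else None


@dataclass(frozen=True)
class SpreadingSummary:
    extensions_5p: list[float]
    extensions_3p: list[float]

    @property
    def mean_5p(self) -> float:
        return float(np.mean(self.extensions_5p)) if self.extensions_5p else float("nan")

    @property
    def mean_3p(self) -> float:
        return float(np.mean(self.extensions_3p)) if self.extensions_3p else float("nan")


def _merge(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Union of intervals per chromosome as sorted (start, end) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged)
    return out


def _intersection_length(
    start: int, end: int, merged: np.ndarray
) -> int:
    lo = np.minimum(end, merged[:, 1])
    hi = np.maximum(start, merged[:, 0])
    return int(np.maximum(0, lo - hi).sum())


def overlap_regions(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    min_frac: float = 0.5,
) -> list[bool]:
    """Flag each query interval overlapping ≥ min_frac of its length with the
    subject union (boundary cases at exactly min_frac are counted)."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    merged = _merge(subject) if subject else {}
    flags = []
    for q in query:
        m = merged.get(q.chrom)
        if m is None:
            flags.append(False)
            continue
        ov = _intersection_length(q.start, q.end, m)
        flags.append(ov >= min_frac * len(q))
    return flags


def overlap_with_significance(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    universe_N: int,
    min_frac: float = 0.5,
) -> OverlapResult:
    """Overlap counts plus representation factor and hypergeometric p, with
    x = overlapping queries, n1 = |query|, n2 = |subject| in a universe of
    ``universe_N`` region slots."""
    flags = overlap_regions(query, subject, min_frac)
    x = int(sum(flags))
    n1, n2 = len(query), len(subject)
    rep = None
    if n1 and n2 and universe_N:
        rep = representation_factor(n1, n2, min(x, min(n1, n2)), universe_N)
    pct = 100.0 * x / n1 if n1 else 0.0
    return OverlapResult(n1, n2, x, pct, rep, universe_N)


def default_universe(chrom_lengths: Mapping[str, int], region_size: int = 200) -> int:
    """Default representation-factor universe: genome length in region-sized
    slots (floor(total length / region_size))."""
    return sum(chrom_lengths.values()) // region_size


def _match_pairs(
    dmrs: Sequence[GenomicInterval],
    damaged: Sequence[GenomicInterval],
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Each DMR matched to the damaged interval with the largest overlap
    (ties → leftmost); DMRs with no overlap are skipped."""
    pairs = []
    for dmr in dmrs:
        best, best_ov = None, 0
        for dam in sorted(damaged, key=lambda d: (d.chrom, d.start)):
            ov = dmr.overlap_length(dam)
            if ov > best_ov:
                best, best_ov = dam, ov
        if best is not None:
            pairs.append((dmr, best))
    return pairs


def spreading_lengths(
    dmrs: Sequence[GenomicInterval],
    damaged_regions: Sequence[GenomicInterval],
) -> SpreadingSummary:
    """5' and 3' extension (bp) of each overlapping DMR beyond its matched
    damaged interval, on the plus-strand orientation convention."""
    ext5, ext3 = [], []
    for dmr, dam in _match_pairs(dmrs, damaged_regions):
        ext5.append(float(max(0, dam.start - dmr.start)))
        ext3.append(float(max(0, dmr.end - dam.end)))
    return SpreadingSummary(ext5, ext3)


def corrected_overlap(
    damaged_regions: Sequence[GenomicInterval],
    dmrs: Sequence[GenomicInterval],
    spread5: float,
    spread3: float,
    universe_N: int,
    min_frac: float = 0.5,
    chrom_lengths: Mapping[str, int] | None = None,
) -> OverlapResult:
    """Overlap of damaged regions with DMRs after widening each damaged
    region by the mean spreading distances.

    The intersection is computed against the widened interval but the
    ``min_frac`` denominator stays the ORIGINAL region length, so the
    corrected count is never below the strict count and is non-decreasing in
    the spread parameters.
    """
    if spread5 < 0 or spread3 < 0:
        raise ValueError("spread distances must be non-negative")
    merged = _merge(dmrs) if dmrs else {}
    flags = []
    for dam in damaged_regions:
        m = merged.get(dam.chrom)
        if m is None:
            flags.append(False)
            continue
        start = max(0, int(dam.start - spread5))
        end = int(dam.end + spread3)
        if chrom_lengths and dam.chrom in chrom_lengths:
            end = min(end, chrom_lengths[dam.chrom])
        ov = _intersection_length(start, end, m)
        flags.append(ov >= min_frac * len(dam))
    x = int(sum(flags))
    n1, n2 = len(damaged_regions), len(dmrs)
    rep = None
    if n1 and n2 and universe_N:
        rep = representation_factor(n1, n2, min(x, min(n1, n2)), universe_N)
    pct = 100.0 * x / n1 if n1 else 0.0
    return OverlapResult(n1, n2, x, pct, rep, universe_N)


def state_composition_of_regions(
    regions: Sequence[GenomicInterval],
    annotation: GenomeAnnotation,
) -> dict:
    """Chromatin-state makeup of a region set versus the genome-wide state
    fractions (chi-square goodness of fit).

    Each region is assigned the state with the largest overlap (ties → the
    lowest-numbered state); regions overlapping no state interval are
    dropped from the composition.
    """
    genome_fractions = annotation.state_fractions()
    if not genome_fractions:
        raise ValueError("annotation carries no chromatin states")
    states = sorted(genome_fractions)
    merged_by_state = {
        s: [iv for iv in annotation.chromatin_states if iv.name == s] for s in states
    }
    assigned: list[str] = []
    for region in regions:
        best, best_ov = None, 0
        for s in states:
            ov = sum(region.overlap_length(iv) for iv in merged_by_state[s])
            if ov > best_ov:
                best, best_ov = s, ov
        if best is not None:
            assigned.append(best)
    counts = {s: assigned.count(s) for s in states}
    n = len(assigned)
    fractions = {s: (c / n if n else 0.0) for s, c in counts.items()}
    test: TestResult | None = None
    if n:
        test = chi_square_gof(
            [counts[s] for s in states], [genome_fractions[s] for s in states]
        )
    return {
        "counts": counts,
        "fractions": fractions,
        "genome_fractions": genome_fractions,
        "test": test,
        "n_assigned": n,
    }
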