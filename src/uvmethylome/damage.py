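"""Photolesion-enrichment calling from IP versus input read sets.

Antibody-enriched (anti-CPD / anti-6,4-PP) sequencing reads are compared to
an input library with a transparent binned Poisson model: the genome is cut
into fixed bins, reads are assigned to the bin holding their midpoint, input
counts are scaled to the IP library size, and each bin's IP count is tested
against a Poisson null whose rate is the scaled input plus a pseudocount.
Benjamini–Hochberg-significant bins above a fold floor are merged across
small gaps and re-scored on their summed counts.

Read tables are DataFrames with columns ``chrom``, ``start``, ``end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomicInterval
from .stats import bh_adjust

__all__ = ["DamageCallerParams", "EnrichedRegion", "bin_counts", "call_enriched_regions"]


@dataclass(frozen=True)
class DamageCallerParams:
    bin_size: int = 200
    fold_min: float = 2.0
    q_max: float = 0.05
    merge_gap: int = 200
    pseudocount: float = 1.0


@dataclass(frozen=True)
class EnrichedRegion:
    interval: GenomicInterval
    ip_count: int
    input_count_scaled: float
    fold: float
    p_value: float
    q_value: float


def bin_counts(
    reads: pd.DataFrame, chrom_lengths: Mapping[str, int], bin_size: int
) -> dict[str, np.ndarray]:
    """Per-bin read counts; a read belongs to the bin holding its midpoint."""
    counts = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    if reads.empty:
        return counts
    for chrom, grp in reads.groupby("chrom"):
        if chrom not in counts:
            raise KeyError(f"read chromosome {chrom} not in genome")
        mid = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
        idx = np.clip(mid // bin_size, 0, len(counts[chrom]) - 1)
        np.add.at(counts[chrom], idx, 1)
    return counts


def call_enriched_regions(
    ip_reads: pd.DataFrame,
    input_reads: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    params: DamageCallerParams | None = None,
) -> list[EnrichedRegion]:
    """Poisson-enrichment regions of the IP library over the scaled input."""
    params = params or DamageCallerParams()
    if not chrom_lengths or sum(chrom_lengths.values()) == 0:
        raise ValueError("empty genome")
    if ip_reads.empty or input_reads.empty:
        raise ValueError("both IP and input libraries must be non-empty")
    scale = len(ip_reads) / len(input_reads)
    ip_bins = bin_counts(ip_reads, chrom_lengths, params.bin_size)
    in_bins = bin_counts(input_reads, chrom_lengths, params.bin_size)

    records = []
    for chrom in chrom_lengths:
        ip = ip_bins[chrom]
        lam = in_bins[chrom] * scale + params.pseudocount
        p = sps.poisson.sf(ip - 1, lam)
        fold = ip / lam
        for i in range(len(ip)):
            records.append((chrom, i, int(ip[i]), float(lam[i] - params.pseudocount),
                            float(fold[i]), float(p[i])))
    df = pd.DataFrame(
        records, columns=["chrom", "bin", "ip", "input_scaled", "fold", "p"]
    )
    df["q"] = bh_adjust(df["p"].to_numpy())
    sig = df[(df["q"] <= params.q_max) & (df["fold"] >= params.fold_min)]
    if sig.empty:
        return []

    regions: list[EnrichedRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("bin")
        bins = grp["bin"].to_numpy()
        # split where the bp gap between consecutive significant bins,
        # (diff - 1) * bin_size, exceeds merge_gap
        gap_bins = -(-params.merge_gap // params.bin_size)
        breaks = np.flatnonzero(np.diff(bins) > gap_bins + 1)
        pieces = np.split(np.arange(len(bins)), breaks + 1)
        for piece in pieces:
            b0, b1 = bins[piece[0]], bins[piece[-1]]
            start = int(b0) * params.bin_size
            end = min(int(b1 + 1) * params.bin_size, chrom_lengths[chrom])
            sel_ip = int(ip_bins[chrom][b0 : b1 + 1].sum())
            sel_in = float(in_bins[chrom][b0 : b1 + 1].sum() * scale)
            lam = sel_in + params.pseudocount
            regions.append(
                EnrichedRegion(
                    GenomicInterval(chrom, start, end),
                    sel_ip,
                    sel_in,
                    sel_ip / lam,
                    float(sps.poisson.sf(sel_ip - 1, lam)),
                    float(grp["q"].iloc[piece].min()),
                )
            )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def union_regions(
    *region_sets: list[EnrichedRegion], merge_gap: int = 0
) -> list[GenomicInterval]:
    """Union of enriched-region sets (e.g. CPD and 6,4-PP calls pooled into a
    single photolesion set); overlapping or abutting intervals are merged."""
    intervals = sorted(
        (r.interval for rs in region_sets for r in rs),
        key=lambda iv: (iv.chrom, iv.start),
    )
    merged: list[GenomicInterval] = []
    for iv in intervals:
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end + merge_gap:
            last = merged[-1]
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end)
            )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged
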