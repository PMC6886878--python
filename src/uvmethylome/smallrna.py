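"""Small-RNA size-class quantification over genomic regions.

Plant silencing small RNAs fall into canonical 21-, 22- and 24-nt classes;
24-nt siRNAs guide RNA-directed DNA methylation and are largely RNA POL IV
dependent.  Reads are partitioned by length, counted per region when at
least half the read lies inside it, and normalised as reads per million
(RPM) against the total mapped small-RNA content of the library.

Read tables are DataFrames with ``chrom``, ``start``, ``end`` (length =
end − start) and optionally ``strand``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval
from .stats import TestResult, wilcoxon_signed_rank

__all__ = [
    "SIZE_CLASSES",
    "RegionRPM",
    "size_partition",
    "region_rpm",
    "paired_abundance_test",
    "sizeclass_correlation",
]

SIZE_CLASSES = (21, 22, 24)
MIN_LEN, MAX_LEN = 18, 30


@dataclass(frozen=True)
class RegionRPM:
    region: GenomicInterval
    counts: dict  # size class -> raw count
    rpm: dict  # size class -> reads per million
    library_size: int


def size_partition(reads: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Split reads into the canonical 21/22/24-nt classes; other lengths are
    discarded."""
    lengths = reads["end"] - reads["start"]
    return {k: reads[lengths == k] for k in SIZE_CLASSES}


def region_rpm(
    reads: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    library_size: int,
    min_frac: float = 0.5,
) -> list[RegionRPM]:
    """Per-region, per-size-class read counts and RPM.

    A read counts toward a region when ≥ min_frac of the read's length lies
    inside it (boundary counted).  ``library_size`` is the total mapped
    small-RNA read count of the library, before size partitioning.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    classes = size_partition(reads)
    out = []
    for region in regions:
        counts = {}
        for k, df in classes.items():
            sel = df[df["chrom"] == region.chrom]
            if sel.empty:
                counts[k] = 0
                continue
            start = sel["start"].to_numpy()
            end = sel["end"].to_numpy()
            ov = np.minimum(end, region.end) - np.maximum(start, region.start)
            counts[k] = int((ov >= min_frac * (end - start)).sum())
        rpm = {k: 1e6 * c / library_size for k, c in counts.items()}
        out.append(RegionRPM(region, counts, rpm, library_size))
    return out


def paired_abundance_test(
    rpm_a: Sequence[float], rpm_b: Sequence[float]
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test of per-region abundances
    between two conditions measured over the same regions."""
    if len(rpm_a) != len(rpm_b):
        raise ValueError("paired vectors must have equal length")
    return wilcoxon_signed_rank(list(zip(rpm_a, rpm_b)))


def sizeclass_correlation(rpm_table: pd.DataFrame) -> dict:
    """Pairwise Pearson correlations among size-class abundance vectors and
    correlation-circle coordinates on the first two principal components.

    ``rpm_table`` holds one column per size class (e.g. 21, 22, 24) and one
    row per region.  Each variable's circle coordinates are its loadings
    (correlation with PC1 and PC2) so vector lengths are ≤ 1.  Zero-variance
    classes are flagged and excluded from the circle.
    """
    cols = list(rpm_table.columns)
    variances = rpm_table.var(axis=0, ddof=1)
    degenerate = [c for c in cols if not np.isfinite(variances[c]) or variances[c] == 0]
    active = [c for c in cols if c not in degenerate]
    corr = rpm_table[active].corr(method="pearson") if len(active) >= 2 else None
    coords: dict = {}
    explained = None
    if len(active) >= 2:
        X = rpm_table[active].to_numpy(dtype=float)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        R = np.asarray(corr)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
        eigval[eigval < 1e-12] = 0.0  # suppress numerical dust on degenerate axes
        # loadings: correlation of each standardised variable with each PC
        loadings = eigvec * np.sqrt(eigval)
        for i, c in enumerate(active):
            coords[c] = (float(loadings[i, 0]), float(loadings[i, 1] if R.shape[0] > 1 else 0.0))
        total = eigval.sum()
        explained = tuple(float(v / total) for v in eigval[:2]) if total else (0.0, 0.0)
    return {
        "correlations": corr,
        "circle": coords,
        "explained": explained,
        "excluded": degenerate,
    }
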