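"""Genome sequences, intervals, cytosine contexts and composition statistics.

Coordinates are 0-based half-open everywhere in this package.  Plant cytosine
methylation occurs in three sequence contexts — CG, CHG and CHH (H = A, T or
C) — read 5'→3' on the strand carrying the cytosine; context assignment here
is therefore strand-aware.  UV photolesions (CPDs and 6,4-photoproducts) form
between adjacent pyrimidines, so per-strand di-pyrimidine (CC/CT/TC/TT)
frequencies of candidate regions are the relevant sequence statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .stats import TestResult, chi_square_gof

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DIPYRIMIDINES = ("CC", "CT", "TC", "TT")
#: H = A, T or C — any base that is not G.
H_BASES = frozenset("ATC")

__all__ = [
    "GenomeSequence",
    "GenomicInterval",
    "GenomeAnnotation",
    "assign_context",
    "dipyrimidine_frequencies",
    "annotate_regions",
    "composition_vs_genome",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeSequence:
    """Per-chromosome nucleotide strings restricted to the A/C/G/T/N alphabet."""

    def __init__(self, chromosomes: Mapping[str, str]):
        self._chroms: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if name in self._chroms:
                raise ValueError(f"duplicate chromosome {name}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty chromosome {name}")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"chromosome {name}: invalid characters {bad}")
            self._chroms[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __iter__(self):
        return iter(self._chroms)

    def items(self):
        return self._chroms.items()

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._chroms.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self._chroms[interval.chrom]
        if interval.end > len(seq):
            raise IndexError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


@dataclass
class GenomeAnnotation:
    """Pericentromeres, PCG/TE/intergenic features and 9 chromatin states.

    ``features`` carry ``name`` = "PCG", "TE" or "TE:<family>"; chromatin-state
    intervals carry ``name`` = "1".."9".  Chromatin states are expected to tile
    each chromosome without overlap where provided.
    """

    pericentromeres: list[GenomicInterval] = field(default_factory=list)
    features: list[GenomicInterval] = field(default_factory=list)
    chromatin_states: list[GenomicInterval] = field(default_factory=list)

    def state_fractions(self) -> dict[str, float]:
        """Genome-wide fraction of annotated length in each chromatin state."""
        lengths: dict[str, float] = {}
        for iv in self.chromatin_states:
            lengths[iv.name] = lengths.get(iv.name, 0.0) + len(iv)
        total = sum(lengths.values())
        if total == 0:
            return {}
        return {state: L / total for state, L in sorted(lengths.items())}

    def is_pericentromeric(self, interval: GenomicInterval) -> bool:
        """True when the interval midpoint lies in a pericentromere."""
        mid = (interval.start + interval.end) // 2
        return any(
            p.chrom == interval.chrom and p.start <= mid < p.end
            for p in self.pericentromeres
        )


def assign_context(
    genome: GenomeSequence, chrom: str, pos: int, strand: str
) -> str:
    """Sequence context of the cytosine at ``pos`` on ``strand``.

    Returns "CG", "CHG", "CHH", or "none" when the two downstream bases run
    off the chromosome or contain N.  Raises if the position is out of range
    or the base there (read on ``strand``) is not a cytosine.
    """
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        raise IndexError(f"{chrom}:{pos} out of range")
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}+ is {seq[pos]}, not C")
        nxt = seq[pos + 1 : pos + 3]
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}- is {seq[pos]} on +, not G")
        # 3' direction on the minus strand runs toward lower plus coordinates.
        nxt = reverse_complement(seq[max(0, pos - 2) : pos])
    else:
        raise ValueError(f"invalid strand {strand!r}")

    if len(nxt) >= 1 and nxt[0] == "G":
        return "CG"
    if len(nxt) < 2 or "N" in nxt:
        return "none"
    if nxt[0] in H_BASES and nxt[1] == "G":
        return "CHG"
    if nxt[0] in H_BASES and nxt[1] in H_BASES:
        return "CHH"
    return "none"


def dipyrimidine_frequencies(
    genome: GenomeSequence,
    regions: Sequence[GenomicInterval],
    strand: str,
) -> dict:
    """Di-pyrimidine counts and frequencies over regions, one strand at a time.

    The minus strand is read 5'→3' on the reverse complement.  The denominator
    is the number of dinucleotide positions (region length − 1, summed over
    regions); an empty region list yields zero counts, not an error.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    counts = {d: 0 for d in DIPYRIMIDINES}
    total_positions = 0
    for region in regions:
        seq = genome.fetch(
            GenomicInterval(region.chrom, region.start, region.end, strand)
        )
        total_positions += len(seq) - 1
        for i in range(len(seq) - 1):
            di = seq[i : i + 2]
            if di in counts:
                counts[di] += 1
    freqs = {
        d: (c / total_positions if total_positions else 0.0)
        for d, c in counts.items()
    }
    return {"counts": counts, "frequencies": freqs, "positions": total_positions}


def _feature_class(name: str) -> str:
    return "TE" if name == "TE" or name.startswith("TE:") else name


def annotate_regions(
    regions: Sequence[GenomicInterval], annotation: GenomeAnnotation
) -> list[dict]:
    """Assign each region the identity {PCG, TE, intergenic} of the feature
    with the largest overlap; ties break TE > PCG > intergenic; no overlap →
    intergenic.  TE assignments keep the family recorded in the feature name
    ("TE:<family>").
    """
    chroms = {f.chrom for f in annotation.features} | {
        s.chrom for s in annotation.chromatin_states
    }
    precedence = {"TE": 0, "PCG": 1, "intergenic": 2}
    out = []
    for region in regions:
        if chroms and region.chrom not in chroms:
            raise KeyError(f"chromosome {region.chrom} absent from annotation")
        best = ("intergenic", "", 0)
        for feat in annotation.features:
            ov = region.overlap_length(feat)
            if ov == 0:
                continue
            cls = _feature_class(feat.name)
            family = feat.name.split(":", 1)[1] if ":" in feat.name else ""
            better = ov > best[2] or (
                ov == best[2] and precedence[cls] < precedence[best[0]]
            )
            if better:
                best = (cls, family, ov)
        out.append(
            {
                "region": region,
                "identity": best[0],
                "family": best[1] if best[0] == "TE" else "",
                "overlap": best[2],
            }
        )
    return out


def composition_vs_genome(
    region_labels: Iterable[str],
    background_fractions: Mapping[str, float],
) -> TestResult:
    """Goodness-of-fit chi-square of region identity counts against genome-wide
    background fractions (e.g. observed PCG/TE/intergenic makeup of DMRs versus
    the whole genome)."""
    labels = list(region_labels)
    categories = list(background_fractions)
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    total_frac = sum(background_fractions.values())
    if abs(total_frac - 1.0) > 1e-9:
        raise ValueError(f"background fractions sum to {total_frac}, not 1")
    observed = [sum(1 for l in labels if l == c) for c in categories]
    expected_frac = [background_fractions[c] for c in categories]
    return chi_square_gof(observed, expected_frac)
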