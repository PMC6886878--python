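"""Synthetic study generator: every input of the pipeline, with ground truth.

Emulates the data the analysis consumes — a small plant-like genome with
pericentromeres, PCG/TE features and 9 chromatin states; paired
control/treated bisulfite call tables with planted context-specific DMRs
concentrated in pericentromeres; photolesion IP/input read sets whose
enrichment follows di-pyrimidine density and chromatin state; 21/22/24-nt
small-RNA libraries including a POL IV-depleted one; and DAPI-like nucleus
images with known chromocenter occupancy.

Every generator is deterministic under the configured seed; sub-generators
draw from independent streams keyed by (seed, module tag) so each data type
can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .genome import GenomeAnnotation, GenomeSequence, GenomicInterval

__all__ = [
    "SimulationConfig",
    "GenomeSpec",
    "MethylomeSpec",
    "DamageSpec",
    "SmallRNASpec",
    "ImageSpec",
    "simulate_genome",
    "simulate_methylomes",
    "simulate_damage_reads",
    "simulate_smallrna",
    "simulate_nucleus_image",
    "cytosine_contexts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STREAM_TAGS = {"genome": 0, "methylome": 1, "damage": 2, "smallrna": 3, "image": 4}
TE_FAMILIES = ("Gypsy", "Copia", "LINE", "Helitron", "MuDR")


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM_TAGS[tag]]))


@dataclass(frozen=True)
class GenomeSpec:
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000}
    )
    pericentromere_fraction: float = 0.3
    te_fraction_peri: float = 0.8  # probability a pericentromeric slot is a TE
    te_fraction_arm: float = 0.1
    pcg_fraction_arm: float = 0.5
    mean_feature_length: int = 2_000
    mean_gap_length: int = 1_000
    mean_state_length: int = 5_000

    def __post_init__(self) -> None:
        if not 0 <= self.pericentromere_fraction < 1:
            raise ValueError("pericentromere fraction outside [0,1)")
        for chrom, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")


@dataclass(frozen=True)
class MethylomeSpec:
    #: baseline methylation probability per compartment and context
    baseline: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "pericentromere": {"CG": 0.85, "CHG": 0.65, "CHH": 0.10},
            "arm": {"CG": 0.25, "CHG": 0.10, "CHH": 0.03},
        }
    )
    coverage_mean: float = 20.0
    dmr_count: int = 100
    dmr_length: int = 600
    dmr_context: str = "CHH"
    dmr_delta: float = 0.3
    #: probability a planted DMR falls in a pericentromere
    dmr_peri_bias: float = 0.9
    #: fraction of planted DMRs that are hypermethylated in the treated sample
    dmr_hyper_fraction: float = 1.0

    def __post_init__(self) -> None:
        for comp, ctxs in self.baseline.items():
            for ctx, p in ctxs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"baseline {comp}/{ctx} outside [0,1]")
                if ctx != self.dmr_context:
                    continue
                if self.dmr_hyper_fraction > 0 and p + self.dmr_delta > 1:
                    raise ValueError(
                        f"dmr_delta pushes {comp}/{ctx} methylation above 1"
                    )
                if self.dmr_hyper_fraction < 1 and p - self.dmr_delta < 0:
                    raise ValueError(
                        f"dmr_delta pushes {comp}/{ctx} methylation below 0"
                    )
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")


@dataclass(frozen=True)
class DamageSpec:
    region_count: int = 20
    region_length: int = 1_000
    enrichment_fold: float = 8.0
    read_length: int = 75
    n_ip_reads: int = 200_000
    #: input sequenced deeper than the IP to stabilise the background rate
    n_input_reads: int = 400_000
    #: multiplicative IP weight per chromatin state ("1".."9")
    state_weights: Mapping[str, float] = field(default_factory=dict)
    #: weight floor added to the di-pyrimidine density factor; the large
    #: floor keeps the modulation mild, matching the absence of a strong
    #: di-pyrimidine bias at damaged regions in real UV IP data
    dipyrimidine_floor: float = 0.5
    bin_size: int = 200


@dataclass(frozen=True)
class SmallRNASpec:
    library_size: int = 1_000_000
    #: mix over canonical size classes
    size_mix: Mapping[int, float] = field(
        default_factory=lambda: {21: 0.25, 22: 0.15, 24: 0.60}
    )
    #: share of reads originating from the designated source intervals
    region_share: float = 0.05
    #: probability a source-interval read is RNA POL IV dependent
    pol_iv_dependent_fraction: float = 0.9
    #: fold change of the source share in the treated library (UV induction)
    treated_boost: float = 2.0


@dataclass(frozen=True)
class ImageSpec:
    n_nuclei: int = 12
    nucleus_radius_px: int = 30
    #: target chromocenter occupancies (%), cycled over nuclei
    co_targets: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    spots_per_nucleus: int = 3
    noise_sd: float = 0.0
    background_level: float = 0.05
    nucleus_level: float = 0.45
    spot_level: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    methylome: MethylomeSpec = field(default_factory=MethylomeSpec)
    damage: DamageSpec = field(default_factory=DamageSpec)
    smallrna: SmallRNASpec = field(default_factory=SmallRNASpec)
    image: ImageSpec = field(default_factory=ImageSpec)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, GenomeAnnotation]:
    """I.i.d. uniform A/C/G/T chromosomes with central pericentromeres,
    compartment-biased PCG/TE features and tiling 9-state chromatin."""
    rng = _rng(config.seed, "genome")
    spec = config.genome
    chroms: dict[str, str] = {}
    peri: list[GenomicInterval] = []
    features: list[GenomicInterval] = []
    states: list[GenomicInterval] = []
    for chrom, L in spec.chrom_lengths.items():
        seq = _BASES[rng.integers(0, 4, size=L)].tobytes().decode("ascii")
        chroms[chrom] = seq
        peri_len = int(round(L * spec.pericentromere_fraction))
        if peri_len > 0:
            p0 = (L - peri_len) // 2
            peri.append(GenomicInterval(chrom, p0, p0 + peri_len))
            peri_iv = (p0, p0 + peri_len)
        else:
            peri_iv = (L, L)
        features.extend(_place_features(rng, chrom, L, peri_iv, spec))
        states.extend(_place_states(rng, chrom, L, peri_iv, spec))
    return GenomeSequence(chroms), GenomeAnnotation(peri, features, states)


def _place_features(rng, chrom, L, peri_iv, spec: GenomeSpec):
    out = []
    pos = int(rng.integers(0, spec.mean_gap_length + 1))
    while pos < L:
        flen = max(200, int(rng.exponential(spec.mean_feature_length)))
        end = min(pos + flen, L)
        if end - pos < 200:
            break
        mid = (pos + end) // 2
        in_peri = peri_iv[0] <= mid < peri_iv[1]
        u = rng.random()
        if in_peri:
            kind = "TE" if u < spec.te_fraction_peri else None
        else:
            if u < spec.te_fraction_arm:
                kind = "TE"
            elif u < spec.te_fraction_arm + spec.pcg_fraction_arm:
                kind = "PCG"
            else:
                kind = None
        if kind == "TE":
            family = TE_FAMILIES[int(rng.integers(0, len(TE_FAMILIES)))]
            out.append(GenomicInterval(chrom, pos, end, name=f"TE:{family}"))
        elif kind == "PCG":
            out.append(GenomicInterval(chrom, pos, end, name="PCG"))
        pos = end + max(1, int(rng.exponential(spec.mean_gap_length)))
    return out


def _place_states(rng, chrom, L, peri_iv, spec: GenomeSpec):
    """Tile the chromosome with chromatin states 1..9; heterochromatic states
    8 and 9 dominate the pericentromere, euchromatic states the arms."""
    arm_w = np.array([2, 2, 2, 1.5, 1.5, 1, 1, 0.5, 0.5])
    peri_w = np.array([0.2, 0.2, 0.2, 0.5, 0.5, 1, 1, 3, 4])
    out = []
    pos = 0
    while pos < L:
        slen = max(1000, int(rng.exponential(spec.mean_state_length)))
        end = min(pos + slen, L)
        mid = (pos + end) // 2
        w = peri_w if peri_iv[0] <= mid < peri_iv[1] else arm_w
        state = 1 + rng.choice(9, p=w / w.sum())
        out.append(GenomicInterval(chrom, pos, end, name=str(state)))
        pos = end
    return out


# ---------------------------------------------------------------------------
# cytosine context scan (vectorised)


def _contexts_plus(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions and context codes (0=CG, 1=CHG, 2=CHH, 3=none) of plus-strand
    cytosines in a uint8 base-code array."""
    C, G, N = ord("C"), ord("G"), ord("N")
    L = codes.size
    pos = np.flatnonzero(codes == C)
    ctx = np.full(pos.size, 3, dtype=np.int8)
    has1 = pos + 1 < L
    n1 = np.where(has1, codes[np.minimum(pos + 1, L - 1)], N)
    has2 = pos + 2 < L
    n2 = np.where(has2, codes[np.minimum(pos + 2, L - 1)], N)
    is_cg = has1 & (n1 == G)
    h1 = has1 & (n1 != G) & (n1 != N)
    is_chg = h1 & has2 & (n2 == G)
    is_chh = h1 & has2 & (n2 != G) & (n2 != N)
    ctx[is_cg] = 0
    ctx[is_chg] = 1
    ctx[is_chh] = 2
    return pos, ctx


_COMPLEMENT_LUT = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT_LUT[a] = b


def cytosine_contexts(seq: str) -> pd.DataFrame:
    """All cytosines of both strands with their 0-based position, strand and
    context ∈ {CG, CHG, CHH, none} (context read 5'→3' on the cytosine's
    strand)."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    names = np.array(["CG", "CHG", "CHH", "none"])
    pos_p, ctx_p = _contexts_plus(codes)
    rc = _COMPLEMENT_LUT[codes[::-1]]
    pos_rc, ctx_m = _contexts_plus(rc)
    pos_m = codes.size - 1 - pos_rc
    df = pd.DataFrame(
        {
            "pos": np.concatenate([pos_p, pos_m]),
            "strand": np.concatenate(
                [np.full(pos_p.size, "+"), np.full(pos_m.size, "-")]
            ),
            "context": names[np.concatenate([ctx_p, ctx_m])],
        }
    )
    return df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylomes


def simulate_methylomes(
    genome: GenomeSequence,
    annotation: GenomeAnnotation,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Paired control/treated per-cytosine call tables plus the planted-DMR
    truth list.

    For every context-assigned cytosine, coverage ~ Poisson(mean) and
    methylated count ~ Binomial(coverage, p), with p the compartment baseline
    shifted by ±delta inside planted DMR intervals in the treated sample
    only.  Cytosines with zero coverage are omitted from a sample's table
    (unsequenced positions do not appear in real call tables).
    """
    rng = _rng(config.seed, "methylome")
    spec = config.methylome
    truth = _plant_dmrs(rng, genome, annotation, spec)
    control_parts, treated_parts = [], []
    for chrom, seq in genome.items():
        sites = cytosine_contexts(seq)
        sites = sites[sites["context"] != "none"].reset_index(drop=True)
        peri_mask = np.zeros(len(seq), dtype=bool)
        for p in annotation.pericentromeres:
            if p.chrom == chrom:
                peri_mask[p.start : p.end] = True
        in_peri = peri_mask[sites["pos"].to_numpy()]
        p_base = np.empty(len(sites))
        for comp, mask in (("pericentromere", in_peri), ("arm", ~in_peri)):
            for ctx in ("CG", "CHG", "CHH"):
                sel = mask & (sites["context"] == ctx).to_numpy()
                p_base[sel] = spec.baseline[comp][ctx]
        p_treated = p_base.copy()
        pos_arr = sites["pos"].to_numpy()
        ctx_arr = sites["context"].to_numpy()
        for t in truth:
            if t["chrom"] != chrom:
                continue
            sel = (
                (pos_arr >= t["start"]) & (pos_arr < t["end"]) & (ctx_arr == t["context"])
            )
            shifted = p_base[sel] + t["delta"]
            if shifted.size and (shifted.min() < 0 or shifted.max() > 1):
                raise ValueError("planted delta pushes methylation outside [0,1]")
            p_treated[sel] = shifted
        for parts, p in ((control_parts, p_base), (treated_parts, p_treated)):
            cov = rng.poisson(spec.coverage_mean, size=len(sites))
            meth = rng.binomial(cov, p)
            keep = cov > 0
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos_arr[keep],
                        "strand": sites["strand"].to_numpy()[keep],
                        "context": ctx_arr[keep],
                        "n_meth": meth[keep],
                        "n_total": cov[keep],
                    }
                )
            )
    control = pd.concat(control_parts, ignore_index=True)
    treated = pd.concat(treated_parts, ignore_index=True)
    return control, treated, truth


def _plant_dmrs(rng, genome, annotation, spec: MethylomeSpec) -> list[dict]:
    lengths = genome.lengths
    chroms = list(lengths)
    peri_by_chrom = {
        c: [p for p in annotation.pericentromeres if p.chrom == c] for c in chroms
    }
    truth = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(truth) < spec.dmr_count and attempts < spec.dmr_count * 200:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = lengths[chrom]
        if L <= spec.dmr_length:
            continue
        use_peri = rng.random() < spec.dmr_peri_bias and peri_by_chrom[chrom]
        if use_peri:
            p = peri_by_chrom[chrom][0]
            if len(p) <= spec.dmr_length:
                continue
            start = int(rng.integers(p.start, p.end - spec.dmr_length))
        else:
            start = int(rng.integers(0, L - spec.dmr_length))
        end = start + spec.dmr_length
        # keep planted regions separated by a window length so calls stay distinct
        if any(start < e + 400 and end > s - 400 for s, e in placed[chrom]):
            continue
        hyper = rng.random() < spec.dmr_hyper_fraction
        truth.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "context": spec.dmr_context,
                "delta": spec.dmr_delta if hyper else -spec.dmr_delta,
                "direction": "hyper" if hyper else "hypo",
            }
        )
        placed[chrom].append((start, end))
    if len(truth) < spec.dmr_count:
        raise ValueError("could not place the requested number of DMRs")
    return truth


# ---------------------------------------------------------------------------
# photolesion IP / input reads


def simulate_damage_reads(
    genome: GenomeSequence,
    annotation: GenomeAnnotation,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GenomicInterval]]:
    """IP and input read tables plus the true enriched intervals.

    Input reads are uniform.  IP reads are drawn per genome bin with weight
    ∝ (1 + (fold−1)·truth overlap fraction) × (floor + di-pyrimidine
    density) × chromatin-state weight.
    """
    rng = _rng(config.seed, "damage")
    spec = config.damage
    lengths = genome.lengths
    if sum(lengths.values()) == 0:
        raise ValueError("zero-length genome")
    truth = _plant_damage(rng, lengths, spec)
    ip = _sample_weighted_reads(rng, genome, annotation, truth, spec)
    inp = _sample_uniform_reads(rng, lengths, spec.n_input_reads, spec.read_length)
    return ip, inp, truth


def _plant_damage(rng, lengths, spec: DamageSpec) -> list[GenomicInterval]:
    chroms = list(lengths)
    out: list[GenomicInterval] = []
    attempts = 0
    while len(out) < spec.region_count and attempts < spec.region_count * 200:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = lengths[chrom]
        if L <= spec.region_length:
            continue
        start = int(rng.integers(0, L - spec.region_length))
        end = start + spec.region_length
        if any(
            iv.chrom == chrom and start < iv.end + 2 * spec.bin_size
            and end > iv.start - 2 * spec.bin_size
            for iv in out
        ):
            continue
        out.append(GenomicInterval(chrom, start, end))
    if len(out) < spec.region_count:
        raise ValueError("could not place the requested number of damage regions")
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def _dipyrimidine_density(seq_codes: np.ndarray, bin_size: int) -> np.ndarray:
    pyr = (seq_codes == ord("C")) | (seq_codes == ord("T"))
    dipyr = (pyr[:-1] & pyr[1:]).astype(float)
    n_bins = -(-seq_codes.size // bin_size)
    dens = np.zeros(n_bins)
    for b in range(n_bins):
        lo, hi = b * bin_size, min((b + 1) * bin_size, dipyr.size)
        if hi > lo:
            dens[b] = dipyr[lo:hi].mean()
    return dens


def _sample_weighted_reads(rng, genome, annotation, truth, spec: DamageSpec):
    parts = []
    lengths = genome.lengths
    chrom_weights = {}
    for chrom, L in lengths.items():
        codes = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        dens = _dipyrimidine_density(codes, spec.bin_size)
        n_bins = dens.size
        w = spec.dipyrimidine_floor + dens
        state_w = np.ones(n_bins)
        if spec.state_weights:
            for iv in annotation.chromatin_states:
                if iv.chrom != chrom:
                    continue
                sw = spec.state_weights.get(iv.name, 1.0)
                b0, b1 = iv.start // spec.bin_size, -(-iv.end // spec.bin_size)
                state_w[b0:b1] = sw
        fold_w = np.ones(n_bins)
        for iv in truth:
            if iv.chrom != chrom:
                continue
            for b in range(iv.start // spec.bin_size, -(-iv.end // spec.bin_size)):
                lo, hi = b * spec.bin_size, min((b + 1) * spec.bin_size, lengths[chrom])
                frac = max(0, min(hi, iv.end) - max(lo, iv.start)) / max(1, hi - lo)
                fold_w[b] = 1.0 + (spec.enrichment_fold - 1.0) * frac
        bin_len = np.minimum(
            (np.arange(n_bins) + 1) * spec.bin_size, lengths[chrom]
        ) - np.arange(n_bins) * spec.bin_size
        chrom_weights[chrom] = w * state_w * fold_w * bin_len
    total_w = np.concatenate([chrom_weights[c] for c in lengths])
    prob = total_w / total_w.sum()
    draws = rng.multinomial(spec.n_ip_reads, prob)
    offset = 0
    for chrom, L in lengths.items():
        n_bins = chrom_weights[chrom].size
        counts = draws[offset : offset + n_bins]
        offset += n_bins
        starts = []
        for b in np.flatnonzero(counts):
            lo = b * spec.bin_size
            hi = min((b + 1) * spec.bin_size, L)
            s = rng.integers(lo, hi, size=counts[b])
            starts.append(np.minimum(s, max(0, L - spec.read_length)))
        if starts:
            s = np.concatenate(starts)
            parts.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": s, "end": s + spec.read_length}
                )
            )
    return pd.concat(parts, ignore_index=True).sort_values(
        ["chrom", "start"], ignore_index=True
    )


def _sample_uniform_reads(rng, lengths, n_reads, read_length):
    chroms = list(lengths)
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    draws = rng.multinomial(n_reads, sizes / sizes.sum())
    parts = []
    for chrom, n in zip(chroms, draws):
        hi = max(1, lengths[chrom] - read_length)
        s = rng.integers(0, hi, size=n)
        parts.append(pd.DataFrame({"chrom": chrom, "start": s, "end": s + read_length}))
    return pd.concat(parts, ignore_index=True).sort_values(
        ["chrom", "start"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# small RNA libraries


def simulate_smallrna(
    chrom_lengths: Mapping[str, int],
    source_intervals: Sequence[GenomicInterval],
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Small-RNA libraries: untreated, treated (source share boosted) and a
    POL IV-depleted counterpart of the treated library.

    Reads of length 21/22/24 nt are placed either inside the designated
    source intervals (share = ``region_share``, boosted in the treated
    library) or uniformly as background.  Source reads are POL IV dependent
    with probability ``pol_iv_dependent_fraction`` and are removed from the
    depleted library.
    """
    rng = _rng(config.seed, "smallrna")
    spec = config.smallrna
    libs: dict[str, pd.DataFrame] = {}
    untreated, _ = _sample_library(rng, chrom_lengths, source_intervals, spec, spec.region_share)
    treated, dep_mask = _sample_library(
        rng, chrom_lengths, source_intervals, spec,
        min(1.0, spec.region_share * spec.treated_boost),
    )
    libs["untreated"] = untreated
    libs["treated"] = treated
    libs["treated_pol_iv_depleted"] = treated[~dep_mask].reset_index(drop=True)
    return libs


def _sample_library(rng, chrom_lengths, sources, spec: SmallRNASpec, share):
    sizes = np.array([len(s) for s in sources], dtype=float) if sources else np.array([])
    classes = np.array(sorted(spec.size_mix))
    probs = np.array([spec.size_mix[k] for k in classes], dtype=float)
    probs = probs / probs.sum()
    n = spec.library_size
    lens = classes[rng.choice(len(classes), size=n, p=probs)]
    from_source = rng.random(n) < share if len(sizes) else np.zeros(n, dtype=bool)
    chroms_list = list(chrom_lengths)
    genome_sizes = np.array([chrom_lengths[c] for c in chroms_list], dtype=float)
    chrom_idx = rng.choice(len(chroms_list), size=n, p=genome_sizes / genome_sizes.sum())
    starts = np.empty(n, dtype=np.int64)
    chrom_names = np.empty(n, dtype=object)
    bg = ~from_source
    for ci, chrom in enumerate(chroms_list):
        sel = bg & (chrom_idx == ci)
        hi = max(1, chrom_lengths[chrom] - 30)
        starts[sel] = rng.integers(0, hi, size=int(sel.sum()))
        chrom_names[sel] = chrom
    if from_source.any():
        src_idx = rng.choice(len(sources), size=int(from_source.sum()), p=sizes / sizes.sum())
        where = np.flatnonzero(from_source)
        for j, si in zip(where, src_idx):
            src = sources[si]
            hi = max(src.start + 1, src.end - int(lens[j]))
            starts[j] = rng.integers(src.start, hi)
            chrom_names[j] = src.chrom
    dependent = from_source & (rng.random(n) < spec.pol_iv_dependent_fraction)
    df = pd.DataFrame(
        {
            "chrom": chrom_names,
            "start": starts,
            "end": starts + lens,
            "from_source": from_source,
        }
    )
    return df, dependent


# ---------------------------------------------------------------------------
# nucleus images


def _place_spot_centres(rng, cy, cx, ry, rx, spot_r, n_spots, restarts=300):
    """Non-overlapping spot centres inside the central part of an ellipse;
    each restart redraws the whole configuration so placement cannot get
    stuck on a bad first draw."""
    min_sep2 = (2.1 * spot_r) ** 2
    for _ in range(restarts):
        pts = []
        for _ in range(n_spots):
            ang = rng.random() * 2 * np.pi
            rad = np.sqrt(rng.random()) * 0.65
            pts.append((cy + rad * ry * np.sin(ang), cx + rad * rx * np.cos(ang)))
        ok = all(
            (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2 >= min_sep2
            for i, a in enumerate(pts)
            for b in pts[i + 1 :]
        )
        if ok:
            return pts
    return None


def simulate_nucleus_image(
    config: SimulationConfig,
) -> tuple[np.ndarray, list[dict]]:
    """DAPI-like grayscale image (float in [0,1]) with elliptical nuclei and
    bright circular chromocenter spots sized to hit per-nucleus CO targets.

    Truth CO is computed from the drawn pixel masks: 100 × Σ spot px /
    nucleus px.
    """
    rng = _rng(config.seed, "image")
    spec = config.image
    r = spec.nucleus_radius_px
    cell = int(4 * r)
    n_cols = int(np.ceil(np.sqrt(spec.n_nuclei)))
    n_rows = -(-spec.n_nuclei // n_cols)
    img = np.full((n_rows * cell, n_cols * cell), spec.background_level, dtype=float)
    truth = []
    for i in range(spec.n_nuclei):
        row, col = divmod(i, n_cols)
        cy, cx = row * cell + cell // 2, col * cell + cell // 2
        ry = r * (0.85 + 0.3 * rng.random())
        rx = r * (0.85 + 0.3 * rng.random())
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        nucleus = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        img[nucleus] = spec.nucleus_level
        nucleus_area = int(nucleus.sum())
        co_target = spec.co_targets[i % len(spec.co_targets)]
        target_area = co_target / 100.0 * nucleus_area
        spot_mask = np.zeros_like(nucleus)
        spot_areas = []
        n_spots = spec.spots_per_nucleus if target_area > 0 else 0
        per_spot = target_area / n_spots if n_spots else 0.0
        spot_r = max(1.0, np.sqrt(per_spot / np.pi)) if n_spots else 0.0
        if spot_r >= min(rx, ry) * 0.8:
            raise ValueError("chromocenter spots cannot fit inside the nucleus")
        placed = (
            _place_spot_centres(rng, cy, cx, ry, rx, spot_r, n_spots)
            if n_spots
            else []
        )
        if placed is None:
            raise ValueError("chromocenter spots cannot fit inside the nucleus")
        for sy, sx in placed:
            rr, cc = draw_disk((sy, sx), spot_r, shape=img.shape)
            keep = nucleus[rr, cc]
            rr, cc = rr[keep], cc[keep]
            img[rr, cc] = spec.spot_level
            one = np.zeros_like(nucleus)
            one[rr, cc] = True
            spot_mask |= one
            spot_areas.append(int(one.sum()))
        truth.append(
            {
                "nucleus_id": i + 1,
                "center": (cy, cx),
                "nucleus_area": nucleus_area,
                "spot_areas": spot_areas,
                "total_spot_area": int(spot_mask.sum()),
                "co": 100.0 * spot_mask.sum() / nucleus_area,
                "co_target": co_target,
            }
        )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
    return img, truth
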