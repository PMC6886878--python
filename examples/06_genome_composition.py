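"""Sequence and chromatin composition of a region set.

Computes per-strand di-pyrimidine (CC/CT/TC/TT) frequencies of damage-prone
regions — the substrate of UV photolesions — classifies regions against
PCG/TE/intergenic annotation, and tests the chromatin-state makeup of a
region set against the genome-wide state fractions with a chi-square
goodness of fit.
"""

from uvmethylome import annotate_regions, dipyrimidine_frequencies
from uvmethylome.overlap import state_composition_of_regions
from uvmethylome.simulate import SimulationConfig, simulate_damage_reads, simulate_genome

cfg = SimulationConfig(seed=21)
genome, annotation = simulate_genome(cfg)
_, _, damage_truth = simulate_damage_reads(genome, annotation, cfg)

for strand in "+-":
    freqs = dipyrimidine_frequencies(genome, damage_truth, strand)["frequencies"]
    txt = ", ".join(f"{k} {v:.3f}" for k, v in sorted(freqs.items()))
    print(f"strand {strand}: {txt}")
# On an i.i.d. uniform genome each of the 16 dinucleotides has frequency
# 1/16 = 0.0625 per strand; real genomes deviate.

identities = [r["identity"] for r in annotate_regions(damage_truth, annotation)]
for cls in ("PCG", "TE", "intergenic"):
    print(f"{cls}: {identities.count(cls)}/{len(identities)} damaged regions")

comp = state_composition_of_regions(damage_truth, annotation)
top = max(comp["fractions"], key=comp["fractions"].get)
print(
    f"most common chromatin state: {top} "
    f"({100*comp['fractions'][top]:.0f}% of regions); "
    f"chi-square vs genome p = {comp['test'].p_value:.3f}"
)
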