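"""Quantify 21/22/24-nt small-RNA abundance over regions and test RNA POL IV
dependence.

Simulates an untreated, a treated (UV-boosted) and a POL IV-depleted small
RNA library over a set of source regions, computes per-region RPM by size
class, compares treated vs depleted with the Wilcoxon matched-pairs test,
and draws the size-class correlation circle.
"""

import pandas as pd

from uvmethylome import (
    GenomicInterval,
    paired_abundance_test,
    region_rpm,
    sizeclass_correlation,
)
from uvmethylome.simulate import SimulationConfig, SmallRNASpec, simulate_smallrna

regions = [
    GenomicInterval("chr1", 20_000 + 60_000 * i, 22_000 + 60_000 * i)
    for i in range(12)
]
cfg = SimulationConfig(
    seed=8, smallrna=SmallRNASpec(library_size=400_000, region_share=0.15)
)
libs = simulate_smallrna({"chr1": 1_000_000}, regions, cfg)

treated = region_rpm(libs["treated"], regions, len(libs["treated"]))
depleted = region_rpm(
    libs["treated_pol_iv_depleted"], regions, len(libs["treated_pol_iv_depleted"])
)
rpm24_t = [r.rpm[24] for r in treated]
rpm24_d = [r.rpm[24] for r in depleted]
print(f"mean 24-nt RPM: treated {sum(rpm24_t)/12:.0f}, POL IV-depleted {sum(rpm24_d)/12:.0f}")
res = paired_abundance_test(rpm24_t, rpm24_d)
print(f"Wilcoxon matched-pairs p = {res.p_value:.4f} ({res.method})")

table = pd.DataFrame({k: [r.rpm[k] for r in treated] for k in (21, 22, 24)})
out = sizeclass_correlation(table)
print("pairwise Pearson r:")
print(out["correlations"].round(2))
for k, (x, y) in out["circle"].items():
    print(f"  {k}-nt loading on PC1/PC2: ({x:+.2f}, {y:+.2f})")
# Strongly co-varying size classes point the same way on the correlation
# circle; a drop of 24-nt RPM in the depleted library reflects the planted
# POL IV dependence of the source regions.
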