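"""Synthetic-data generator: determinism, marginals, planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from uvmethylome import GenomicInterval
from uvmethylome.simulate import (
    GenomeSpec,
    ImageSpec,
    MethylomeSpec,
    SimulationConfig,
    SmallRNASpec,
    cytosine_contexts,
    simulate_damage_reads,
    simulate_genome,
    simulate_methylomes,
    simulate_nucleus_image,
    simulate_smallrna,
)
from uvmethylome.genome import GenomeSequence, assign_context


class TestSimulateGenome:
    def test_determinism(self, small_config):
        g1, a1 = simulate_genome(small_config)
        g2, a2 = simulate_genome(small_config)
        assert g1["chr1"] == g2["chr1"]
        assert a1.features == a2.features
        assert a1.chromatin_states == a2.chromatin_states

    def test_pericentromere_fraction(self):
        cfg = SimulationConfig(
            seed=0,
            genome=GenomeSpec(
                chrom_lengths={"chr1": 100_000}, pericentromere_fraction=0.2
            ),
        )
        _, ann = simulate_genome(cfg)
        assert sum(len(p) for p in ann.pericentromeres) == 20_000

    def test_base_frequencies_uniform(self):
        cfg = SimulationConfig(
            seed=2, genome=GenomeSpec(chrom_lengths={"chr1": 100_000})
        )
        genome, _ = simulate_genome(cfg)
        seq = genome["chr1"]
        se = np.sqrt(0.25 * 0.75 / len(seq))
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=3 * se)

    def test_chromatin_states_tile_without_overlap(self, small_genome):
        _, ann = small_genome
        states = sorted(ann.chromatin_states, key=lambda iv: iv.start)
        assert states[0].start == 0
        for a, b in zip(states, states[1:]):
            assert a.end == b.start


class TestCytosineContexts:
    def test_agrees_with_per_position_assignment(self, small_genome):
        genome, _ = small_genome
        seq = genome["chr1"][:3000]
        sub = GenomeSequence({"chr1": seq})
        table = cytosine_contexts(seq)
        assert len(table)  # sanity
        for _, row in table.sample(200, random_state=0).iterrows():
            assert (
                assign_context(sub, "chr1", int(row["pos"]), row["strand"])
                == row["context"]
            )


class TestSimulateMethylomes:
    def test_determinism(self, small_config, small_genome):
        genome, ann = small_genome
        c1, t1, tr1 = simulate_methylomes(genome, ann, small_config)
        c2, t2, tr2 = simulate_methylomes(genome, ann, small_config)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)
        assert tr1 == tr2

    def test_planted_interval_shifted_mean(self, small_config, small_genome):
        genome, ann = small_genome
        control, treated, truth = simulate_methylomes(genome, ann, small_config)
        t = truth[0]
        sel = (
            (treated["pos"] >= t["start"])
            & (treated["pos"] < t["end"])
            & (treated["context"] == t["context"])
        )
        sub = treated[sel]
        level = sub["n_meth"].sum() / sub["n_total"].sum()
        csel = (
            (control["pos"] >= t["start"])
            & (control["pos"] < t["end"])
            & (control["context"] == t["context"])
        )
        csub = control[csel]
        base = csub["n_meth"].sum() / csub["n_total"].sum()
        n = sub["n_total"].sum()
        se = np.sqrt(0.5 * 0.5 / n)
        assert level - base == pytest.approx(t["delta"], abs=4 * se + 0.02)

    def test_null_config_draws_identical_distributions(self, small_genome):
        genome, ann = small_genome
        cfg = SimulationConfig(
            seed=3,
            genome=GenomeSpec(chrom_lengths={"chr1": 200_000}),
            methylome=MethylomeSpec(dmr_count=0),
        )
        control, treated, truth = simulate_methylomes(genome, ann, cfg)
        assert truth == []
        # same marginal methylation per context within sampling error
        for ctx in ("CG", "CHG", "CHH"):
            lc = control[control["context"] == ctx]
            lt = treated[treated["context"] == ctx]
            mc = lc["n_meth"].sum() / lc["n_total"].sum()
            mt = lt["n_meth"].sum() / lt["n_total"].sum()
            assert mc == pytest.approx(mt, abs=0.01)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            MethylomeSpec(dmr_context="CG", dmr_delta=0.5)  # peri CG 0.85+0.5>1


class TestSimulateDamageReads:
    def test_determinism_and_truth(self, small_config, small_genome):
        genome, ann = small_genome
        ip1, in1, t1 = simulate_damage_reads(genome, ann, small_config)
        ip2, in2, t2 = simulate_damage_reads(genome, ann, small_config)
        pd.testing.assert_frame_equal(ip1, ip2)
        pd.testing.assert_frame_equal(in1, in2)
        assert t1 == t2

    def test_ip_enriched_inside_truth(self, small_config, small_genome):
        genome, ann = small_genome
        ip, inp, truth = simulate_damage_reads(genome, ann, small_config)
        L = genome.lengths["chr1"]
        truth_len = sum(len(t) for t in truth)
        mid_ip = (ip["start"] + ip["end"]) // 2
        in_truth = sum(
            ((mid_ip >= t.start) & (mid_ip < t.end)).sum() for t in truth
        )
        frac_ip = in_truth / len(ip)
        frac_genome = truth_len / L
        assert frac_ip > 3 * frac_genome  # strong enrichment at fold 8


class TestSimulateSmallRNA:
    def test_depleted_library_loses_dependent_reads(self):
        cfg = SimulationConfig(
            seed=4,
            smallrna=SmallRNASpec(
                library_size=50_000, pol_iv_dependent_fraction=1.0
            ),
        )
        sources = [GenomicInterval("chr1", 10_000, 12_000)]
        libs = simulate_smallrna({"chr1": 1_000_000}, sources, cfg)
        dep = libs["treated_pol_iv_depleted"]
        assert dep["from_source"].sum() == 0
        assert libs["treated"]["from_source"].sum() > 0

    def test_region_share_binomial(self):
        cfg = SimulationConfig(
            seed=5, smallrna=SmallRNASpec(library_size=100_000, region_share=0.05)
        )
        sources = [GenomicInterval("chr1", 10_000, 12_000)]
        libs = simulate_smallrna({"chr1": 1_000_000}, sources, cfg)
        n = 100_000
        se = np.sqrt(0.05 * 0.95 / n)
        assert libs["untreated"]["from_source"].mean() == pytest.approx(
            0.05, abs=3 * se
        )

    def test_size_mix_and_determinism(self):
        cfg = SimulationConfig(seed=6, smallrna=SmallRNASpec(library_size=30_000))
        libs1 = simulate_smallrna({"chr1": 500_000}, [], cfg)
        libs2 = simulate_smallrna({"chr1": 500_000}, [], cfg)
        pd.testing.assert_frame_equal(libs1["treated"], libs2["treated"])
        lens = libs1["untreated"]["end"] - libs1["untreated"]["start"]
        assert set(lens.unique()) <= {21, 22, 24}


class TestSimulateNucleusImage:
    def test_truth_matches_construction(self):
        cfg = SimulationConfig(seed=7)
        img, truth = simulate_nucleus_image(cfg)
        for t in truth:
            assert t["co"] == pytest.approx(
                100.0 * t["total_spot_area"] / t["nucleus_area"]
            )
            # drawn CO close to its target (discretisation error only)
            assert t["co"] == pytest.approx(t["co_target"], abs=2.0)

    def test_zero_spots_gives_zero_co(self):
        cfg = SimulationConfig(
            seed=8, image=ImageSpec(co_targets=(0.0,), spots_per_nucleus=0)
        )
        img, truth = simulate_nucleus_image(cfg)
        assert all(t["co"] == 0.0 for t in truth)

    def test_determinism(self):
        cfg = SimulationConfig(seed=9)
        i1, t1 = simulate_nucleus_image(cfg)
        i2, t2 = simulate_nucleus_image(cfg)
        np.testing.assert_array_equal(i1, i2)
        assert t1 == t2

    def test_oversized_spots_rejected(self):
        cfg = SimulationConfig(
            seed=10,
            image=ImageSpec(nucleus_radius_px=8, co_targets=(90.0,), spots_per_nucleus=1),
        )
        with pytest.raises(ValueError):
            simulate_nucleus_image(cfg)
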