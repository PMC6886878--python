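"""Sliding-window DMR caller: windowing, testing, joining, recovery."""

import numpy as np
import pandas as pd
import pytest

from uvmethylome import (
    DMRCallerParams,
    GenomicInterval,
    call_dmrs,
    methylation_at_regions,
    test_window as evaluate_window,
    window_genome,
    window_methylation,
)
from uvmethylome.simulate import (
    GenomeSpec,
    MethylomeSpec,
    SimulationConfig,
    simulate_genome,
    simulate_methylomes,
)

from conftest import make_calls, uniform_window_calls


class TestWindowGenome:
    def test_length_500_gives_three_windows(self):
        w = window_genome({"c": 500})
        assert [(iv.start, iv.end) for iv in w] == [(0, 200), (150, 350), (300, 500)]

    def test_too_short_chromosome(self):
        assert window_genome({"c": 199}) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_count_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(150, 5000))
        params = DMRCallerParams()
        windows = window_genome({"c": L}, params)
        # brute-force loop oracle
        expected = []
        s = 0
        while True:
            if s + params.window_length > L:
                break
            expected.append(s)
            s += params.window_length - params.window_overlap
        assert [iv.start for iv in windows] == expected


class TestWindowMethylation:
    def test_count_weighted(self):
        calls = make_calls(
            [("c", 10, "+", "CHH", 5, 10), ("c", 20, "+", "CHH", 2, 40)]
        )
        level, n = window_methylation(calls)
        assert level == pytest.approx(7 / 50)
        assert n == 2

    def test_mean_of_ratios_alternative(self):
        calls = make_calls(
            [("c", 10, "+", "CHH", 5, 10), ("c", 20, "+", "CHH", 2, 40)]
        )
        level, _ = window_methylation(calls, weighted=False)
        assert level == pytest.approx((0.5 + 0.05) / 2)

    def test_empty_is_nan(self):
        level, n = window_methylation(make_calls([]))
        assert np.isnan(level) and n == 0

    def test_fully_methylated(self):
        calls = make_calls([("c", i, "+", "CG", 10, 10) for i in range(4)])
        assert window_methylation(calls)[0] == 1.0


class TestTestWindow:
    def test_exact_chh_example(self):
        """Six matched CHH positions, control 0.0 vs treated 0.2: delta above
        the CHH threshold with exact Wilcoxon p = 0.03125 → retained."""
        iv = GenomicInterval("c", 0, 200)
        control = uniform_window_calls("c", 0, 180, "CHH", 0.0, step=30)
        treated = uniform_window_calls("c", 0, 180, "CHH", 0.2, step=30)
        res = evaluate_window(control, treated, iv, "CHH")
        assert res.n_sites == 6
        assert res.delta == pytest.approx(0.2)
        assert res.p_value == pytest.approx(2 / 64)
        assert res.retained

    def test_identical_samples_not_retained(self):
        iv = GenomicInterval("c", 0, 200)
        calls = uniform_window_calls("c", 0, 200, "CHH", 0.1, step=25)
        res = evaluate_window(calls, calls.copy(), iv, "CHH")
        assert res.delta == 0.0
        assert not res.retained

    def test_subthreshold_delta_not_retained(self):
        iv = GenomicInterval("c", 0, 200)
        control = uniform_window_calls("c", 0, 200, "CHH", 0.0, coverage=100, step=25)
        treated = uniform_window_calls("c", 0, 200, "CHH", 0.09, coverage=100, step=25)
        res = evaluate_window(control, treated, iv, "CHH")
        assert abs(res.delta) < 0.1
        assert not res.retained

    def test_threshold_is_inclusive(self):
        iv = GenomicInterval("c", 0, 200)
        control = uniform_window_calls("c", 0, 200, "CHH", 0.0, coverage=10, step=25)
        treated = uniform_window_calls("c", 0, 200, "CHH", 0.1, coverage=10, step=25)
        res = evaluate_window(
            control, treated, iv, "CHH", DMRCallerParams(alpha=None)
        )
        assert res.retained

    def test_too_few_matched_sites_skipped(self):
        iv = GenomicInterval("c", 0, 200)
        control = uniform_window_calls("c", 0, 90, "CHH", 0.0, step=30)  # 3 sites
        treated = uniform_window_calls("c", 0, 90, "CHH", 0.3, step=30)
        assert evaluate_window(control, treated, iv, "CHH") is None

    def test_low_coverage_sites_excluded(self):
        iv = GenomicInterval("c", 0, 200)
        control = uniform_window_calls("c", 0, 200, "CHH", 0.0, coverage=3, step=25)
        treated = uniform_window_calls("c", 0, 200, "CHH", 1.0, coverage=3, step=25)
        assert evaluate_window(control, treated, iv, "CHH") is None


def bruteforce_call_oracle(control, treated, chrom_lengths, params):
    """Naive scan: test every window with test_window, join by hand."""
    retained = []
    for iv in window_genome(chrom_lengths, params):
        for ctx in ("CG", "CHG", "CHH"):
            res = evaluate_window(control, treated, iv, ctx, params)
            if res is not None and res.retained:
                retained.append(res)
    joined = {}
    for ctx in ("CG", "CHG", "CHH"):
        winds = sorted(
            (w for w in retained if w.context == ctx),
            key=lambda w: (w.interval.chrom, np.sign(w.delta), w.interval.start),
        )
        dmrs = []
        for w in winds:
            if (
                dmrs
                and dmrs[-1][0] == w.interval.chrom
                and dmrs[-1][3] == np.sign(w.delta)
                and w.interval.start <= dmrs[-1][2]
            ):
                dmrs[-1][2] = max(dmrs[-1][2], w.interval.end)
            else:
                dmrs.append(
                    [w.interval.chrom, w.interval.start, w.interval.end, np.sign(w.delta)]
                )
        joined[ctx] = sorted((c, s, e) for c, s, e, _ in dmrs)
    return joined


class TestCallDmrs:
    def test_join_rule_overlapping_windows(self):
        control = uniform_window_calls("c", 0, 350, "CHH", 0.0, step=25)
        treated = uniform_window_calls("c", 0, 350, "CHH", 0.2, step=25)
        dmrs = call_dmrs(control, treated, {"c": 350})
        assert len(dmrs["CHH"]) == 1
        d = dmrs["CHH"][0]
        assert (d.interval.start, d.interval.end) == (0, 350)
        assert d.n_windows == 2
        assert d.direction == "hyper"

    def test_opposite_directions_not_joined(self):
        c1 = uniform_window_calls("c", 0, 200, "CHH", 0.0, step=25)
        t1 = uniform_window_calls("c", 0, 200, "CHH", 0.2, step=25)
        # hypo signal in the next non-overlapping stretch
        c2 = uniform_window_calls("c", 300, 500, "CHH", 0.2, step=25)
        t2 = uniform_window_calls("c", 300, 500, "CHH", 0.0, step=25)
        control = pd.concat([c1, c2], ignore_index=True)
        treated = pd.concat([t1, t2], ignore_index=True)
        dmrs = call_dmrs(control, treated, {"c": 500})
        dirs = sorted(d.direction for d in dmrs["CHH"])
        assert dirs == ["hyper", "hypo"]

    def test_empty_tables(self):
        empty = make_calls([])
        out = call_dmrs(empty, empty, {"c": 1000})
        assert all(len(v) == 0 for v in out.values())

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        control = uniform_window_calls("c", 0, 800, "CHH", 0.1, coverage=10, step=20)
        treated = uniform_window_calls("c", 0, 800, "CHH", 0.4, coverage=10, step=20)
        shuffled_c = control.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled_t = treated.sample(frac=1, random_state=2).reset_index(drop=True)
        a = call_dmrs(control, treated, {"c": 800})
        b = call_dmrs(shuffled_c, shuffled_t, {"c": 800})
        for ctx in a:
            assert [
                (d.interval.start, d.interval.end, d.direction) for d in a[ctx]
            ] == [(d.interval.start, d.interval.end, d.direction) for d in b[ctx]]

    def test_matches_bruteforce_oracle_on_toy_genome(self):
        """Vectorised caller equals the naive every-window scan on a 100-kb
        synthetic methylome with planted DMRs."""
        cfg = SimulationConfig(
            seed=5,
            genome=GenomeSpec(chrom_lengths={"chr1": 100_000}),
            methylome=MethylomeSpec(dmr_count=6),
        )
        genome, ann = simulate_genome(cfg)
        control, treated, _ = simulate_methylomes(genome, ann, cfg)
        params = DMRCallerParams()
        fast = call_dmrs(control, treated, genome.lengths, params)
        oracle = bruteforce_call_oracle(control, treated, genome.lengths, params)
        for ctx in ("CG", "CHG", "CHH"):
            got = sorted(
                (d.interval.chrom, d.interval.start, d.interval.end)
                for d in fast[ctx]
            )
            assert got == oracle[ctx]

    def test_reported_dmrs_have_consistent_direction(self):
        cfg = SimulationConfig(
            seed=9,
            genome=GenomeSpec(chrom_lengths={"chr1": 150_000}),
            methylome=MethylomeSpec(dmr_count=5),
        )
        genome, ann = simulate_genome(cfg)
        control, treated, _ = simulate_methylomes(genome, ann, cfg)
        dmrs = call_dmrs(control, treated, genome.lengths)
        for ctx, lst in dmrs.items():
            for d in lst:
                assert abs(d.delta) > 0
                assert d.direction == ("hyper" if d.delta > 0 else "hypo")


class TestMethylationAtRegions:
    def test_region_equals_window(self):
        calls = uniform_window_calls("c", 0, 200, "CHH", 0.2, step=25)
        region = GenomicInterval("c", 0, 200)
        levels = methylation_at_regions(calls, [region], "CHH")
        assert levels[0] == pytest.approx(0.2)

    def test_empty_region_is_nan(self):
        calls = uniform_window_calls("c", 0, 200, "CHH", 0.2, step=25)
        levels = methylation_at_regions(calls, [GenomicInterval("c", 5000, 5200)])
        assert np.isnan(levels[0])

    def test_matches_per_cytosine_summation(self):
        rng = np.random.default_rng(4)
        rows = [
            ("c", int(p), "+", "CG", int(m), 20)
            for p, m in zip(rng.integers(0, 1000, 50), rng.integers(0, 21, 50))
        ]
        calls = make_calls(rows)
        region = GenomicInterval("c", 100, 700)
        sel = [(p, m) for (_, p, _, _, m, _) in rows if 100 <= p < 700]
        expected = sum(m for _, m in sel) / (20 * len(sel))
        assert methylation_at_regions(calls, [region], "CG")[0] == pytest.approx(expected)
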