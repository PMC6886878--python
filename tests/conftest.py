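import pandas as pd
import pytest

from uvmethylome.simulate import GenomeSpec, SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11, genome=GenomeSpec(chrom_lengths={"chr1": 200_000})
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


def make_calls(rows) -> pd.DataFrame:
    """Build a call table from (chrom, pos, strand, context, n_meth, n_total)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )


def uniform_window_calls(
    chrom, start, end, context, ratio, coverage=20, step=25, strand="+"
) -> pd.DataFrame:
    """Evenly spaced cytosines across [start, end) with a fixed methylation
    ratio; n_meth = ratio * coverage must be integral."""
    n_meth = ratio * coverage
    assert abs(n_meth - round(n_meth)) < 1e-9
    rows = [
        (chrom, pos, strand, context, int(round(n_meth)), coverage)
        for pos in range(start, end, step)
    ]
    return make_calls(rows)
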