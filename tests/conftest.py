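import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from allelic import ChromSpec, ReadSim, SnpTable, simulate_chip_reads

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("allelic").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def snp_table_small() -> SnpTable:
    """Four informative SNPs on two chromosomes."""
    return SnpTable(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "pos": [100, 150, 400, 50],
                "a1": ["G", "A", "T", "C"],
                "a2": ["C", "T", "G", "A"],
            }
        ),
        chrom_lengths={"chr1": 1000, "chr2": 500},
    )


@pytest.fixture(scope="session")
def trisomic_sim():
    """A small error-free 1:2-copy simulation shared by several tests."""
    chrom = ChromSpec("chr15", 500_000, copies_a1=1, copies_a2=2, snp_density=2.0)
    sim = ReadSim(read_length=100, background_rate=1.0, error_rate=0.0, n_clones=2, seed=42)
    reads, snps, truth = simulate_chip_reads([chrom], [], sim)
    return chrom, sim, reads, snps, truth


def binom_ci_contains(k: int, n: int, p: float, z: float = 4.0) -> bool:
    """Normal-approximation check that k/n is within z SEs of p."""
    se = np.sqrt(p * (1 - p) / n)
    return abs(k / n - p) <= z * se
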