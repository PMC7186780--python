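import numpy as np
import pytest

from rhoscape import HaplotypeBlock, SimConfig, build_truth_map, simulate_haplotypes


@pytest.fixture(scope="session")
def small_block() -> HaplotypeBlock:
    """19 haplotypes over 100 kb, uniform rho = 0.004, theta = 0.03."""
    cfg = SimConfig(seq_length=100_000, background_rho=0.004,
                    hotspot_spec=(), seed=1234)
    return simulate_haplotypes(cfg, build_truth_map(cfg))


@pytest.fixture()
def toy_block() -> HaplotypeBlock:
    """Hand-built 4-haplotype block for exact LD arithmetic."""
    genotypes = np.array([        # rows = samples, columns = sites
        [0, 0, 0, 0],
        [0, 1, 0, 0],
        [1, 0, 1, 1],
        [1, 1, 1, 1],
    ], dtype=np.int8)
    return HaplotypeBlock(
        chromosome="chr1",
        positions=np.array([100, 300, 700, 1500]),
        genotypes=genotypes,
        ref=np.array(list("ACGT")),
        alt=np.array(list("GTAC")),
        sequence_length=2000,
    )
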