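import numpy as np
import pytest

from sarcopred import (
    GenotypePanel,
    SimulationConfig,
    VariantKey,
    simulate_study,
)


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study under the default conditions, shared
    across tests (deterministic under its fixed seed)."""
    config = SimulationConfig(seed=1)
    panel, sumstats, truth = simulate_study(config)
    return config, panel, sumstats, truth


@pytest.fixture
def small_panel():
    """A tiny hand-checkable panel: 4 samples x 3 variants, one missing call."""
    variants = [
        VariantKey("rs1", "A", "G", chrom="1", pos=100),
        VariantKey("rs2", "C", "T", chrom="1", pos=200),
        VariantKey("rs3", "A", "C", chrom="2", pos=300),
    ]
    dosages = np.array(
        [
            [0, 2, 1],
            [1, 1, 0],
            [2, 0, -1],
            [1, 2, 2],
        ],
        dtype=np.int16,
    )
    return GenotypePanel(
        sample_ids=["s1", "s2", "s3", "s4"],
        variants=variants,
        dosages=dosages,
        counted_alleles=["G", "T", "C"],
    )
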