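import numpy as np
import pytest

from pirnakit.io_formats import Assembly
from pirnakit.synthetic import (
    GenomeConfig,
    HybridConfig,
    PirnaConfig,
    SimulationConfig,
    generate_genome_pair,
)


def random_assembly(seed: int, length: int = 5000, name: str = "chr1") -> Assembly:
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return Assembly({name: seq}, source_label=f"rand{seed}")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study conditions shared by the slower fixtures."""
    return SimulationConfig(
        seed=11,
        genome=GenomeConfig(contig_length=60_000),
        pirna=PirnaConfig(cluster_span=10_000, n_reads=2_000),
        hybrid=HybridConfig(n_reads=4_000),
    )


@pytest.fixture(scope="session")
def genome_pair(small_config):
    return generate_genome_pair(small_config)
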