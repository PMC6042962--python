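import numpy as np
import pytest

from chromark import simulate as sim
from chromark.model import CoverageTrack


@pytest.fixture(scope="session")
def genome():
    """Small deterministic genome: 1 chromosome, 100 kb, 20 genes."""
    return sim.generate_genome(
        n_chroms=1, chrom_length=100_000, n_genes=20, frac_non_polII=0.1, seed=0
    )


@pytest.fixture(scope="session")
def polII_ids(genome):
    return [g.gene_id for g in genome if g.polymerase == "PolII"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def constant_track(value: float, length: int = 10_000, chrom: str = "chr1",
                   sample_id: str = "t") -> CoverageTrack:
    return CoverageTrack(sample_id, {chrom: np.full(length, float(value))})
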