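import numpy as np
import pytest

from zfpkit import simulate as sim
from zfpkit.io_formats import EnrichedWindow, GeneModel


@pytest.fixture(scope="session")
def small_annotation() -> dict[str, GeneModel]:
    """Deterministic 60-gene annotation used across interval tests."""
    return sim.make_annotation(sim.SimConfig(seed=11, n_genes=60))


@pytest.fixture
def two_exon_gene() -> GeneModel:
    """'+' strand, exons [1000,2000) and [3000,5000), CDS [1500,3600)."""
    return GeneModel(
        "gX", "chr1", "+", 1000, 5000,
        exons=[(1000, 2000), (3000, 5000)],
        utr5=[(1000, 1500)], cds=[(1500, 2000), (3000, 3600)], utr3=[(3600, 5000)],
    )


def make_window(start: int, end: int, gene_id: str = "gX",
                strand: str = "+", chrom: str = "chr1") -> EnrichedWindow:
    return EnrichedWindow(chrom, start, end, strand, gene_id,
                          odds_ratio=10.0, fdr=0.01)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
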