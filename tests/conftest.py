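import numpy as np
import pytest

from psgscan.io_formats import GeneModel
from psgscan.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One small but complete synthetic study shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_genes=60, n_codons=60, site_spacing=30)
    return simulate_study(cfg)


@pytest.fixture
def plus_gene():
    """+strand gene, 2 exons, UTRs on both terminal exons.

    Layout (0-based half-open): tx 5000-6500, exon1 5000-5600
    (UTR5 5000-5200, CDS part 5200-5600), intron 5600-5900,
    exon2 5900-6500 (CDS part 5900-6300, UTR3 6300-6500).
    """
    return GeneModel(
        gene_id="gplus", chrom="Chr01", strand="+",
        tx_start=5000, tx_end=6500,
        exons=((5000, 5600), (5900, 6500)),
        cds_start=5200, cds_end=6300,
    )


@pytest.fixture
def minus_gene():
    """-strand mirror of plus_gene: TSS at the high-coordinate end (8000)."""
    return GeneModel(
        gene_id="gminus", chrom="Chr01", strand="-",
        tx_start=6500, tx_end=8000,
        exons=((6500, 7100), (7400, 8000)),
        cds_start=6700, cds_end=7800,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
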