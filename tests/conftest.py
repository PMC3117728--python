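import numpy as np
import pytest

from mhdiv.io_model import CodonAlignment, GenotypeTable
from mhdiv.synthetic_data import SimConfig, gen_allele_pool, gen_panel


@pytest.fixture
def toy_alignment():
    """4 short in-frame alleles with a mix of syn/nonsyn variation."""
    return CodonAlignment(
        ("a1", "a2", "a3", "a4"),
        (
            "ATGGCTAAAGGA",
            "ATGGCTAAAGGG",  # syn change at codon 4 (GGA->GGG)
            "ATGGCGAAAGGA",  # syn change at codon 2 (GCT->GCG)
            "ATGACTAAAGGA",  # nonsyn at codon 2 (GCT->ACT, Ala->Thr)
        ),
    )


@pytest.fixture
def toy_genotypes():
    return GenotypeTable(
        {"i1": ("a1", "a2"), "i2": ("a1", "a1"), "i3": ("a3", "a4")}
    )


@pytest.fixture(scope="session")
def default_pool():
    """Seeded 17-allele pool with 2 planted recombinants (90 codons)."""
    cfg = SimConfig(seed=11, n_recombinants=2)
    return gen_allele_pool(cfg)


@pytest.fixture(scope="session")
def default_panel(default_pool):
    pool, _ = default_pool
    cfg = SimConfig(seed=13, panel_size=101)
    return gen_panel(pool, cfg, np.random.default_rng(13))
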