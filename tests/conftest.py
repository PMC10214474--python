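import numpy as np
import pandas as pd
import pytest

from riboprof.model import GeneModel
from riboprof.simulate import SimulationConfig


@pytest.fixture
def toy_gene() -> GeneModel:
    """30 nt 5'UTR, 30 nt CDS, 30 nt 3'UTR; no uORF in the UTR."""
    utr5 = "CCAACCAACCAACCAACCAACCAACCAACC"
    cds = "ATG" + "GCA" * 8 + "TAA"
    utr3 = "TTGTTGTTGTTGTTGTTGTTGTTGTTGTTG"
    g = GeneModel(gene_id="toy", sequence=utr5 + cds + utr3,
                  utr5=(0, 30), cds=(30, 60), utr3=(60, 90))
    g.validate()
    return g


@pytest.fixture
def toy_genes(toy_gene) -> list[GeneModel]:
    other = GeneModel(gene_id="toy2",
                      sequence="A" * 20 + "ATG" + "CCA" * 98 + "TGA" + "G" * 25,
                      utr5=(0, 20), cds=(20, 320), utr3=(320, 345))
    other.validate()
    return [toy_gene, other]


def make_reads(rows) -> pd.DataFrame:
    """rows: iterable of (gene_id, start, length, library, sample)."""
    return pd.DataFrame(rows, columns=["gene_id", "start", "length",
                                       "library", "sample"])


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=120, reads_per_library=20_000, seed=11,
                            te_effect_genes=0.2,
                            feature_plant={"uorf": 1.0, "top": 1.0,
                                           "pg4": 1.0, "high_gc": 1.0,
                                           "long_utr": 1.0})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
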