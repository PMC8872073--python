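import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/helpers.py

from dupshift.records import GeneRecord
from dupshift.simulate import SimulationConfig, generate_pairs, truth_frame


@pytest.fixture(scope="session")
def small_dataset():
    """24 simulated pairs with all scenario types, shared across tests."""
    cfg = SimulationConfig(
        seed=101,
        n_pairs=24,
        ancestor_len_codons=200,
        t_post=0.05,
        scenario_mix={"C": 0.5, "N": 0.25, "M": 0.25},
    )
    genes, truths = generate_pairs(cfg)
    return cfg, genes, truths, truth_frame(truths)


@pytest.fixture()
def toy_gene():
    cds = (
        "ATGGCTGAAGATCTGAAACGTTGGTTTGCTGAAGATCTGAAACGTTGGTTTGCTGAAGAT"
        "CTGAAACGTTGGTTTGCTGAAGATCTGAAATAA"
    )
    return GeneRecord(gene_id="g1", species="sp1", transcripts=[cds])


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
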