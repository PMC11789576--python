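import numpy as np
import pytest
import scipy.sparse as sp

import snpipe


@pytest.fixture(scope="session")
def tiny_sim_config() -> snpipe.SimConfig:
    """A small but complete read-simulation condition used across tests."""
    return snpipe.SimConfig(
        seed=42,
        n_cells_A=15,
        n_cells_B=15,
        reads_per_cell=40,
        collision_rate=0.05,
        droplet_whitelist_size=200,
        n_genes={"protein_coding": 30, "lncRNA": 15, "snoRNA": 2, "snRNA": 2, "miRNA": 2, "other": 2},
    )


@pytest.fixture(scope="session")
def tiny_transcriptome(tiny_sim_config):
    return snpipe.simulate_transcriptome(tiny_sim_config)


@pytest.fixture(scope="session")
def tiny_reads(tiny_sim_config, tiny_transcriptome, tmp_path_factory):
    genes, seqs = tiny_transcriptome
    outdir = tmp_path_factory.mktemp("reads")
    truth = snpipe.simulate_reads(tiny_sim_config, genes, seqs, outdir)
    return outdir, truth


def random_count_matrix(rng: np.random.Generator, n_cells: int, n_genes: int) -> snpipe.CountMatrix:
    counts = rng.poisson(2.0, size=(n_cells, n_genes))
    return snpipe.CountMatrix(
        sp.csr_matrix(counts),
        [f"c{i}" for i in range(n_cells)],
        [f"g{i}" for i in range(n_genes)],
    )
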