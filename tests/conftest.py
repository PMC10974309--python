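import numpy as np
import pytest

from evesurveyor import phylo, synthetic_data as sd


@pytest.fixture(scope="session")
def jtt():
    return phylo.JttModel()


@pytest.fixture(scope="session")
def planted_genome():
    """One genome with two intronic insertions (opposite/same orientation),
    shared across read-level tests."""
    cfg = sd.SimulationConfig(
        seed=7,
        contig_lengths=[20000, 15000],
        gene_specs=[(3, 300, 2000, "+"), (2, 400, 2500, "-")],
        insertion_specs=[
            sd.InsertionSpec("vNcP1", 100, aa_divergence=0.30,
                             orientation="OPPOSITE"),
            sd.InsertionSpec("vNcP2", 100, aa_divergence=0.20,
                             orientation="SAME"),
        ],
    )
    genome, genes, truth = sd.simulate_genome(cfg)
    return cfg, genome, genes, truth


def make_config(seed, insertions=None, contigs=(20000,),
                gene_specs=((3, 300, 2000, "+"),)):
    return sd.SimulationConfig(
        seed=seed,
        contig_lengths=list(contigs),
        gene_specs=[tuple(g) for g in gene_specs],
        insertion_specs=list(insertions or []),
    )
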