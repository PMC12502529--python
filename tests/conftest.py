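import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from natspec.genome_io import GeneRecord, GenomeRecord
from natspec.ortholog_table import core_genes
from natspec.synthetic_data import SimulationConfig, simulate_panel, \
    two_clade_newick

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_genome(genome_id: str, sequences: dict[str, str],
                feature_type: str = "CDS") -> GenomeRecord:
    """Genome from pre-extracted genes, each on its own contig."""
    genes = [
        GeneRecord(gene_id=gid, genome_id=genome_id, sequence=seq,
                   contig=gid, start=0, end=len(seq), strand="+",
                   feature_type=feature_type)
        for gid, seq in sequences.items()
    ]
    return GenomeRecord(genome_id=genome_id,
                        contigs={g.gene_id: g.sequence for g in genes},
                        genes=genes)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def panel6():
    """Two 3-strain clades split by a deep branch, with gene loss.

    Divergences are chosen so that within-clade pairs keep a large fraction
    of identical genes (~55%) while cross-clade pairs keep ~1%.
    """
    config = SimulationConfig(
        tree_newick=two_clade_newick(3, deep=0.0067, shallow=0.001),
        n_genes=60, gene_length=(300, 300), rate_shape=None,
        loss_prob=0.02, include_16s=True, seed=7)
    genomes, truth = simulate_panel(config)
    return config, genomes, truth


@pytest.fixture(scope="session")
def panel6_core(panel6):
    _, genomes, _ = panel6
    return core_genes(genomes)
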