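"""FASTA/GFF3 ingestion, coordinate conventions, and genome statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from natspec.errors import CoordinateError, EmptyInputError, FormatError
from natspec.genome_io import (FEATURE_16S, genome_stats, read_genome,
                               write_gene_fasta, write_genome_fasta,
                               write_gff3)
from natspec.pairwise_align import reverse_complement
from natspec.synthetic_data import SimulationConfig, simulate_panel

from conftest import make_genome


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


@pytest.fixture
def toy_inputs(tmp_path):
    fasta = _write(tmp_path, "g.fna", ">chr1\nATGAAATAG\n")
    gff = _write(tmp_path, "g.gff3", "\n".join([
        "##gff-version 3",
        "chr1\t.\tCDS\t1\t9\t.\t+\t0\tID=geneA",
    ]) + "\n")
    return fasta, gff


def test_plus_strand_cds_is_identity_slice(toy_inputs):
    genome = read_genome(*toy_inputs)
    assert [g.sequence for g in genome.genes] == ["ATGAAATAG"]
    assert genome.genes[0].start == 0 and genome.genes[0].end == 9


def test_minus_strand_cds_is_reverse_complement(tmp_path):
    fasta = _write(tmp_path, "g.fna", ">chr1\nATGAAATAG\n")
    gff = _write(tmp_path, "g.gff3",
                 "##gff-version 3\nchr1\t.\tCDS\t1\t9\t.\t-\t0\tID=geneA\n")
    genome = read_genome(fasta, gff)
    assert genome.genes[0].sequence == "CTATTTCAT"


def test_16s_rrna_feature_is_classified(tmp_path):
    fasta = _write(tmp_path, "g.fna", ">c\n" + "ACGT" * 10 + "\n")
    gff = _write(tmp_path, "g.gff3", "\n".join([
        "##gff-version 3",
        "c\t.\trRNA\t1\t12\t.\t+\t.\tID=r1;product=16S ribosomal RNA",
        "c\t.\trRNA\t13\t24\t.\t+\t.\tID=r2;product=23S ribosomal RNA",
    ]) + "\n")
    genome = read_genome(fasta, gff)
    types = {g.gene_id: g.feature_type for g in genome.genes}
    assert types["r1"] == FEATURE_16S
    assert types["r2"] == "other"


def test_without_gff_each_record_is_a_gene(tmp_path):
    fasta = _write(tmp_path, "genes.fna", ">g1\nATGA\n>g2\nCCGG\n")
    genome = read_genome(fasta)
    assert [g.sequence for g in genome.genes] == ["ATGA", "CCGG"]


def test_feature_outside_contig_raises(tmp_path):
    fasta = _write(tmp_path, "g.fna", ">chr1\nATGAAATAG\n")
    gff = _write(tmp_path, "g.gff3",
                 "##gff-version 3\nchr1\t.\tCDS\t1\t50\t.\t+\t0\tID=bad\n")
    with pytest.raises(CoordinateError):
        read_genome(fasta, gff)


def test_ambiguity_codes_other_than_n_are_rejected(tmp_path):
    fasta = _write(tmp_path, "g.fna", ">chr1\nATGRAATAG\n")
    with pytest.raises(FormatError):
        read_genome(fasta)


def test_duplicate_gene_ids_are_disambiguated(tmp_path):
    fasta = _write(tmp_path, "g.fna", ">c\nATGAAATAGATGAAATAG\n")
    gff = _write(tmp_path, "g.gff3", "\n".join([
        "##gff-version 3",
        "c\t.\tCDS\t1\t9\t.\t+\t0\tID=dup",
        "c\t.\tCDS\t10\t18\t.\t+\t0\tID=dup",
    ]) + "\n")
    genome = read_genome(fasta, gff)
    assert len({g.gene_id for g in genome.genes}) == 2


def test_simulated_genome_round_trips_byte_identically(tmp_path):
    config = SimulationConfig(tree_newick="(X:0.01,Y:0.02);", n_genes=10,
                              gene_length=(60, 120), seed=5)
    genomes, _ = simulate_panel(config)
    for genome in genomes:
        fasta = tmp_path / f"{genome.genome_id}.fna"
        gff = tmp_path / f"{genome.genome_id}.gff3"
        write_genome_fasta(genome, str(fasta))
        write_gff3(genome, str(gff))
        again = read_genome(str(fasta), str(gff))
        assert again.contigs == genome.contigs
        orig = {g.gene_id: g for g in genome.genes}
        assert set(g.gene_id for g in again.genes) == set(orig)
        for g in again.genes:
            o = orig[g.gene_id]
            assert (g.sequence, g.start, g.end, g.strand) == \
                (o.sequence, o.start, o.end, o.strand)


def test_gene_fasta_written_in_reading_orientation(tmp_path):
    config = SimulationConfig(tree_newick="(X:0.0,Y:0.0);", n_genes=4,
                              gene_length=(30, 30), seed=1)
    genomes, _ = simulate_panel(config)
    out = tmp_path / "genes.fna"
    write_gene_fasta(genomes[0], str(out))
    again = read_genome(str(out))
    orig = {g.gene_id: g.sequence for g in genomes[0].genes}
    assert {g.gene_id: g.sequence for g in again.genes} == orig


@pytest.mark.parametrize("seq,gc,length", [
    ("GGCC", 100.0, 4),
    ("ATGC", 50.0, 4),
    ("ATGCNN", 50.0, 6),  # ambiguous bases excluded from the GC ratio
])
def test_genome_stats_worked_examples(seq, gc, length):
    genome = make_genome("g", {"x": seq})
    stats = genome_stats(genome)
    assert stats["gc_percent"] == pytest.approx(gc)
    assert stats["length_bp"] == length
    assert stats["n_genes"] == 1


@given(st.text(alphabet="ACGTN", min_size=1, max_size=200).filter(
    lambda s: set(s) != {"N"}))
def test_gc_percent_invariant_under_reverse_complement(seq):
    g1 = make_genome("a", {"x": seq})
    g2 = make_genome("b", {"x": reverse_complement(seq)})
    assert genome_stats(g1)["gc_percent"] == \
        pytest.approx(genome_stats(g2)["gc_percent"])


def test_empty_genome_raises():
    with pytest.raises(EmptyInputError):
        genome_stats(make_genome("g", {}))
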