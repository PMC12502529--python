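"""Genome and gene records, FASTA/GFF3 ingestion, and basic genome statistics.

Coordinates are stored 0-based half-open internally; GFF3 input is 1-based
inclusive and converted on read. A gene on the '-' strand stores the reverse
complement of its contig slice, i.e. the sequence in reading orientation.

Only ``A C G T N`` are accepted; other IUPAC ambiguity codes are rejected at
parse time so that the downstream zero-degeneracy statistic stays well
defined on finished genomes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import CoordinateError, EmptyInputError, FormatError
from .pairwise_align import reverse_complement

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

FEATURE_CDS = "CDS"
FEATURE_16S = "rRNA_16S"
FEATURE_OTHER = "other"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: sequence in reading orientation plus provenance."""

    gene_id: str
    genome_id: str
    sequence: str
    contig: str
    start: int  # 0-based
    end: int    # half-open
    strand: str  # '+' or '-'
    feature_type: str = FEATURE_CDS

    def __post_init__(self):
        if self.end <= self.start:
            raise CoordinateError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})")
        if len(self.sequence) != self.end - self.start:
            raise CoordinateError(
                f"gene {self.gene_id}: sequence length {len(self.sequence)} "
                f"!= end - start ({self.end - self.start})")
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class GenomeRecord:
    """A genome: named contigs plus the genes annotated on them."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)
    accession: str | None = None

    def validate(self) -> None:
        if not self.contigs:
            raise EmptyInputError(f"genome {self.genome_id} has no contigs")
        for g in self.genes:
            if g.contig not in self.contigs:
                raise CoordinateError(
                    f"gene {g.gene_id}: contig {g.contig!r} not in genome {self.genome_id}")
            clen = len(self.contigs[g.contig])
            if g.end > clen:
                raise CoordinateError(
                    f"gene {g.gene_id}: end {g.end} beyond contig {g.contig} "
                    f"length {clen}")
            slice_ = self.contigs[g.contig][g.start:g.end]
            expect = slice_ if g.strand == "+" else reverse_complement(slice_)
            if g.sequence != expect:
                raise CoordinateError(
                    f"gene {g.gene_id}: sequence does not match its contig slice")

    def cds_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.feature_type == FEATURE_CDS]

    def rrna_16s(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.feature_type == FEATURE_16S]


def _check_alphabet(seq: str, name: str, path: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FormatError(
            f"{path}: record {name!r} contains non-ACGTN character(s) "
            f"{sorted(bad)}; ambiguity codes other than N are not supported")
    return seq


def _classify_feature(ftype: str, attributes: dict) -> str | None:
    """Map a GFF3 feature to an internal feature class (None = skip)."""
    if ftype == "CDS":
        return FEATURE_CDS
    if ftype == "rRNA":
        words = []
        for key in ("product", "Name", "gene", "note"):
            words.extend(str(v) for v in attributes.get(key, []))
        text = " ".join(words).lower()
        return FEATURE_16S if "16s" in text else FEATURE_OTHER
    return None


def read_genome(fasta_path: str, gff_path: str | None = None,
                genome_id: str | None = None,
                accession: str | None = None) -> GenomeRecord:
    """Read a genome from FASTA (+ optional GFF3) into a :class:`GenomeRecord`.

    With a GFF3, CDS and rRNA features are extracted ('-' strand genes are
    reverse complemented). Without one, each FASTA record is treated as one
    pre-extracted gene on its own single-gene contig.
    """
    import gffutils

    fasta_path = str(fasta_path)
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(fasta_path))[0]
    try:
        records = list(SeqIO.parse(fasta_path, "fasta"))
    except (ValueError, IOError) as exc:
        raise FormatError(f"{fasta_path}: cannot parse FASTA: {exc}") from exc
    if not records:
        raise EmptyInputError(f"{fasta_path}: no FASTA records")
    contigs: dict[str, str] = {}
    for rec in records:
        if rec.id in contigs:
            raise FormatError(f"{fasta_path}: duplicate record id {rec.id!r}")
        contigs[rec.id] = _check_alphabet(str(rec.seq), rec.id, fasta_path)

    genome = GenomeRecord(genome_id=genome_id, contigs=contigs, accession=accession)
    seen: dict[str, int] = {}

    def _unique_id(raw: str) -> str:
        if raw not in seen:
            seen[raw] = 0
            return raw
        seen[raw] += 1
        new = f"{raw}_{seen[raw]}"
        logger.warning("duplicate gene id %r disambiguated as %r", raw, new)
        return new

    if gff_path is None:
        for rec_id, seq in contigs.items():
            genome.genes.append(GeneRecord(
                gene_id=_unique_id(rec_id), genome_id=genome_id, sequence=seq,
                contig=rec_id, start=0, end=len(seq), strand="+",
                feature_type=FEATURE_CDS))
        genome.validate()
        return genome

    try:
        db = gffutils.create_db(str(gff_path), ":memory:",
                                merge_strategy="create_unique", keep_order=True)
    except Exception as exc:
        raise FormatError(f"{gff_path}: cannot parse GFF3: {exc}") from exc

    for feat in db.all_features(order_by=("seqid", "start")):
        ftype = _classify_feature(feat.featuretype, dict(feat.attributes))
        if ftype is None:
            continue
        if feat.seqid not in contigs:
            raise CoordinateError(
                f"{gff_path}: feature {feat.id!r} on unknown contig {feat.seqid!r}")
        start, end = feat.start - 1, feat.end  # GFF3 1-based inclusive -> half-open
        contig_seq = contigs[feat.seqid]
        if start < 0 or end > len(contig_seq):
            raise CoordinateError(
                f"{gff_path}: feature {feat.id!r} ({feat.start}..{feat.end}) outside "
                f"contig {feat.seqid} (length {len(contig_seq)})")
        strand = feat.strand if feat.strand in "+-" else "+"
        seq = contig_seq[start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        raw_id = feat.attributes.get("ID", [feat.id or f"{feat.seqid}:{feat.start}"])[0]
        genome.genes.append(GeneRecord(
            gene_id=_unique_id(raw_id), genome_id=genome_id, sequence=seq,
            contig=feat.seqid, start=start, end=end, strand=strand,
            feature_type=ftype))
    genome.validate()
    return genome


def write_genome_fasta(genome: GenomeRecord, path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_gene_fasta(genome: GenomeRecord, path: str) -> None:
    """Per-genome gene FASTA (sequences in reading orientation)."""
    with open(path, "w") as fh:
        for g in genome.genes:
            fh.write(f">{g.gene_id} {g.contig}:{g.start + 1}-{g.end}({g.strand}) "
                     f"{g.feature_type}\n")
            for i in range(0, len(g.sequence), 80):
                fh.write(g.sequence[i:i + 80] + "\n")


def write_gff3(genome: GenomeRecord, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in genome.genes:
            ftype = "CDS" if g.feature_type == FEATURE_CDS else "rRNA"
            attrs = f"ID={g.gene_id}"
            if g.feature_type == FEATURE_16S:
                attrs += ";product=16S ribosomal RNA"
            fh.write("\t".join([
                g.contig, "natspec", ftype, str(g.start + 1), str(g.end),
                ".", g.strand, "0" if ftype == "CDS" else ".", attrs]) + "\n")


def genome_stats(genome: GenomeRecord) -> dict:
    """Total length, GC percent (ambiguous bases excluded) and gene count."""
    if not genome.contigs:
        raise EmptyInputError(f"genome {genome.genome_id} has no contigs")
    gc = at = 0
    for seq in genome.contigs.values():
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise EmptyInputError(f"genome {genome.genome_id} has no unambiguous bases")
    return {
        "length_bp": sum(len(s) for s in genome.contigs.values()),
        "gc_percent": 100.0 * gc / (gc + at),
        "n_genes": len(genome.genes),
    }
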