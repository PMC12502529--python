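"""Common-gene tables (pairwise) and single-copy core-gene families.

A *common gene* of a genome pair is a reciprocal best hit (RBH) between
their CDS complements whose global alignment passes the strict thresholds
``identity > 70`` and ``coverage > 70`` of *both* genes' lengths. Best hits
are ranked by affine alignment score with fully specified tie-breaking
(higher identity, then longer combined length, then lexicographic gene id),
so the matching is deterministic and symmetric in the two genomes.

Core families across a strain set are built by anchoring on a reference
genome (the first by default) and intersecting its RBH tables against every
other genome: a reference gene founds a family only if it has an RBH partner
in every strain. Reference anchoring avoids the paralog merging that
transitive closure over all pairwise RBH graphs can produce.

Candidate generation before the exact DP: pairs whose length ratio cannot
reach the coverage threshold are skipped outright, and the remaining pairs
are screened with a unit-cost edit-distance identity estimate kept 10 points
looser than the identity threshold; the ``exhaustive`` strategy aligns all
pairs and exists to validate the screen.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ArgumentError, EmptyInputError
from .genome_io import GenomeRecord
from .pairwise_align import (AlignParams, DEFAULT_PARAMS, align_global,
                             is_zero_degeneracy, screen_identity)

SCREEN_MARGIN = 10.0  # identity points of slack between screen and threshold


@dataclass(frozen=True)
class Thresholds:
    identity: float = 70.0
    coverage: float = 70.0

    def validate(self):
        for name, v in (("identity", self.identity), ("coverage", self.coverage)):
            if not 0.0 < v < 100.0:
                raise ArgumentError(f"{name} threshold must be in (0, 100), got {v}")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    identity: float
    coverage_a: float
    coverage_b: float
    score: float
    zero_degeneracy: bool


@dataclass
class CommonGeneTable:
    genome_a: str
    genome_b: str
    pairs: list[OrthologPair]
    n_genes_a: int
    n_genes_b: int

    def zero_degeneracy_count(self) -> int:
        return sum(p.zero_degeneracy for p in self.pairs)

    def percents(self) -> dict:
        """Common-gene percentages with every candidate denominator."""
        n = len(self.pairs)
        return {
            "of_smaller": 100.0 * n / min(self.n_genes_a, self.n_genes_b),
            "of_a": 100.0 * n / self.n_genes_a,
            "of_b": 100.0 * n / self.n_genes_b,
        }


@dataclass
class CoreGeneSet:
    genome_ids: list[str]
    families: list[dict[str, str]]  # genome_id -> gene_id, one per genome
    reference: str


def common_gene_percent(table: CommonGeneTable) -> float:
    """Percent of the smaller gene complement that is common to the pair."""
    return table.percents()["of_smaller"]


def _rank_key(hit):
    """Sort key for best-hit ranking: score desc, identity desc, combined
    length desc, partner gene id asc."""
    score, identity, comb_len, gene_id = hit
    return (-score, -identity, -comb_len, gene_id)


def common_genes(a: GenomeRecord, b: GenomeRecord,
                 thresholds: Thresholds = DEFAULT_THRESHOLDS,
                 params: AlignParams = DEFAULT_PARAMS,
                 strategy: str = "screened") -> CommonGeneTable:
    """One-to-one common-gene table of two genomes by reciprocal best hit."""
    thresholds.validate()
    if strategy not in ("screened", "exhaustive"):
        raise ArgumentError(f"unknown strategy {strategy!r}")
    genes_a = sorted(a.cds_genes(), key=lambda g: g.gene_id)
    genes_b = sorted(b.cds_genes(), key=lambda g: g.gene_id)
    if not genes_a:
        raise EmptyInputError(f"genome {a.genome_id} has no CDS genes")
    if not genes_b:
        raise EmptyInputError(f"genome {b.genome_id} has no CDS genes")

    min_ratio = thresholds.coverage / 100.0
    screen_cut = thresholds.identity - SCREEN_MARGIN
    alignments: dict[tuple[int, int], object] = {}
    for i, ga in enumerate(genes_a):
        la = len(ga.sequence)
        for j, gb in enumerate(genes_b):
            lb = len(gb.sequence)
            # coverage of the longer gene is at most min(la, lb)/max(la, lb)
            if min(la, lb) <= min_ratio * max(la, lb):
                continue
            if strategy == "screened" and ga.sequence != gb.sequence \
                    and screen_identity(ga.sequence, gb.sequence,
                                        min_identity=screen_cut) < screen_cut:
                continue
            alignments[(i, j)] = align_global(ga.sequence, gb.sequence, params)

    best_for_a: dict[int, int] = {}
    best_for_b: dict[int, int] = {}
    by_a: dict[int, list] = {}
    by_b: dict[int, list] = {}
    for (i, j), res in alignments.items():
        comb = len(genes_a[i].sequence) + len(genes_b[j].sequence)
        by_a.setdefault(i, []).append((res.score, res.identity, comb,
                                       genes_b[j].gene_id, j))
        by_b.setdefault(j, []).append((res.score, res.identity, comb,
                                       genes_a[i].gene_id, i))
    for i, hits in by_a.items():
        best_for_a[i] = min(hits, key=lambda h: _rank_key(h[:4]))[4]
    for j, hits in by_b.items():
        best_for_b[j] = min(hits, key=lambda h: _rank_key(h[:4]))[4]

    pairs: list[OrthologPair] = []
    for i, j in sorted(best_for_a.items()):
        if best_for_b.get(j) != i:
            continue
        res = alignments[(i, j)]
        if res.identity <= thresholds.identity:
            continue
        if min(res.coverage_a, res.coverage_b) <= thresholds.coverage:
            continue
        pairs.append(OrthologPair(
            gene_a=genes_a[i].gene_id, gene_b=genes_b[j].gene_id,
            identity=res.identity, coverage_a=res.coverage_a,
            coverage_b=res.coverage_b, score=res.score,
            zero_degeneracy=is_zero_degeneracy(genes_a[i].sequence,
                                               genes_b[j].sequence)))
    return CommonGeneTable(genome_a=a.genome_id, genome_b=b.genome_id,
                           pairs=pairs, n_genes_a=len(genes_a),
                           n_genes_b=len(genes_b))


def core_genes(genomes: list[GenomeRecord],
               thresholds: Thresholds = DEFAULT_THRESHOLDS,
               params: AlignParams = DEFAULT_PARAMS,
               strategy: str = "screened",
               reference: str | None = None) -> CoreGeneSet:
    """Single-copy core families present in every genome (reference-anchored)."""
    if len(genomes) < 2:
        raise ArgumentError("core_genes requires at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ArgumentError("genome ids must be unique")
    if reference is None:
        reference = ids[0]
    if reference not in ids:
        raise ArgumentError(f"reference {reference!r} not among genomes")
    ref = genomes[ids.index(reference)]
    others = [g for g in genomes if g.genome_id != reference]

    partner: dict[str, dict[str, str]] = {}  # ref gene -> genome -> gene
    for other in others:
        table = common_genes(ref, other, thresholds, params, strategy)
        for p in table.pairs:
            partner.setdefault(p.gene_a, {})[other.genome_id] = p.gene_b

    families = []
    for gene in sorted(partner):
        m = partner[gene]
        if len(m) == len(others):
            fam = {reference: gene}
            fam.update(m)
            families.append(fam)
    return CoreGeneSet(genome_ids=ids, families=families, reference=reference)


def gene_index(genomes: list[GenomeRecord]) -> dict[str, dict[str, str]]:
    """genome_id -> gene_id -> sequence, for fast family lookups."""
    return {g.genome_id: {x.gene_id: x.sequence for x in g.genes}
            for g in genomes}
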