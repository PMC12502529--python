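"""Simulated strain panels with known truth.

The generator emulates the statistical structure the delineation analysis
assumes: a set of strains related by a known tree, protein-coding genes of
varying length evolving under Jukes-Cantor substitution with per-gene gamma
rate multipliers, per-branch gene loss (so common-gene percentages fall below
100%), and — when the tree contains a deep split — a genetic boundary that
exists by construction. Every draw comes from one numpy Generator seeded from
the config, so identical configs give byte-identical FASTA/GFF output.

Jukes-Cantor is used because the probability that a site differs after
evolutionary distance ``t`` has the closed form ``p(t) = 3/4 (1 - e^{-4t/3})``
and the site-change kernel composes along a path, which makes the expected
zero-degeneracy ratio of a strain pair analytically available:
``100 * mean_g (1 - p(t_pair * r_g))^{L_g}``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ArgumentError
from .genome_io import FEATURE_16S, FEATURE_CDS, GeneRecord, GenomeRecord, \
    write_genome_fasta, write_gff3
from .pairwise_align import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def jc_pdiff(t: float) -> float:
    """Per-site probability two sequences differ after JC distance ``t``."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def jc_distance_for_pdiff(p: float) -> float:
    """Branch length whose JC per-site difference probability is ``p``."""
    if not 0.0 <= p < 0.75:
        raise ArgumentError(f"per-site difference probability must be in [0, 0.75), got {p}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pair_newick(pdiff: float, labels=("S1", "S2")) -> str:
    """Two-strain tree whose pairwise per-site difference probability is ``pdiff``."""
    t = jc_distance_for_pdiff(pdiff)
    return f"({labels[0]}:0.0,{labels[1]}:{t:.10f});"


def two_clade_newick(n_per_clade: int = 3, deep: float = 0.007,
                     shallow: float = 0.001, prefix=("A", "B")) -> str:
    """Two star clades separated by a deep internal branch (lengths in subs/site)."""
    clades = []
    for p, n in ((prefix[0], n_per_clade), (prefix[1], n_per_clade)):
        leaves = ",".join(f"{p}{i + 1}:{shallow:.10f}" for i in range(n))
        clades.append(f"({leaves}):{deep:.10f}")
    return f"({clades[0]},{clades[1]});"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated panel.

    tree_newick
        Topology with branch lengths in expected substitutions/site; leaf
        labels become genome ids.
    n_genes, gene_length
        Number of ancestral genes and the (min, max) of their uniform length
        distribution in bp.
    gc
        Ancestral GC fraction; default 0.73 matches the high-GC genus the
        pipeline targets.
    rate_shape
        Gamma shape for per-gene rate multipliers (mean 1); ``None`` disables
        rate heterogeneity.
    loss_prob
        Per-branch per-gene loss probability; losses propagate to the subtree.
    include_16s
        Emit one slow-evolving 16S-like rRNA gene per strain (never lost).
    """

    tree_newick: str
    n_genes: int = 300
    gene_length: tuple[int, int] = (300, 900)
    gc: float = 0.73
    rate_shape: float | None = 3.0
    loss_prob: float = 0.02
    include_16s: bool = True
    s16_length: int = 1520
    s16_rate: float = 0.05
    spacer_length: int = 30
    seed: int = 42
    #: optional second seed for mutation/loss/emission draws; gene lengths and
    #: rate multipliers stay tied to ``seed`` so Monte-Carlo replicates can
    #: share gene parameters while varying the evolutionary realization
    evolution_seed: int | None = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ArgumentError(f"n_genes must be >= 1, got {self.n_genes}")
        lo, hi = self.gene_length
        if not (1 <= lo <= hi):
            raise ArgumentError(f"gene_length must satisfy 1 <= min <= max, got {self.gene_length}")
        if not 0.0 <= self.gc <= 1.0:
            raise ArgumentError(f"gc must be in [0, 1], got {self.gc}")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ArgumentError(f"loss_prob must be in [0, 1], got {self.loss_prob}")
        if self.rate_shape is not None and self.rate_shape <= 0:
            raise ArgumentError(f"rate_shape must be positive, got {self.rate_shape}")
        tree = self._tree()
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ArgumentError("tree branch lengths must be >= 0")
        if len(tree.leaf_nodes()) < 2:
            raise ArgumentError("tree must have at least 2 leaves")

    def _tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.tree_newick, schema="newick")

    def strain_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree().leaf_node_iter()]


@dataclass
class TruthSet:
    """Ground truth of a simulated panel."""

    tree_newick: str
    strain_ids: list[str]
    gene_lengths: np.ndarray           # ancestral CDS lengths
    rate_multipliers: np.ndarray
    ortholog_map: dict[int, dict[str, str]]   # family -> strain -> gene_id
    mutation_counts: dict[int, dict[str, int]]  # family -> edge (child label) -> sites changed
    expected_pdiff: np.ndarray         # strain x strain, length-weighted over shared CDS
    path_lengths: np.ndarray           # strain x strain, tree path length (subs/site)

    def surviving_families(self) -> list[int]:
        """Families present in every strain (the true single-copy core)."""
        n = len(self.strain_ids)
        return [f for f, m in self.ortholog_map.items() if len(m) == n]

    def to_json(self) -> dict:
        return {
            "tree_newick": self.tree_newick,
            "strain_ids": self.strain_ids,
            "gene_lengths": self.gene_lengths.tolist(),
            "rate_multipliers": self.rate_multipliers.tolist(),
            "ortholog_map": {str(k): v for k, v in self.ortholog_map.items()},
            "mutation_counts": {str(k): v for k, v in self.mutation_counts.items()},
            "expected_pdiff": self.expected_pdiff.tolist(),
            "path_lengths": self.path_lengths.tolist(),
        }


def _gene_params(config: SimulationConfig, rng: np.random.Generator):
    lo, hi = config.gene_length
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    if config.rate_shape is None:
        rates = np.ones(config.n_genes)
    else:
        rates = rng.gamma(config.rate_shape, 1.0 / config.rate_shape,
                          size=config.n_genes)
    return lengths, rates


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, p: float):
    """JC kernel: each site changes with probability p, uniformly to another base."""
    if p <= 0.0:
        return seq.copy(), 0
    hit = rng.random(seq.shape[0]) < p
    n_hit = int(hit.sum())
    out = seq.copy()
    if n_hit:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out, n_hit


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def _path_length_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


def simulate_panel(config: SimulationConfig):
    """Simulate a strain panel; returns ``(genomes, truth)``.

    Genomes are emitted as single-contig concatenations of the surviving
    genes (alternating strands, short random spacers between genes) with the
    annotations a GFF3 would carry.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths, rates = _gene_params(config, rng)
    if config.evolution_seed is not None:
        rng = np.random.default_rng(config.evolution_seed)
    tree = config._tree()
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]

    ancestor = [_random_seq(rng, int(L), config.gc) for L in lengths]
    s16_anc = _random_seq(rng, config.s16_length, config.gc) if config.include_16s else None
    # intergenic spacers are ancestral too and evolve at the mean rate, so a
    # zero-divergence pair is identical base for base (ANI exactly 100)
    n_spacers = config.n_genes + 2 if config.spacer_length else 0
    spacer_anc = [_random_seq(rng, config.spacer_length, config.gc)
                  for _ in range(n_spacers)]

    # evolve sequences and loss status down the tree (preorder)
    node_seqs: dict[int, list] = {}
    node_s16: dict[int, np.ndarray] = {}
    node_spacers: dict[int, list] = {}
    node_alive: dict[int, np.ndarray] = {}
    mutation_counts: dict[int, dict[str, int]] = {f: {} for f in range(config.n_genes)}
    edge_idx = 0
    for node in tree.preorder_node_iter():
        nid = id(node)
        if node.parent_node is None:
            node_seqs[nid] = ancestor
            node_alive[nid] = np.ones(config.n_genes, dtype=bool)
            node_spacers[nid] = spacer_anc
            if s16_anc is not None:
                node_s16[nid] = s16_anc
            continue
        pid = id(node.parent_node)
        t = node.edge.length or 0.0
        edge_label = node.taxon.label if node.is_leaf() else f"node{edge_idx}"
        edge_idx += 1
        seqs = []
        for f in range(config.n_genes):
            seq, n_hit = _mutate(rng, node_seqs[pid][f], jc_pdiff(t * rates[f]))
            seqs.append(seq)
            mutation_counts[f][edge_label] = n_hit
        node_seqs[nid] = seqs
        alive = node_alive[pid].copy()
        lost = rng.random(config.n_genes) < config.loss_prob
        alive &= ~lost
        node_alive[nid] = alive
        node_spacers[nid] = [_mutate(rng, sp, jc_pdiff(t))[0]
                             for sp in node_spacers[pid]]
        if s16_anc is not None:
            node_s16[nid], _ = _mutate(rng, node_s16[pid],
                                       jc_pdiff(t * config.s16_rate))

    # emit genomes
    genomes = []
    ortholog_map: dict[int, dict[str, str]] = {f: {} for f in range(config.n_genes)}
    for leaf in tree.leaf_node_iter():
        sid = leaf.taxon.label
        nid = id(leaf)
        parts: list[str] = []
        genes: list[GeneRecord] = []
        pos = 0

        def _spacer(slot):
            nonlocal pos
            if config.spacer_length:
                sp = _decode(node_spacers[nid][slot])
                parts.append(sp)
                pos += len(sp)

        for f in range(config.n_genes):
            if not node_alive[nid][f]:
                continue
            _spacer(f)
            seq = _decode(node_seqs[nid][f])
            strand = "+" if f % 2 == 0 else "-"
            placed = seq if strand == "+" else reverse_complement(seq)
            gene_id = f"{sid}_g{f:04d}"
            genes.append(GeneRecord(
                gene_id=gene_id, genome_id=sid, sequence=seq, contig=sid,
                start=pos, end=pos + len(seq), strand=strand,
                feature_type=FEATURE_CDS))
            ortholog_map[f][sid] = gene_id
            parts.append(placed)
            pos += len(placed)
        if s16_anc is not None:
            _spacer(config.n_genes)
            seq = _decode(node_s16[nid])
            genes.append(GeneRecord(
                gene_id=f"{sid}_16S", genome_id=sid, sequence=seq, contig=sid,
                start=pos, end=pos + len(seq), strand="+",
                feature_type=FEATURE_16S))
            parts.append(seq)
            pos += len(seq)
        _spacer(config.n_genes + 1)
        genome = GenomeRecord(genome_id=sid, contigs={sid: "".join(parts)},
                              genes=genes)
        genome.validate()
        genomes.append(genome)

    path = _path_length_matrix(tree, labels)
    n = len(labels)
    expected = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = [f for f in range(config.n_genes)
                      if labels[i] in ortholog_map[f] and labels[j] in ortholog_map[f]]
            if shared:
                ls = lengths[shared].astype(float)
                ps = np.array([jc_pdiff(path[i, j] * rates[f]) for f in shared])
                expected[i, j] = expected[j, i] = float((ls * ps).sum() / ls.sum())

    truth = TruthSet(
        tree_newick=config.tree_newick, strain_ids=labels,
        gene_lengths=lengths, rate_multipliers=rates,
        ortholog_map={f: m for f, m in ortholog_map.items() if m},
        mutation_counts=mutation_counts,
        expected_pdiff=expected, path_lengths=path,
    )
    return genomes, truth


def expected_zero_degeneracy(config: SimulationConfig, pair: tuple[str, str]) -> float:
    """Analytic expected zero-degeneracy ratio (percent) for a strain pair.

    ``100 * mean_g (1 - p_jc(t_pair * r_g))^{L_g}`` over the ancestral CDS
    complement; gene loss is independent of substitution, so conditioning on
    survival leaves the per-gene expectation unchanged.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths, rates = _gene_params(config, rng)
    tree = config._tree()
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for s in pair:
        if s not in labels:
            raise ArgumentError(f"strain {s!r} not on the config tree")
    path = _path_length_matrix(tree, labels)
    t = path[labels.index(pair[0]), labels.index(pair[1])]
    probs = np.array([(1.0 - jc_pdiff(t * r)) ** int(L)
                      for L, r in zip(lengths, rates)])
    return 100.0 * float(probs.mean())


def write_panel(genomes, truth: TruthSet, out_dir: str) -> None:
    """Write FASTA + GFF3 per strain plus the truth set as JSON."""
    os.makedirs(out_dir, exist_ok=True)
    for g in genomes:
        write_genome_fasta(g, os.path.join(out_dir, f"{g.genome_id}.fna"))
        write_gff3(g, os.path.join(out_dir, f"{g.genome_id}.gff3"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
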