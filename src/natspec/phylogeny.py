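"""Concatenated core-gene p-distances, neighbor joining, bootstrap, Newick.

p-distance is the proportion of differing sites between two aligned
sequences with no substitution-model correction. Gap columns are excluded
per pair (pairwise deletion); the concatenated-alignment distance of a pair
is therefore the column-weighted average over families: total mismatched
columns / total compared columns.

Neighbor joining is the Saitou-Nei agglomeration on the Q-criterion, with
ties broken by the smallest (i, j) index pair in the current node order
(original label order, merged nodes appended). Negative branch lengths are
clamped to zero for output with the total deficit logged. NJ is consistent:
on an additive matrix it recovers the generating topology exactly.

Bootstrap resamples whole gene families with replacement rather than single
alignment columns: the concatenate is built from genes, and family
resampling respects intragenic correlation. Supports are attached to the
internal edges of the full-data tree as integer percent labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import ArgumentError, EmptyInputError
from .genome_io import GenomeRecord
from .ortholog_table import CoreGeneSet, gene_index
from .pairwise_align import (AlignParams, COL_MISMATCH, COL_MATCH,
                             DEFAULT_PARAMS, align_global)

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ArgumentError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ArgumentError("distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ArgumentError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ArgumentError("distances must be non-negative")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for name, row in zip(self.labels, self.d):
            lines.append(name.ljust(12) + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def family_pair_stats(core: CoreGeneSet, genomes: list[GenomeRecord],
                      params: AlignParams = DEFAULT_PARAMS):
    """Per family, per genome pair: (mismatched columns, compared columns).

    Compared columns are those where neither sequence is gapped. Shapes:
    ``(n_families, n_genomes, n_genomes)``; this is the cached input both
    :func:`pdistance` and :func:`bootstrap` re-aggregate.
    """
    if not core.families:
        raise EmptyInputError("core gene set is empty")
    seqs = gene_index(genomes)
    ids = core.genome_ids
    n = len(ids)
    nfam = len(core.families)
    mism = np.zeros((nfam, n, n), dtype=np.int64)
    comp = np.zeros((nfam, n, n), dtype=np.int64)
    for f, fam in enumerate(core.families):
        for i in range(n):
            si = seqs[ids[i]][fam[ids[i]]]
            comp[f, i, i] = len(si)
            for j in range(i + 1, n):
                sj = seqs[ids[j]][fam[ids[j]]]
                if si == sj:
                    mm, cc = 0, len(si)
                elif len(si) == len(sj):
                    # ungapped comparison is exact when lengths match and
                    # identity is high; the aligner confirms via gap-free path
                    res = align_global(si, sj, params)
                    if res.gap_columns == 0:
                        mm, cc = res.mismatches, res.alignment_length
                    else:
                        cols = res.columns
                        mm = int((cols == COL_MISMATCH).sum())
                        cc = int(((cols == COL_MATCH) | (cols == COL_MISMATCH)).sum())
                else:
                    res = align_global(si, sj, params)
                    cols = res.columns
                    mm = int((cols == COL_MISMATCH).sum())
                    cc = int(((cols == COL_MATCH) | (cols == COL_MISMATCH)).sum())
                mism[f, i, j] = mism[f, j, i] = mm
                comp[f, i, j] = comp[f, j, i] = cc
    return mism, comp


def _stats_to_distance(labels, mism, comp) -> DistanceMatrix:
    tot_m = mism.sum(axis=0).astype(float)
    tot_c = comp.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot_c > 0, tot_m / np.maximum(tot_c, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(labels), d=d)


def pdistance(core: CoreGeneSet, genomes: list[GenomeRecord],
              params: AlignParams = DEFAULT_PARAMS) -> DistanceMatrix:
    """Concatenated core-genome p-distance matrix (pairwise gap deletion)."""
    mism, comp = family_pair_stats(core, genomes, params)
    return _stats_to_distance(core.genome_ids, mism, comp)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree."""
    n = len(dm.labels)
    if n < 3:
        raise ArgumentError("neighbor joining requires at least 3 labels")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.d.copy()
    active = list(range(n))
    clamp_deficit = 0.0

    def _set_len(node, value):
        nonlocal clamp_deficit
        if value < 0:
            clamp_deficit += -value
            value = 0.0
        node.edge.length = float(value)

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) in current node order
        flat = np.argmin(q)
        qi, qj = divmod(int(flat), m)
        if qi > qj:
            qi, qj = qj, qi
        i, j = active[qi], active[qj]
        dij = d[i, j]
        li = 0.5 * dij + (r[qi] - r[qj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        _set_len(nodes[i], li)
        _set_len(nodes[j], lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances to the new node
        new_idx = d.shape[0]
        newrow = np.zeros(new_idx + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for qk in range(m):
            k = active[qk]
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - dij)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j = active
    root = dendropy.Node()
    _set_len(nodes[i], 0.5 * d[i, j])
    _set_len(nodes[j], 0.5 * d[i, j])
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    # suppress the degree-2 root so the tree is genuinely unrooted
    tree.seed_node = root
    tree.is_rooted = False
    tree.suppress_unifurcations()
    collapsed = [c for c in tree.seed_node.child_nodes()]
    if len(collapsed) == 2:
        # merge the root: attach one side's children to the other
        a, b = collapsed
        if b.is_leaf():
            a, b = b, a
        join_len = (a.edge.length or 0.0) + (b.edge.length or 0.0)
        for child in list(b.child_nodes()):
            b.remove_child(child)
            tree.seed_node.add_child(child)
        tree.seed_node.remove_child(b)
        a.edge.length = join_len
    if clamp_deficit > 1e-9:
        logger.warning("clamped negative NJ branch lengths; total deficit %.6g",
                       clamp_deficit)
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits as frozensets of the smaller-side leaf labels."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap(core: CoreGeneSet, genomes: list[GenomeRecord],
              replicates: int = 1000, seed: int = 42,
              params: AlignParams = DEFAULT_PARAMS) -> dendropy.Tree:
    """NJ tree with family-resampling bootstrap supports on internal edges."""
    if replicates < 1:
        raise ArgumentError("replicates must be >= 1")
    mism, comp = family_pair_stats(core, genomes, params)
    full = neighbor_joining(_stats_to_distance(core.genome_ids, mism, comp))
    target = {bp: 0 for bp in bipartitions(full)}
    rng = np.random.default_rng(seed)
    nfam = mism.shape[0]
    for _ in range(replicates):
        idx = rng.integers(0, nfam, size=nfam)
        dm = _stats_to_distance(core.genome_ids, mism[idx], comp[idx])
        for bp in bipartitions(neighbor_joining(dm)):
            if bp in target:
                target[bp] += 1

    all_labels = frozenset(core.genome_ids)
    for node in full.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), sorted(s)))
        support = 100.0 * target[key] / replicates
        node.label = str(int(round(support)))
    return full


def write_newick(tree: dendropy.Tree, outgroup: str | None = None) -> str:
    """Newick text with branch lengths and integer supports as node labels."""
    out = tree.clone(depth=1)
    if outgroup is not None:
        node = None
        for lf in out.leaf_node_iter():
            if lf.taxon.label == outgroup:
                node = lf
                break
        if node is None:
            raise ArgumentError(f"outgroup {outgroup!r} is not a leaf of the tree")
        out.to_outgroup_position(node, update_bipartitions=False,
                                 suppress_unifurcations=True)
    text = out.as_string(schema="newick", suppress_rooting=True,
                         real_value_format_specifier=".6f")
    return text.strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")
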