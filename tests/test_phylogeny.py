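"""p-distance, neighbor joining (with oracles), bootstrap, Newick round trips."""

import dendropy
import numpy as np
import pytest

from natspec.errors import ArgumentError
from natspec.ortholog_table import CoreGeneSet
from natspec.phylogeny import (DistanceMatrix, bipartitions, bootstrap,
                               neighbor_joining, pdistance, read_newick,
                               write_newick)

from conftest import make_genome


def _core_for(genomes, gene_ids):
    ids = [g.genome_id for g in genomes]
    return CoreGeneSet(genome_ids=ids,
                       families=[{i: gid for i in ids} for gid in gene_ids],
                       reference=ids[0])


def _random_additive(rng, n_leaves):
    """Random binary topology + strictly positive lengths; returns
    (dendropy tree, labels, additive distance matrix)."""
    labels = [f"T{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels[:3]]
    center = tree.seed_node
    for nd in nodes:
        center.add_child(nd)
    edges = list(center.child_edge_iter())
    for label in labels[3:]:
        edge = edges[rng.integers(len(edges))]
        head = edge.head_node
        parent = head.parent_node
        mid = dendropy.Node()
        parent.remove_child(head)
        parent.add_child(mid)
        mid.add_child(head)
        leaf = dendropy.Node(taxon=taxa.get_taxon(label))
        mid.add_child(leaf)
        edges = [nd.edge for nd in tree.preorder_node_iter()
                 if nd.parent_node is not None]
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(rng.uniform(0.05, 0.5))
    pdm = tree.phylogenetic_distance_matrix()
    t = {l: taxa.get_taxon(l) for l in labels}
    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = pdm.distance(t[labels[i]], t[labels[j]])
    return tree, labels, d


def test_pdistance_hand_counted_example():
    """Families ACGT/ACGA and AAAA/AAAA: 1 mismatch over 8 columns."""
    a = make_genome("A", {"g1": "ACGT", "g2": "AAAA"})
    b = make_genome("B", {"g1": "ACGA", "g2": "AAAA"})
    core = _core_for([a, b], ["g1", "g2"])
    dm = pdistance(core, [a, b])
    assert dm.d[0, 1] == pytest.approx(1 / 8)


def test_pdistance_of_identical_genomes_is_zero():
    a = make_genome("A", {"g": "ACGTACGT"})
    b = make_genome("B", {"g": "ACGTACGT"})
    dm = pdistance(_core_for([a, b], ["g"]), [a, b])
    assert dm.d[0, 1] == 0.0


def test_pdistance_excludes_gap_columns():
    # forced gap: equal flanks, one extra base; 0 mismatches, 8 compared cols
    a = make_genome("A", {"g": "AACCGGTTA"})
    b = make_genome("B", {"g": "AACCGGTT"})
    dm = pdistance(_core_for([a, b], ["g"]), [a, b])
    assert dm.d[0, 1] == 0.0


def test_pdistance_recovers_simulated_divergence(panel6, panel6_core):
    _, genomes, truth = panel6
    dm = pdistance(panel6_core, genomes)
    labels = truth.strain_ids
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = truth.expected_pdiff[labels.index(dm.labels[i]),
                                     labels.index(dm.labels[j])]
            cols = 300 * len(panel6_core.families)
            se = np.sqrt(p * (1 - p) / cols)
            assert abs(dm.d[i, j] - p) <= 3 * se + 1e-9


def test_three_taxon_closed_form():
    # limb lengths from the three-point formulas
    d = DistanceMatrix(labels=["A", "B", "C"],
                       d=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
    tree = neighbor_joining(d)
    limb = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert limb["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert limb["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert limb["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_four_taxon_additive_matrix_recovers_tree_and_lengths():
    rng = np.random.default_rng(0)
    true_tree, labels, d = _random_additive(rng, 4)
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    assert bipartitions(tree) == bipartitions(true_tree)
    # total tree length is preserved on additive input
    total = sum(nd.edge.length for nd in tree.preorder_node_iter()
                if nd.parent_node is not None)
    true_total = sum(nd.edge.length for nd in true_tree.preorder_node_iter()
                     if nd.parent_node is not None)
    assert total == pytest.approx(true_total)


def test_nj_matches_independent_implementation_on_random_matrices():
    """Cross-check topology against scikit-bio's neighbor joining."""
    import skbio

    rng = np.random.default_rng(99)
    for _ in range(10):
        n = int(rng.integers(4, 9))
        base = rng.uniform(0.1, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"L{i}" for i in range(n)]
        ours = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        their_tree = read_newick(str(theirs).strip())
        assert bipartitions(ours) == bipartitions(their_tree)


def test_nj_requires_three_labels():
    with pytest.raises(ArgumentError):
        neighbor_joining(DistanceMatrix(labels=["A", "B"],
                                        d=np.array([[0, 1], [1, 0]], float)))


def test_negative_distances_rejected():
    with pytest.raises(ArgumentError):
        DistanceMatrix(labels=["A", "B"], d=np.array([[0, -1], [-1, 0]], float))


def test_bootstrap_on_uniform_families_gives_full_support():
    """If every family carries the same signal, resampling cannot change the
    distance matrix, so every internal edge is supported in 100% of reps."""
    fams = {}
    for f in range(6):
        base = "ACGTACGTACGT"
        fams[f"g{f}"] = {
            "A": base, "B": base[:-1] + "A",
            "C": "TGCATGCATGCA", "D": "TGCATGCATGCC",
        }
    genomes = [make_genome(s, {g: fams[g][s] for g in fams})
               for s in "ABCD"]
    core = _core_for(genomes, list(fams))
    tree = bootstrap(core, genomes, replicates=50, seed=0)
    supports = [int(nd.label) for nd in tree.preorder_node_iter()
                if nd.parent_node is not None and not nd.is_leaf()
                and nd.label is not None]
    assert supports and all(s == 100 for s in supports)


def test_deep_split_gets_high_support(panel6, panel6_core):
    _, genomes, _ = panel6
    tree = bootstrap(panel6_core, genomes, replicates=100, seed=42)
    split = frozenset(["A1", "A2", "A3"])
    found = None
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if side in (split, frozenset(["B1", "B2", "B3"])):
            found = int(nd.label)
    assert found is not None and found >= 95


def test_bootstrap_is_deterministic_given_seed(panel6, panel6_core):
    _, genomes, _ = panel6
    t1 = bootstrap(panel6_core, genomes, replicates=30, seed=9)
    t2 = bootstrap(panel6_core, genomes, replicates=30, seed=9)
    assert write_newick(t1) == write_newick(t2)


def test_newick_round_trip_preserves_topology_lengths_supports(panel6, panel6_core):
    _, genomes, _ = panel6
    tree = bootstrap(panel6_core, genomes, replicates=20, seed=3)
    text = write_newick(tree)
    again = read_newick(text)
    assert bipartitions(again) == bipartitions(tree)
    assert write_newick(again) == text


def test_outgroup_rooting_preserves_bipartitions(panel6, panel6_core):
    _, genomes, _ = panel6
    tree = bootstrap(panel6_core, genomes, replicates=20, seed=3)
    rooted = read_newick(write_newick(tree, outgroup="B1"))
    assert bipartitions(rooted) == bipartitions(tree)
    first = write_newick(rooted).strip()
    assert "B1" in first
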