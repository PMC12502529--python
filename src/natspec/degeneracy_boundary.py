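"""Zero-degeneracy gene counts, ratios, and the genetic-boundary call.

The boundary statistic between two strains is the percentage of their shared
genes that are *exactly* identical — no substitutions, no indels, no ``N``.
Within a natural species recent common ancestry leaves a large fraction of
genes untouched; across a genetic boundary (isolated gene pools) essentially
every gene has accumulated at least one difference, so the ratio collapses
toward zero. Landmark values from the species-delineation literature are
shipped as named presets: ratios below ~2% indicate a boundary, and ~6% is
the classic Salmonella typhi / typhimurium split.

Two denominator conventions are supported:

* ``core_of_set`` — genes common to *all* strains of the panel (the
  convention behind a panel-wide comparison figure); counts and denominators
  then share one core across every pair.
* ``pairwise_common`` — each pair's own common-gene table.

The boundary call is single-linkage: strain pairs with ratio >= threshold are
linked, and connected components are the natural-species clusters. Single
linkage is the right relation here because the argument for merging two
strains is the existence of *any* high-ratio link, while a boundary requires
*all* cross-links to be low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ArgumentError, EmptyInputError
from .genome_io import GenomeRecord
from .ortholog_table import (CoreGeneSet, DEFAULT_THRESHOLDS, Thresholds,
                             common_genes, core_genes, gene_index)
from .pairwise_align import is_zero_degeneracy

#: Named boundary thresholds (percent of shared genes with identical sequence).
THRESHOLD_PRESETS = {
    "boundary_landmark": 2.0,   # below this: clearly isolated gene pools
    "salmonella_landmark": 6.0,  # S. typhi vs S. typhimurium
    "default": 10.0,
}


@dataclass
class DegeneracyMatrix:
    genome_ids: list[str]
    counts: np.ndarray        # int, symmetric
    denominators: np.ndarray  # int, symmetric
    ratios: np.ndarray        # percent, symmetric, diagonal 100
    mode: str

    def ratio(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.ratios[i, j])

    def to_dataframe(self, which: str = "ratios"):
        import pandas as pd

        return pd.DataFrame(getattr(self, which), index=self.genome_ids,
                            columns=self.genome_ids)


@dataclass
class BoundaryCall:
    genome_ids: list[str]
    clusters: list[list[str]]
    threshold_percent: float
    evidence: DegeneracyMatrix

    def to_json(self) -> dict:
        return {
            "genome_ids": self.genome_ids,
            "clusters": self.clusters,
            "threshold_percent": self.threshold_percent,
            "ratios": np.round(self.evidence.ratios, 6).tolist(),
        }


def degeneracy_matrix(genomes: list[GenomeRecord],
                      core: CoreGeneSet | None = None,
                      mode: str = "core_of_set",
                      thresholds: Thresholds = DEFAULT_THRESHOLDS,
                      strategy: str = "screened") -> DegeneracyMatrix:
    """Pairwise zero-degeneracy counts, denominators and percent ratios."""
    if mode not in ("core_of_set", "pairwise_common"):
        raise ArgumentError(f"unknown mode {mode!r}")
    ids = [g.genome_id for g in genomes]
    n = len(ids)
    counts = np.zeros((n, n), dtype=int)
    denom = np.zeros((n, n), dtype=int)

    if mode == "core_of_set":
        if core is None:
            core = core_genes(genomes, thresholds, strategy=strategy)
        if not core.families:
            raise EmptyInputError(
                "the panel has no core families; consider mode='pairwise_common'")
        seqs = gene_index(genomes)
        nfam = len(core.families)
        for i in range(n):
            counts[i, i] = denom[i, i] = nfam
            for j in range(i + 1, n):
                c = 0
                for fam in core.families:
                    sa = seqs[ids[i]][fam[ids[i]]]
                    sb = seqs[ids[j]][fam[ids[j]]]
                    if is_zero_degeneracy(sa, sb):
                        c += 1
                counts[i, j] = counts[j, i] = c
                denom[i, j] = denom[j, i] = nfam
    else:
        for i in range(n):
            for j in range(i + 1, n):
                table = common_genes(genomes[i], genomes[j], thresholds,
                                     strategy=strategy)
                counts[i, j] = counts[j, i] = table.zero_degeneracy_count()
                denom[i, j] = denom[j, i] = len(table.pairs)
            counts[i, i] = denom[i, i] = max(len(genomes[i].cds_genes()), 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(denom > 0, 100.0 * counts / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(ratios, 100.0)
    return DegeneracyMatrix(genome_ids=ids, counts=counts,
                            denominators=denom, ratios=ratios, mode=mode)


def call_boundaries(matrix: DegeneracyMatrix,
                    threshold_percent: float = THRESHOLD_PRESETS["default"]
                    ) -> BoundaryCall:
    """Partition strains by single-linkage at the given ratio threshold."""
    if not 0.0 < threshold_percent < 100.0:
        raise ArgumentError(
            f"threshold_percent must be in (0, 100), got {threshold_percent}")
    r = matrix.ratios
    if r.shape[0] != r.shape[1] or not np.allclose(r, r.T):
        raise ArgumentError("ratio matrix must be square and symmetric")
    adj = (r >= threshold_percent).astype(int)
    np.fill_diagonal(adj, 1)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = [[] for _ in range(n_comp)]
    for gid, lab in zip(matrix.genome_ids, labels):
        clusters[lab].append(gid)
    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: c[0])
    return BoundaryCall(genome_ids=matrix.genome_ids, clusters=clusters,
                        threshold_percent=threshold_percent, evidence=matrix)
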