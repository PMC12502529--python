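# Methods

This note documents the models, conventions and numerical choices behind
`natspec`, what the synthetic panels do and do not emulate, and the known
limitations.

## The zero-degeneracy statistic and the boundary rule

Two strains share a *zero-degeneracy* gene when a common-gene pair has
exactly identical sequences: equal length, no substitutions, no indels,
and no `N` (an `N` is unknown, so it can never certify identity). The
statistic for a pair is

    r(i,j) = 100 · #identical families / #families,

with the denominator taken either over the panel-wide single-copy core
(`core_of_set`, the default, so every pair is measured against the same
gene set) or over each pair's own common genes (`pairwise_common`).
Comparison is per gene — genes are not concatenated before the identity
check, since a single mutation anywhere in a concatenate would hide which
genes remained untouched.

The boundary call is single-linkage: pairs with `r >= threshold` are
linked and connected components are reported as natural-species clusters,
ordered by their lexicographically smallest member. Single linkage is the
correct relation for this argument: one high-ratio link is evidence of a
shared gene pool, whereas a boundary claim requires *every* cross-link to
be low. The default threshold is 10% with two literature landmarks
shipped as presets (2% "clear boundary", 6% for the classic
typhi/typhimurium split); any cut between those landmarks and the
within-species ratios (tens of percent) yields the same partition on
panels with a real boundary, and the choice is exposed, never hidden.

## Common genes and core families

A common gene is a reciprocal best hit (RBH) between the CDS complements
of two genomes under exact global affine-gap alignment, retained when
identity > 70 and both coverages > 70 (strict inequalities). Identity is
matches over *all* alignment columns including gaps (the conservative
convention); coverage of each gene is the fraction of its bases aligned
against a base of the partner. Best hits are ranked by alignment score
with ties broken by higher identity, then longer combined length, then
lexicographic gene id, so the matching is deterministic and symmetric.
The common-gene percentage uses the smaller gene complement as
denominator; both per-genome percentages are also emitted.

Core families are built by anchoring on a reference genome (first in the
list, configurable): a reference gene founds a family only when it has an
RBH partner in every other genome. Reference anchoring avoids the paralog
merging that transitive closure over all pairwise RBH graphs can produce,
and makes the family set deterministic.

Candidate generation before the exact DP: pairs whose length ratio cannot
satisfy the coverage threshold are skipped, and the rest are screened with
a bounded unit-cost edit-distance identity estimate kept 10 points looser
than the identity threshold. The `exhaustive` strategy aligns every pair
and exists to validate the screen; a test asserts both strategies produce
identical matchings on diverged panels.

## Alignment engine

Global alignment is an exact Gotoh three-state affine DP (numba kernel)
with fully specified tie-breaking (substitution preferred over gaps, gap
in the first sequence preferred over gap in the second), so reruns are
byte-reproducible. A gap of length k costs `gap_open + k·gap_extend`;
defaults are match +1, mismatch −1, open −2, extend −0.5. `N` scores as a
mismatch against everything. The scores are checked against two
independent oracles (Biopython's exact pairwise aligner on pairs ≤ 40 bp,
and a memoized three-state recursion on tiny inputs) — agreement is exact.

A local (Smith–Waterman) variant of the same kernel provides HSP-like
segments for the fragment metrics below.

## ANI, dDDH-style value, 16S identity

**ANI.** Both genomes are cut into consecutive 1020 bp windows (tails
dropped). Candidate fragment pairs are seeded by shared 16-mers in both
orientations — seed counting, unlike global edit distance, stays correct
when gene gain/loss shifts window boundaries between genomes — and
mutual-best candidates are aligned with the exact local aligner. Fragment
scoring (match +1, mismatch −3, open −4, extend −1) makes a region present
in only one genome cross as a single long gap rather than as low-identity
column soup (at 73% GC the random background match rate is ~30%, so with
mild mismatch costs junk would outscore gaps); gap runs longer than 30 bp
are then excluded from the identity denominator, the way a local aligner's
X-drop splits HSPs around a large indel. ANI is the mean identity over
reciprocal pairs with identity ≥ 35% and coverage ≥ 70% of the fragment.
Identical genomes give exactly 100.

**dDDH-style.** An intergenomic distance `d = 1 − Σmatches / Σcolumns`
over the matched segments is mapped to a DDH percentage by a monotone
log-logistic curve, `DDH = 100 / (1 + exp(−(a + b·ln d)))`, calibrated so
that it passes through the two published decision points of the
formula-2 scale: d = 0.0417 ↔ 70% (species cut) and d = 0.0250 ↔ 79%
(subspecies cut). The curve saturates to 100 as d → 0 and is strictly
decreasing — the two properties the workflow relies on. This is the
package's own calibration of the published anchor points, not a refit of
the original regression; absolute values between the anchors are
interpolations and should be read as such.

**16S identity.** Global alignment identity with terminal gap columns
excluded (so a fragmentary copy is not penalized for missing ends), with a
warning below 1200 bp. When genomes carry multiple annotated 16S copies,
the best copy pair is reported alongside the full per-copy table.

## Phylogeny

p-distance is mismatched over compared columns, gap columns excluded per
pair (pairwise deletion — the matrix is built pairwise, so complete
deletion across all taxa would discard data without benefit). The
concatenated distance is the column-weighted average across families,
i.e. total mismatches over total compared columns.

Neighbor joining is the standard Saitou–Nei Q-criterion agglomeration;
ties take the smallest (i, j) pair in the current node order. Negative
branch lengths are clamped to zero for output with the deficit logged.
Topology is cross-checked against an independent implementation
(scikit-bio) and verified to recover generating trees exactly on additive
matrices.

Bootstrap resamples whole gene families with replacement rather than
single columns: the concatenate is built from genes, and family
resampling respects within-gene correlation. This is a documented
divergence from column-bootstrap defaults in classic tree software.
Supports are percentages over replicates attached to internal edges of
the full-data tree; resampling is driven by one seeded generator, so
supports are reproducible.

## Simulator

Ancestral genes (count, length range, GC — default 0.73, matching
high-GC actinomycete genomes) are drawn i.i.d.; per-gene rate multipliers
come from a gamma with mean 1 (default shape 3; `None` disables
heterogeneity). Sequences evolve along the configured tree under
Jukes–Cantor: on a branch of length t a site changes with probability
`p(t·r_g) = 3/4·(1 − e^{−4t·r_g/3})`, uniformly to another base. Because
the JC kernel composes along paths, the expected per-site difference of a
leaf pair is `p(t_path·r_g)` and the expected zero-degeneracy ratio has
the closed form `100 · mean_g (1 − p(t_path·r_g))^{L_g}`, exposed as
`expected_zero_degeneracy` and validated against Monte-Carlo replicates.

Gene loss is per branch per gene (default 0.02) and propagates to the
subtree; gain is representable as loss on all other lineages. A
slow-evolving 16S-like gene (1520 bp, rate multiplier 0.05) is included
by default and never lost. Genomes are emitted as single-contig
concatenations with alternating strands and short intergenic spacers;
spacers are ancestral sequences evolving at the mean rate, so
zero-divergence pairs are identical base for base. All draws come from
one generator seeded by `seed`; an optional `evolution_seed` reuses the
gene parameters while varying the evolutionary realization, which is what
Monte-Carlo validation and multi-seed recovery runs need.

What the simulator does *not* emulate: within-gene indels (off by
default so the zero-degeneracy closed form stays exact), recombination
and horizontal transfer, codon structure, realistic intergenic content,
rearrangements beyond the implicit shifts caused by gene loss, and
sequencing/assembly error. Passing tests therefore demonstrate
correctness of the statistics under a clean divergence model, not
robustness to recombination — on real genomes, recombined tracts would
inflate zero-degeneracy ratios between otherwise isolated lineages.

## Problem sizes and defaults

Test and acceptance runs use panels of 2–6 strains with 40–500 genes of
40–900 bp — large enough that every statistic is measured against its
analytic expectation within binomial error, while a full run of suite
plus acceptance script completes in a few minutes. The pipeline itself
has no size-dependent logic; larger genomes only change runtime (the
fragment and ortholog stages are quadratic in fragment/gene counts with
seed/length screening keeping constants small). Default thresholds
(70/70), fragment length (1020), bootstrap replicates (1000) and the
boundary threshold (10% plus presets) are the field conventions described
above and are all exposed in `RunConfig`.

## Determinism

Every stochastic operation takes an explicit seed (default 42). Pipeline
outputs (TSV matrices, Newick, JSON reports) are byte-identical across
reruns of the same config; `provenance.json` additionally records
wall-clock stage timings, which naturally vary between runs, plus a
config hash and package versions.
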