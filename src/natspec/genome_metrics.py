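"""Whole-genome relatedness metrics: fragment ANI, dDDH-style distance, 16S identity.

ANI follows the OrthoANI convention: both genomes are cut into consecutive
1020 bp fragments, fragments are paired by reciprocal best match (both
orientations tried), and ANI is the mean alignment identity over reciprocal
pairs passing the identity/coverage filters. Because gene gain/loss and
rearrangement shift fragment boundaries between genomes, fragment identity
is computed from the best *local* alignment of the pair (the in-house
analogue of a BLAST HSP), with gap runs above 30 bp treated as unaligned
sequence between segments. ~95-96% is the conventional species cutoff.

The dDDH-style value mimics GGDC's "formula 2": an intergenomic distance
``d = 1 - (identical columns / total aligned columns)`` over matched
segments (here the reciprocal fragment pairs), mapped to a DDH percentage by
a monotone log-logistic curve anchored at the two published decision points
of the formula-2 scale: distance 0.0417 <-> 70% DDH (species) and distance
0.0250 <-> 79% DDH (subspecies). The curve saturates to 100 as d -> 0 and is
strictly decreasing, the two properties the delineation workflow relies on.
>=70% is the conventional species cutoff.

16S identity is the global alignment identity with terminal gap columns
excluded (mirroring trimmed-alignment conventions for rRNA comparisons).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, UndefinedMetricError
from .genome_io import GenomeRecord
from .pairwise_align import (AlignParams, COL_GAP_IN_A, COL_GAP_IN_B,
                             COL_MATCH, COL_MISMATCH, DEFAULT_PARAMS,
                             align_global, align_local, reverse_complement)

ANI_FRAGMENT_LENGTH = 1020

#: scoring for fragment-level local alignments. The mismatch penalty is
#: stiff relative to the gap costs so that a region present in only one
#: genome (lost gene, insertion) is crossed by one long gap — which the
#: segment statistics then exclude, as BLAST's X-drop would split an HSP —
#: rather than smeared into low-identity column soup, which at high GC
#: (background match ~30%) would otherwise score better than gapping.
FRAGMENT_PARAMS = AlignParams(match=1.0, mismatch=-3.0,
                              gap_open=-4.0, gap_extend=-1.0)

# GGDC formula-2 anchor points: (intergenomic distance, DDH percent)
DDH_ANCHOR_SPECIES = (0.0417, 70.0)
DDH_ANCHOR_SUBSPECIES = (0.0250, 79.0)


@dataclass(frozen=True)
class PairMetrics:
    genome_a: str
    genome_b: str
    ani: float | None = None
    ddh: float | None = None
    s16_identity: float | None = None
    fragments_used: int = 0


#: internal gap runs longer than this are treated as unaligned sequence
#: between two matched segments (the way a local aligner would report two
#: separate HSPs around a large indel) and excluded from identity
MAX_GAP_RUN = 30


def _trim_terminal_gaps(cols: np.ndarray) -> np.ndarray:
    """Alignment column codes with leading/trailing gap runs removed."""
    is_gap = (cols == COL_GAP_IN_A) | (cols == COL_GAP_IN_B)
    lo, hi = 0, len(cols)
    while lo < hi and is_gap[lo]:
        lo += 1
    while hi > lo and is_gap[hi - 1]:
        hi -= 1
    return cols[lo:hi]


def _segment_stats(cols: np.ndarray, max_gap_run: int = MAX_GAP_RUN):
    """(matches, identity-denominator columns, substitution columns) of the
    trimmed alignment, with gap runs longer than ``max_gap_run`` excluded."""
    inner = _trim_terminal_gaps(cols)
    if len(inner) == 0:
        return 0, 0, 0
    matches = int((inner == COL_MATCH).sum())
    subs = int(((inner == COL_MATCH) | (inner == COL_MISMATCH)).sum())
    denom = subs
    run = 0
    for c in inner:
        if c == COL_GAP_IN_A or c == COL_GAP_IN_B:
            run += 1
        else:
            if 0 < run <= max_gap_run:
                denom += run
            run = 0
    if 0 < run <= max_gap_run:
        denom += run
    return matches, denom, subs


@dataclass(frozen=True)
class FragmentMatch:
    """One reciprocal fragment pair, summarized over the trimmed alignment."""

    frag_a: int
    frag_b: int
    matches: int
    inner_columns: int   # identity denominator: trimmed columns minus long gap runs
    substitution_columns: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.inner_columns

    def coverage(self, frag_len: int) -> float:
        return 100.0 * self.substitution_columns / frag_len


def _fragments(genome: GenomeRecord, frag_len: int) -> list[str]:
    frags = []
    for seq in genome.contigs.values():
        for i in range(0, len(seq) - frag_len + 1, frag_len):
            frags.append(seq[i:i + frag_len])
    return frags


SEED_KMER = 16
MIN_SHARED_KMERS = 8


def _match_fragments(a: GenomeRecord, b: GenomeRecord, frag_len: int,
                     params: AlignParams):
    """Reciprocal best fragment pairs with their alignments (best orientation).

    Candidate pairing is seed-based, the way a BLAST-backed implementation
    behaves: fragments sharing the most 16-mers (either orientation) are
    mutual-best candidates, which stays robust when gene gain/loss shifts
    fragment boundaries between the genomes. The exact affine *local*
    alignment — the in-house analogue of the BLAST HSP — is then computed
    for the reciprocal pairs only.
    """
    fa = _fragments(a, frag_len)
    fb = _fragments(b, frag_len)
    for g, fr in ((a, fa), (b, fb)):
        if len(fr) < 2:
            total = sum(len(s) for s in g.contigs.values())
            raise EmptyInputError(
                f"genome {g.genome_id} is too short for fragment ANI: "
                f"{total} bp < required {2 * frag_len} bp")
    fb_rc = [reverse_complement(s) for s in fb]

    k = SEED_KMER
    index: dict[str, list[int]] = {}
    for j, s in enumerate(fb):
        for p in range(len(s) - k + 1):
            index.setdefault(s[p:p + k], []).append(j)

    counts: dict[tuple[int, int, int], int] = {}  # (i, j, orientation) -> n
    for i, s in enumerate(fa):
        for orientation, seq in ((0, s), (1, reverse_complement(s))):
            for p in range(len(seq) - k + 1):
                for j in index.get(seq[p:p + k], ()):
                    key = (i, j, orientation)
                    counts[key] = counts.get(key, 0) + 1

    def _best(grouped: dict[int, list[tuple[int, int, int]]]):
        out = {}
        for key, hits in grouped.items():
            # most shared k-mers; ties -> lowest partner index, forward first
            out[key] = min(hits, key=lambda h: (-h[0], h[1], h[2]))
        return out

    by_a: dict[int, list] = {}
    by_b: dict[int, list] = {}
    for (i, j, orientation), n in counts.items():
        if n < MIN_SHARED_KMERS:
            continue
        by_a.setdefault(i, []).append((n, j, orientation))
        by_b.setdefault(j, []).append((n, i, orientation))
    best_a = _best(by_a)
    best_b = _best(by_b)

    out = []
    for i in sorted(best_a):
        n, j, orientation = best_a[i]
        if j not in best_b or best_b[j][1] != i:
            continue
        target = fb_rc[j] if orientation else fb[j]
        res = align_local(fa[i], target, params)
        matches, denom, subs = _segment_stats(res.columns)
        if denom == 0:
            continue
        out.append(FragmentMatch(frag_a=i, frag_b=j, matches=matches,
                                 inner_columns=denom,
                                 substitution_columns=subs))
    return out


def ani(a: GenomeRecord, b: GenomeRecord, frag_len: int = ANI_FRAGMENT_LENGTH,
        min_identity: float = 35.0, min_coverage: float = 70.0,
        params: AlignParams = FRAGMENT_PARAMS) -> float:
    """Average nucleotide identity over reciprocal best fragment pairs."""
    value, _ = ani_details(a, b, frag_len, min_identity, min_coverage, params)
    return value


def ani_details(a: GenomeRecord, b: GenomeRecord,
                frag_len: int = ANI_FRAGMENT_LENGTH,
                min_identity: float = 35.0, min_coverage: float = 70.0,
                params: AlignParams = FRAGMENT_PARAMS) -> tuple[float, int]:
    """ANI value plus the number of fragment pairs it averages over."""
    kept = [m for m in _match_fragments(a, b, frag_len, params)
            if m.identity >= min_identity
            and m.coverage(frag_len) >= min_coverage]
    if not kept:
        raise UndefinedMetricError(
            f"no fragment pairs of {a.genome_id} vs {b.genome_id} pass the "
            f"ANI filters")
    return float(np.mean([m.identity for m in kept])), len(kept)


def _ddh_transform(d: float) -> float:
    """Monotone log-logistic map from intergenomic distance to DDH percent."""
    (d1, y1), (d2, y2) = DDH_ANCHOR_SPECIES, DDH_ANCHOR_SUBSPECIES
    logit1 = math.log(y1 / (100.0 - y1))
    logit2 = math.log(y2 / (100.0 - y2))
    slope = (logit2 - logit1) / (math.log(d2) - math.log(d1))
    intercept = logit1 - slope * math.log(d1)
    if d <= 0.0:
        return 100.0
    y = intercept + slope * math.log(d)
    return 100.0 / (1.0 + math.exp(-y))


def ddh_formula2(a: GenomeRecord, b: GenomeRecord,
                 frag_len: int = ANI_FRAGMENT_LENGTH,
                 min_identity: float = 30.0,
                 params: AlignParams = FRAGMENT_PARAMS) -> float:
    """dDDH-style percentage from summed identities over matched segments."""
    kept = [m for m in _match_fragments(a, b, frag_len, params)
            if m.identity >= min_identity]
    if not kept:
        raise UndefinedMetricError(
            f"no matched segments between {a.genome_id} and {b.genome_id}")
    total_cols = sum(m.inner_columns for m in kept)
    total_matches = sum(m.matches for m in kept)
    d = 1.0 - total_matches / total_cols
    return _ddh_transform(d)


def s16_identity(a_16s: str, b_16s: str, min_length: int = 1200,
                 params: AlignParams = DEFAULT_PARAMS) -> float:
    """Percent identity of two 16S sequences, terminal gap columns excluded."""
    if not a_16s or not b_16s:
        raise EmptyInputError("s16_identity requires two non-empty sequences")
    for name, s in (("first", a_16s), ("second", b_16s)):
        if len(s) < min_length:
            warnings.warn(
                f"{name} 16S sequence is only {len(s)} bp (<{min_length}); "
                f"identity may be unreliable", stacklevel=2)
    res = align_global(a_16s, b_16s, params)
    inner = _trim_terminal_gaps(res.columns)
    if len(inner) == 0:
        raise UndefinedMetricError("alignment has no internal columns")
    matches = int((inner == 0).sum())
    return 100.0 * matches / len(inner)


def best_s16_identity(a: GenomeRecord, b: GenomeRecord,
                      params: AlignParams = DEFAULT_PARAMS):
    """Best identity over all annotated 16S copy pairs, plus per-copy table."""
    copies_a = a.rrna_16s()
    copies_b = b.rrna_16s()
    if not copies_a or not copies_b:
        raise EmptyInputError(
            f"both genomes need annotated 16S copies "
            f"({a.genome_id}: {len(copies_a)}, {b.genome_id}: {len(copies_b)})")
    table = []
    for ga in copies_a:
        for gb in copies_b:
            ident = s16_identity(ga.sequence, gb.sequence, params=params)
            table.append((ga.gene_id, gb.gene_id, ident))
    best = max(table, key=lambda t: t[2])
    return best[2], table


def pair_metrics(a: GenomeRecord, b: GenomeRecord,
                 which: tuple[str, ...] = ("ani", "ddh", "16s"),
                 params: AlignParams = DEFAULT_PARAMS) -> PairMetrics:
    """Convenience wrapper computing the selected metrics for one pair."""
    vals: dict = {"fragments_used": 0}
    if "ani" in which:
        vals["ani"], vals["fragments_used"] = ani_details(a, b, params=params)
    if "ddh" in which:
        vals["ddh"] = ddh_formula2(a, b, params=params)
    if "16s" in which:
        vals["s16_identity"] = best_s16_identity(a, b, params=params)[0]
    return PairMetrics(genome_a=a.genome_id, genome_b=b.genome_id, **vals)
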