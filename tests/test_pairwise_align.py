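"""Alignment engine: worked examples, oracles, symmetry, zero-degeneracy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from natspec.errors import EmptyInputError
from natspec.pairwise_align import (AlignParams, align_global, align_score,
                                    is_zero_degeneracy, reverse_complement,
                                    screen_identity)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


def biopython_score(a: str, b: str, params: AlignParams) -> float:
    """Independent affine-gap oracle via Biopython's exact pairwise aligner.

    Biopython charges open_gap_score on the first gapped column and
    extend_gap_score afterwards; our convention is gap_open + k*gap_extend
    for a gap of length k, hence the open-score shift.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner.score(a, b)


def recursive_score(a: str, b: str, params: AlignParams) -> float:
    """Second oracle: memoized three-state recursion, tiny inputs only."""
    from functools import lru_cache

    go, ge = params.gap_open, params.gap_extend

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 substitution, 1 gap-in-a (consumed b), 2 gap-in-b
        if i == 0 and j == 0:
            return 0.0 if state == 0 else -np.inf
        cands = []
        if state == 0 and i > 0 and j > 0:
            s = params.match if a[i - 1] == b[j - 1] else params.mismatch
            cands = [best(i - 1, j - 1, k) + s for k in range(3)]
        elif state == 1 and j > 0:
            cands = [best(i, j - 1, 0) + go + ge,
                     best(i, j - 1, 1) + ge,
                     best(i, j - 1, 2) + go + ge]
        elif state == 2 and i > 0:
            cands = [best(i - 1, j, 0) + go + ge,
                     best(i - 1, j, 1) + go + ge,
                     best(i - 1, j, 2) + ge]
        return max(cands, default=-np.inf)

    return max(best(len(a), len(b), k) for k in range(3))


def test_identical_sequences_align_perfectly():
    res = align_global("ACGT", "ACGT")
    assert res.identity == 100.0
    assert res.coverage_a == res.coverage_b == 100.0
    assert res.gap_columns == 0
    assert res.score == 4.0


def test_single_substitution_is_forced_by_equal_length():
    res = align_global("ACGT", "ACGA")
    assert (res.matches, res.mismatches) == (3, 1)
    assert res.identity == 75.0


def test_empty_sequence_raises():
    with pytest.raises(EmptyInputError):
        align_global("", "ACGT")


@pytest.mark.parametrize("params", [
    AlignParams(),
    AlignParams(match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0),
])
def test_score_matches_independent_oracle_on_random_pairs(params):
    rng = np.random.default_rng(2024)
    for _ in range(100):
        la, lb = rng.integers(1, 41, size=2)
        a = "".join(rng.choice(list("ACGT"), size=la))
        b = "".join(rng.choice(list("ACGT"), size=lb))
        assert align_score(a, b, params) == pytest.approx(
            biopython_score(a, b, params), abs=1e-9)


def test_score_matches_recursive_oracle_on_tiny_pairs():
    rng = np.random.default_rng(7)
    params = AlignParams()
    for _ in range(60):
        la, lb = rng.integers(1, 11, size=2)
        a = "".join(rng.choice(list("ACGT"), size=la))
        b = "".join(rng.choice(list("ACGT"), size=lb))
        assert align_score(a, b, params) == pytest.approx(
            recursive_score(a, b, params), abs=1e-9)


@given(DNA, DNA)
def test_alignment_is_symmetric(a, b):
    ra = align_global(a, b)
    rb = align_global(b, a)
    assert ra.score == pytest.approx(rb.score)
    assert ra.identity == pytest.approx(rb.identity)
    assert ra.coverage_a == pytest.approx(rb.coverage_b)
    assert ra.coverage_b == pytest.approx(rb.coverage_a)


@given(DNA)
def test_self_alignment_identity_100_and_column_accounting(a):
    res = align_global(a, a)
    assert res.identity == 100.0
    assert res.matches + res.mismatches + res.gap_columns == res.alignment_length
    assert len(res.columns) == res.alignment_length


@given(DNA, DNA)
def test_zero_degeneracy_iff_perfect_ungapped_identity(a, b):
    res = align_global(a, b)
    zd = is_zero_degeneracy(a, b)
    if len(a) == len(b) and res.gap_columns == 0:
        assert zd == (res.identity == 100.0)
    else:
        assert not zd or a == b


def test_n_counts_as_variation_and_scores_as_mismatch():
    assert not is_zero_degeneracy("ATGN", "ATGN")
    assert not is_zero_degeneracy("ATG", "ATGN")
    res = align_global("ANA", "ANA")
    assert res.mismatches == 1 and res.matches == 2


def test_traceback_is_deterministic():
    a, b = "ACGTACGTAC", "ACGACGTTAC"
    cols = [align_global(a, b).columns.tolist() for _ in range(3)]
    assert cols[0] == cols[1] == cols[2]


def test_local_alignment_finds_embedded_segment():
    from natspec.pairwise_align import align_local

    rng = np.random.default_rng(5)
    core = "".join(rng.choice(list("ACGT"), size=120))
    left = "".join(rng.choice(list("ACGT"), size=40))
    right = "".join(rng.choice(list("ACGT"), size=40))
    res = align_local(left + core + right, core,
                      AlignParams(match=1, mismatch=-3, gap_open=-4,
                                  gap_extend=-1))
    assert res.identity == 100.0
    assert (res.start_a, res.end_a) == (40, 160)
    assert (res.start_b, res.end_b) == (0, 120)
    assert res.score == 120.0


def test_local_alignment_score_bounded_by_global_plus_gaps():
    from natspec.pairwise_align import align_local

    rng = np.random.default_rng(8)
    for _ in range(20):
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 60)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 60)))
        local = align_local(a, b)
        assert local.score >= align_global(a, b).score - 1e-9
        assert local.score >= 0.0


def test_reverse_complement_round_trip():
    assert reverse_complement("ATGAAATAG") == "CTATTTCAT"
    assert reverse_complement(reverse_complement("ACGTN")) == "ACGTN"


def test_screen_identity_tracks_alignment_identity_for_similar_pairs():
    rng = np.random.default_rng(11)
    base = "".join(rng.choice(list("ACGT"), size=200))
    mutated = list(base)
    for i in rng.choice(200, size=10, replace=False):
        mutated[i] = "ACGT"[(("ACGT".index(mutated[i])) + 1) % 4]
    est = screen_identity(base, "".join(mutated))
    true = align_global(base, "".join(mutated)).identity
    assert abs(est - true) < 1.0
    assert screen_identity("A" * 50, "C" * 50, min_identity=80.0) == float("-inf")
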