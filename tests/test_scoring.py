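"""Scoring schemes: strict, item, and item-level Levenshtein credit."""

from fractions import Fraction

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chunkrecall import compression_config, generate_recall_corpus
from chunkrecall.pipeline import template_designs
from chunkrecall.scoring import (
    BLANK,
    aggregate,
    chunk_cohesion,
    edit_distance,
    enumerate_optimal_alignments,
    item_score,
    ld_item_score,
    score_corpus,
    strict_score,
)

seqs = st.lists(st.integers(0, 4), min_size=0, max_size=7).map(tuple)


# ---------------------------------------------------------------------------
# strict and item scoring
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "target,response,expected",
    [
        ((1, 2, 3, 4), (1, 2, 4, 3), (1, 1, 0, 0)),
        ((1, 2, 3), (1, 2, 3), (1, 1, 1)),
        ((1, 2, 3), (BLANK, BLANK, BLANK), (0, 0, 0)),
    ],
)
def test_strict_scoring(target, response, expected):
    assert tuple(strict_score(target, response)) == expected


@pytest.mark.parametrize(
    "target,response,expected",
    [
        ((1, 2, 3, 4), (1, 2, 4, 3), (1, 1, 1, 1)),
        # one-to-one matching: a single recalled "1" credits one target "1"
        ((1, 1, 2, 3), (1, 2, 3, BLANK), (1, 0, 1, 1)),
        ((1, 2, 3), (BLANK, BLANK, BLANK), (0, 0, 0)),
    ],
)
def test_item_scoring(target, response, expected):
    assert tuple(item_score(target, response)) == expected


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        strict_score((1, 2, 3), (1, 2))
    with pytest.raises(ValueError, match="length"):
        item_score((1, 2, 3), (1, 2, 3, 4))


# ---------------------------------------------------------------------------
# edit distance and LD credit
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((1, 2, 3, 4), (1, 2, 4, 3), 2),
        ((1, 2, 3), (1, 2, 3), 0),
        ((1, 2, 3), (), 3),
    ],
)
def test_edit_distance_examples(a, b, expected):
    assert edit_distance(a, b) == expected


@settings(derandomize=True, max_examples=150)
@given(seqs, seqs)
def test_edit_distance_matches_edlib(a, b):
    sa = "".join(chr(65 + x) for x in a)
    sb = "".join(chr(65 + x) for x in b)
    if not sa or not sb:
        assert edit_distance(a, b) == max(len(a), len(b))
    else:
        assert edit_distance(a, b) == edlib.align(sa, sb)["editDistance"]


def test_ld_worked_example():
    credit = ld_item_score((1, 2, 3, 4), (1, 2, 4, 3))
    assert credit.match_fraction == (
        Fraction(1),
        Fraction(1),
        Fraction(1, 2),
        Fraction(1, 2),
    )
    assert credit.distance == 2
    assert credit.n_optimal == 2


def test_ld_insertions_cost_nothing_per_item():
    credit = ld_item_score((1, 2, 3), (9, 9, 1, 2, 3, 9))
    assert credit.match_fraction == (Fraction(1),) * 3


def test_ld_perfect_and_blank_handling():
    assert ld_item_score((1, 2, 3), (1, 2, 3)).distance == 0
    assert ld_item_score((1, 2, 3), (1, 2, 3)).match_fraction == (Fraction(1),) * 3
    # blanks are stripped before alignment: omissions become deletions
    credit = ld_item_score((1, 2, 3), (1, BLANK, 3))
    assert credit.distance == 1
    assert credit.match_fraction == (Fraction(1), Fraction(0), Fraction(1))


def _oracle_fractions(target, response):
    alignments = enumerate_optimal_alignments(target, response)
    n = len(alignments)
    return tuple(
        Fraction(sum(1 for al in alignments if any(i == ti for ti, _ in al)), n)
        for i in range(len(target))
    )


@settings(derandomize=True, max_examples=200)
@given(seqs, seqs)
def test_dp_marginals_equal_explicit_enumeration(target, response):
    assert ld_item_score(target, response).match_fraction == _oracle_fractions(
        target, response
    )


@settings(derandomize=True, max_examples=150)
@given(seqs, seqs, st.permutations(list(range(5))))
def test_relabelling_invariance(target, response, perm):
    """Consistently renaming word ids leaves every scheme unchanged."""
    rt = tuple(perm[x] for x in target)
    rr = tuple(perm[x] for x in response)
    assert ld_item_score(target, response).match_fraction == ld_item_score(
        rt, rr
    ).match_fraction
    assert edit_distance(target, response) == edit_distance(rt, rr)
    if len(target) == len(response):
        assert tuple(strict_score(target, response)) == tuple(strict_score(rt, rr))
        assert tuple(item_score(target, response)) == tuple(item_score(rt, rr))


@settings(derandomize=True, max_examples=150)
@given(st.integers(1, 6).flatmap(lambda n: st.tuples(
    st.lists(st.integers(0, 6), min_size=n, max_size=n, unique=True).map(tuple),
    st.lists(st.integers(0, 6), min_size=n, max_size=n).map(tuple),
)))
def test_dominance_and_zero_distance_equivalence(pair):
    """Per item: strict <= item and LD <= item; and for equal-length,
    blank-free pairs, distance 0 <=> all LD credits 1 <=> all strict 1.

    Targets are duplicate-free, as in the experimental designs (words are
    drawn without replacement); with duplicated targets the one-to-one item
    matching and the alignment marginals spread credit differently and the
    per-item dominance need not hold.
    """
    target, response = pair
    s = strict_score(target, response)
    i = item_score(target, response)
    credit = ld_item_score(target, response)
    ld = credit.as_floats()
    assert np.all(s <= i)
    assert np.all(ld <= i + 1e-12)
    all_one = all(f == 1 for f in credit.match_fraction)
    assert (credit.distance == 0) == all_one == bool(np.all(s == 1))


# ---------------------------------------------------------------------------
# chunk cohesion
# ---------------------------------------------------------------------------


def _trial(label_sizes, words):
    from chunkrecall.design import ChunkToken, TrialList

    tokens, it = [], iter(words)
    for s in label_sizes:
        tokens.append(ChunkToken(s, tuple(next(it) for _ in range(s))))
    return TrialList(tuple(tokens))


def test_cohesion_all_or_none_corpus():
    t = _trial((1, 3), (0, 1, 2, 3))
    corpus = [(t, (0, 1, 2, 3)), (t, (0, BLANK, BLANK, BLANK))]
    assert chunk_cohesion(corpus, 3).pooled == 1.0


def test_cohesion_single_member_corpus():
    t = _trial((1, 3), (0, 1, 2, 3))
    corpus = [(t, (0, 1, BLANK, BLANK)), (t, (BLANK, 2, BLANK, BLANK))]
    assert chunk_cohesion(corpus, 3).pooled == 0.0


def test_cohesion_zero_denominator_is_missing():
    t = _trial((1, 3), (0, 1, 2, 3))
    corpus = [(t, (0, BLANK, BLANK, BLANK))]
    result = chunk_cohesion(corpus, 3)
    assert result.pooled is None
    assert result.n_chunks_with_any == 0
    with pytest.raises(ValueError, match="no chunk"):
        chunk_cohesion(corpus, 2)


def test_cohesion_breaks_down_by_start_position(small_corpus):
    result = chunk_cohesion(small_corpus.pairs(), 3)
    assert result.pooled == 1.0  # model emits chunks atomically
    assert set(result.by_start.columns) >= {"start", "n", "p_all_given_any"}
    assert (result.by_start["p_all_given_any"].dropna() == 1.0).all()


# ---------------------------------------------------------------------------
# corpus aggregation
# ---------------------------------------------------------------------------


def test_aggregate_perfect_trials():
    t = _trial((1, 3), (0, 1, 2, 3))
    frame = score_corpus([(t, (0, 1, 2, 3))] * 10, "strict")
    table = aggregate(frame, "strict")
    assert (table["mean"] == 1.0).all()
    assert (table["n"] > 0).all()


def test_aggregate_scheme_dominance_on_simulated_corpus(small_corpus):
    tables = {
        scheme: aggregate(
            score_corpus(small_corpus.pairs(), scheme), scheme
        ).set_index(["condition", "word_class", "word_position"])["mean"]
        for scheme in ("strict", "item", "LD")
    }
    assert np.all(tables["strict"] <= tables["item"] + 1e-12)
    assert np.all(tables["LD"] <= tables["item"] + 1e-12)
    # aggregate ordering: LD can only add credit relative to strict
    assert tables["strict"].mean() <= tables["LD"].mean() + 1e-12
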