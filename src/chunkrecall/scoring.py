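"""Response scoring for paced immediate serial recall.

Three schemes are implemented:

``strict``
    An item is correct only if recalled at its exact serial position.  Paced
    recall makes omissions explicit ("blank"), so responses are positional and
    must have the target's length.

``item``
    Lenient scoring: an item is correct if recalled anywhere, with one-to-one
    multiset matching so a duplicated response token cannot credit two target
    tokens.  Blanks are ignored.

``LD``
    Item-level Levenshtein credit.  The whole-list edit distance frequently
    admits several equally good alignments; each target item is credited with
    the fraction of all optimal alignments in which it is matched to an
    identical response symbol.  E.g. target ``1 2 3 4`` recalled as
    ``1 2 4 3``: the two optimal alignments either delete-and-reinsert the 3
    or the 4, so items 1 and 2 score 1.0 and items 3 and 4 score 0.5 each.
    Insertions elsewhere in the response never reduce an item's credit.

An *alignment* here is an order-preserving matching of identical symbols
between target and response (equivalently, an embedding of a maximum-length
common subsequence).  A column pairing two different symbols is a
substitution: it credits neither item and is not part of the matching, so
alignment identity is carried entirely by the matched pairs.  Credits are
exact ratios of integers (:class:`fractions.Fraction`); the count of optimal
alignments is obtained from forward/backward DP marginals and alignments are
only ever materialised by the explicit enumeration oracle, which is capped.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .design import TrialList

__all__ = [
    "BLANK",
    "AlignmentCredit",
    "strip_blanks",
    "strict_score",
    "item_score",
    "edit_distance",
    "ld_item_score",
    "enumerate_optimal_alignments",
    "chunk_cohesion",
    "CohesionResult",
    "score_corpus",
    "aggregate",
]

#: Sentinel word id for an omitted ("blank") output position.
BLANK = -1

Seq = Sequence[int]


def strip_blanks(seq: Seq) -> tuple[int, ...]:
    """Drop BLANK markers; omissions then surface as deletions."""
    return tuple(int(x) for x in seq if x != BLANK)


def _check_lengths(target: Seq, response: Seq) -> None:
    if len(response) != len(target):
        raise ValueError(
            f"paced response length {len(response)} != target length {len(target)}"
        )
    if any(x == BLANK for x in target):
        raise ValueError("target lists contain no blanks")


def strict_score(target: Seq, response: Seq) -> np.ndarray:
    """Per-position binary credit: 1 iff recalled in the correct position."""
    _check_lengths(target, response)
    return np.fromiter(
        (1 if r == t else 0 for t, r in zip(target, response)),
        dtype=np.int64,
        count=len(target),
    )


def item_score(target: Seq, response: Seq) -> np.ndarray:
    """Per-item binary credit: 1 iff recalled anywhere (one-to-one matching).

    Each response token can credit at most one identical target token, so
    e.g. target ``(1,1,2,3)`` scored against ``(1,2,3,BLANK)`` gives
    ``(1,0,1,1)``.  Blanks are ignored.
    """
    _check_lengths(target, response)
    available = Counter(strip_blanks(response))
    out = np.zeros(len(target), dtype=np.int64)
    for i, t in enumerate(target):
        if available[t] > 0:
            available[t] -= 1
            out[i] = 1
    return out


def edit_distance(a: Seq, b: Seq) -> int:
    """Standard unit-cost Levenshtein distance (insertions, deletions,
    substitutions).  Callers strip blanks from responses first."""
    a, b = tuple(a), tuple(b)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, start=1):
        cur = [i]
        for j, y in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y))
            )
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# Optimal-alignment counting (DP marginals)
# ---------------------------------------------------------------------------


def _lcs_table(a: Seq, b: Seq) -> list[list[int]]:
    n, m = len(a), len(b)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        row, above = L[i], L[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                row[j] = above[j - 1] + 1
            else:
                row[j] = above[j] if above[j] >= row[j - 1] else row[j - 1]
    return L


def _embedding_counts(a: Seq, b: Seq, L: list[list[int]]) -> list[list[int]]:
    """C[i][j] = number of distinct maximum matchings between a[:i] and b[:j].

    A matching is a set of index pairs, strictly increasing in both
    coordinates, pairing identical symbols.  Counted once each via
    inclusion-exclusion: matchings using the pair (i,j); using row i without
    column j (⊂ C[i][j-1]); using column j without row i (⊂ C[i-1][j]) —
    monotonicity forbids using both — and using neither (in both, subtracted
    once via C[i-1][j-1]).  Exact integer arithmetic throughout.
    """
    n, m = len(a), len(b)
    C = [[1] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            lij = L[i][j]
            total = 0
            if a[i - 1] == b[j - 1] and L[i - 1][j - 1] + 1 == lij:
                total += C[i - 1][j - 1]
            if L[i][j - 1] == lij:
                total += C[i][j - 1]
            if L[i - 1][j] == lij:
                total += C[i - 1][j]
            if L[i - 1][j - 1] == lij:
                total -= C[i - 1][j - 1]
            C[i][j] = total
    return C


@dataclass(frozen=True)
class AlignmentCredit:
    """Item-level Levenshtein credit for one target/response pair.

    Attributes
    ----------
    distance:
        Whole-list unit-cost Levenshtein distance.
    n_optimal:
        Number of distinct optimal alignments (order-preserving matchings of
        identical symbols of maximum size).
    match_fraction:
        Per target item, the exact fraction of optimal alignments in which it
        is matched.  ``distance == 0`` implies every fraction is 1; the
        converse holds when the sequences have equal length.
    """

    distance: int
    n_optimal: int
    match_fraction: tuple[Fraction, ...]

    def as_floats(self) -> np.ndarray:
        return np.array([float(f) for f in self.match_fraction])


def ld_item_score(target: Seq, response: Seq) -> AlignmentCredit:
    """Credit each target item with the fraction of optimal alignments that
    match it to an identical response symbol.

    Blanks are stripped from the response first, so omissions manifest as
    deletions; response insertions cost list-level edits but never reduce any
    individual item's credit.
    """
    t = tuple(target)
    r = strip_blanks(response)
    n, m = len(t), len(r)

    Lf = _lcs_table(t, r)
    Cf = _embedding_counts(t, r, Lf)
    tr, rr = t[::-1], r[::-1]
    Lb = _lcs_table(tr, rr)
    Cb = _embedding_counts(tr, rr, Lb)

    total_len = Lf[n][m]
    total = Cf[n][m]
    fractions = []
    for i in range(1, n + 1):
        matched = 0
        for j in range(1, m + 1):
            if t[i - 1] != r[j - 1]:
                continue
            # suffix tables are indexed from the reversed sequences
            if Lf[i - 1][j - 1] + 1 + Lb[n - i][m - j] == total_len:
                matched += Cf[i - 1][j - 1] * Cb[n - i][m - j]
        fractions.append(Fraction(matched, total))
    return AlignmentCredit(
        distance=edit_distance(t, r),
        n_optimal=total,
        match_fraction=tuple(fractions),
    )


def enumerate_optimal_alignments(
    target: Seq, response: Seq, cap: int = 200_000
) -> list[frozenset[tuple[int, int]]]:
    """Explicitly enumerate every optimal alignment as a set of (i, j) pairs
    (0-based target/response indices).  Test oracle for the DP marginals; the
    number of alignments grows combinatorially, hence the ``cap``.
    """
    t = tuple(target)
    r = strip_blanks(response)
    n, m = len(t), len(r)
    Lb = _lcs_table(t[::-1], r[::-1])
    total_len = _lcs_table(t, r)[n][m]
    out: list[frozenset[tuple[int, int]]] = []

    def rec(i: int, j: int, acc: list[tuple[int, int]]) -> None:
        if len(acc) + Lb[n - i][m - j] < total_len:
            return
        if i == n:
            if len(acc) == total_len:
                if len(out) >= cap:
                    raise RuntimeError(f"more than {cap} optimal alignments")
                out.append(frozenset(acc))
            return
        # target item i left unmatched
        rec(i + 1, j, acc)
        # or matched to the next identical response symbol at j' >= j
        for j2 in range(j, m):
            if r[j2] == t[i]:
                acc.append((i, j2))
                rec(i + 1, j2 + 1, acc)
                acc.pop()

    rec(0, 0, [])
    return out


# ---------------------------------------------------------------------------
# Corpus-level scoring
# ---------------------------------------------------------------------------


def trial_scores(target: TrialList, response: Seq, scheme: str) -> np.ndarray:
    """Per-word-position scores for one trial under one scheme."""
    words = target.words
    if scheme == "strict":
        return strict_score(words, response).astype(float)
    if scheme == "item":
        return item_score(words, response).astype(float)
    if scheme == "LD":
        return ld_item_score(words, response).as_floats()
    raise ValueError(f"unknown scheme {scheme!r}")


def score_corpus(
    corpus: Iterable[tuple[TrialList, Seq]],
    scheme: str,
    trial_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Long per-word score frame for a corpus of (trial, response) pairs.

    Columns: trial_id, condition, arrangement, word_position, word_class,
    chunk_index, chunk_start, score.
    """
    rows = []
    for k, (trial, response) in enumerate(corpus):
        tid = trial_ids[k] if trial_ids is not None else k
        scores = trial_scores(trial, response, scheme)
        classes = trial.word_classes()
        chunk_idx = trial.word_chunk_index()
        starts = trial.chunk_starts
        label = trial.spec.label
        arr_label = "".join(map(str, trial.arrangement))
        for p in range(trial.n_words):
            ci = chunk_idx[p]
            rows.append(
                (
                    tid,
                    label,
                    arr_label,
                    p + 1,
                    classes[p],
                    ci,
                    starts[ci - 1],
                    scores[p],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "condition",
            "arrangement",
            "word_position",
            "word_class",
            "chunk_index",
            "chunk_start",
            "score",
        ],
    )


def aggregate(
    scores: pd.DataFrame,
    scheme: str,
    weighting: str = "equal_arrangement",
) -> pd.DataFrame:
    """Condition x word-position mean scores, singleton/chunk slices included.

    ``weighting="equal_arrangement"`` averages arrangement-level means with
    equal weight (composite serial positions); ``"pooled"`` pools trials
    directly.  Empty cells simply do not appear; ``n`` counts contributing
    word observations.
    """
    if weighting not in ("equal_arrangement", "pooled"):
        raise ValueError(f"unknown weighting {weighting!r}")
    keys = ["condition", "word_class", "word_position"]
    if weighting == "pooled":
        g = scores.groupby(keys)["score"].agg(["mean", "count"]).reset_index()
    else:
        per_arr = (
            scores.groupby(keys + ["arrangement"])["score"]
            .agg(["mean", "count"])
            .reset_index()
        )
        g = (
            per_arr.groupby(keys)
            .agg(mean=("mean", "mean"), count=("count", "sum"))
            .reset_index()
        )
    out = g.rename(columns={"count": "n"})
    out.insert(0, "scheme", scheme)
    return out


@dataclass(frozen=True)
class CohesionResult:
    """All-or-none statistics for multiword chunks.

    ``pooled`` is P(all members recalled | at least one member recalled);
    ``None`` when no chunk had any member recalled.  ``by_start`` breaks the
    probability and the per-member accuracies down by the chunk's starting
    word position.
    """

    chunk_size: int
    pooled: float | None
    n_chunks_with_any: int
    n_chunks_total: int
    by_start: pd.DataFrame


def chunk_cohesion(
    corpus: Iterable[tuple[TrialList, Seq]], chunk_size: int
) -> CohesionResult:
    """Chunk cohesion under item scoring, pooled and by starting position."""
    rows = []
    for trial, response in corpus:
        credits = item_score(trial.words, response)
        pos = 0
        for token, start in zip(trial.tokens, trial.chunk_starts):
            member = credits[pos : pos + token.size]
            pos += token.size
            if token.size != chunk_size:
                continue
            rows.append((start, int(member.sum()), *(int(x) for x in member)))
    if not rows:
        raise ValueError(f"corpus contains no chunk of size {chunk_size}")
    member_cols = [f"member_{k + 1}" for k in range(chunk_size)]
    df = pd.DataFrame(rows, columns=["start", "n_recalled", *member_cols])
    any_ = df["n_recalled"] > 0
    all_ = df["n_recalled"] == chunk_size
    pooled = float(all_[any_].mean()) if any_.any() else None

    def _summary(g: pd.DataFrame) -> pd.Series:
        ga = g["n_recalled"] > 0
        out = {
            "n": len(g),
            "p_all_given_any": (
                float((g["n_recalled"] == chunk_size)[ga].mean()) if ga.any() else np.nan
            ),
        }
        for c in member_cols:
            out[c] = float(g[c].mean())
        return pd.Series(out)

    by_start = (
        df.groupby("start").apply(_summary, include_groups=False).reset_index()
    )
    return CohesionResult(
        chunk_size=chunk_size,
        pooled=pooled,
        n_chunks_with_any=int(any_.sum()),
        n_chunks_total=len(df),
        by_start=by_start,
    )
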