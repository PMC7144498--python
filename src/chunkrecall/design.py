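"""Experimental list designs for chunked serial recall.

A list is built from *chunks*: singletons (one word) and prelearned multiword
chunks of two or three words.  A *condition* is the unordered multiset of
chunk sizes — e.g. ``1222`` is one singleton plus three pairs on seven words —
and a concrete trial realises one ordered *arrangement* of that multiset over
word positions ``1..n_words`` (positions are 1-based throughout).

Mixing chunk sizes constrains where singletons can sit: in a ``1222`` list the
singleton can only ever occupy word positions 1, 3, 5 or 7.  Serial-position
curves for mixed lists are therefore *composite*: each word position averages
over the admissible arrangements that place a singleton (or a chunk member)
there.  :func:`composite_positions` exposes exactly that bookkeeping.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass
from itertools import permutations

import numpy as np

__all__ = [
    "ListSpec",
    "TrialList",
    "ChunkToken",
    "NoTripleStartAt",
    "make_spec",
    "parse_spec",
    "parse_constraint",
    "word_starts",
    "enumerate_arrangements",
    "sample_trial",
    "composite_positions",
]

VALID_CHUNK_SIZES = frozenset({1, 2, 3})

#: An ordered sequence of chunk sizes, e.g. ``(2, 1, 2, 2)``.
Arrangement = tuple[int, ...]

#: Predicate accepting an arrangement, or ``None`` for no constraint.
Constraint = Callable[[Arrangement], bool] | None


@dataclass(frozen=True, order=True)
class ListSpec:
    """Unordered composition of a list: a multiset of chunk sizes.

    The composition is stored canonically sorted; conditions describe what a
    list is made of, not the order chunks appear in.
    """

    composition: tuple[int, ...]

    @property
    def n_words(self) -> int:
        return sum(self.composition)

    @property
    def n_chunks(self) -> int:
        return len(self.composition)

    @property
    def label(self) -> str:
        return "".join(str(s) for s in self.composition)

    @property
    def has_singleton(self) -> bool:
        return 1 in self.composition

    @property
    def n_multiword(self) -> int:
        """Number of multiword (prelearned) chunks in the composition."""
        return sum(1 for s in self.composition if s > 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def make_spec(composition: Sequence[int]) -> ListSpec:
    """Build a :class:`ListSpec` from a sequence of chunk sizes.

    Raises
    ------
    ValueError
        If the composition is empty or contains a size outside {1, 2, 3}.
    """
    comp = tuple(int(s) for s in composition)
    if not comp:
        raise ValueError("composition must be non-empty")
    bad = sorted({s for s in comp if s not in VALID_CHUNK_SIZES})
    if bad:
        raise ValueError(f"chunk sizes must be 1, 2 or 3; got {bad}")
    return ListSpec(tuple(sorted(comp)))


def parse_spec(label: str) -> ListSpec:
    """Parse a condition label such as ``"1222"`` into a :class:`ListSpec`."""
    if not label or not label.isdigit():
        raise ValueError(f"not a condition label: {label!r}")
    return make_spec([int(c) for c in label])


def word_starts(arrangement: Arrangement) -> tuple[int, ...]:
    """1-based word position at which each chunk of an arrangement begins."""
    starts, pos = [], 1
    for size in arrangement:
        starts.append(pos)
        pos += size
    return tuple(starts)


@dataclass(frozen=True)
class NoTripleStartAt:
    """Arrangement constraint: no chunk of size 3 may begin at ``position``.

    With seven-word lists, ``NoTripleStartAt(5)`` is equivalent to "no list
    ends in a triple".
    """

    position: int

    def __call__(self, arrangement: Arrangement) -> bool:
        return all(
            not (size == 3 and start == self.position)
            for size, start in zip(arrangement, word_starts(arrangement))
        )

    def __str__(self) -> str:
        return f"no_triple_start_at({self.position})"


def parse_constraint(text: str | None) -> Constraint:
    """Parse ``None``/``"none"`` or ``"no_triple_start_at(P)"``."""
    if text is None or text == "none":
        return None
    if text.startswith("no_triple_start_at(") and text.endswith(")"):
        return NoTripleStartAt(int(text[len("no_triple_start_at(") : -1]))
    raise ValueError(f"unknown constraint: {text!r}")


def enumerate_arrangements(
    spec: ListSpec, constraint: Constraint = None
) -> tuple[Arrangement, ...]:
    """All distinct orderings of the composition multiset, constraint applied.

    Returned in lexicographic order (deterministic).  Raises ``ValueError``
    when the constraint eliminates every arrangement.
    """
    arrangements = sorted(set(permutations(spec.composition)))
    if constraint is not None:
        arrangements = [a for a in arrangements if constraint(a)]
    if not arrangements:
        raise ValueError(
            f"constraint {constraint} eliminates every arrangement of {spec.label}"
        )
    return tuple(arrangements)


@dataclass(frozen=True)
class ChunkToken:
    """One chunk of a concrete trial list: its size and its word identities."""

    size: int
    words: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.words) != self.size:
            raise ValueError("token word count must equal chunk size")

    @property
    def is_prelearned(self) -> bool:
        return self.size > 1


@dataclass(frozen=True)
class TrialList:
    """A concrete ordered trial list realising exactly one :class:`ListSpec`.

    Word identities are opaque integers; the model and all scoring schemes are
    symbol-agnostic, so the published vocabulary never enters any computation.
    """

    tokens: tuple[ChunkToken, ...]

    @property
    def arrangement(self) -> Arrangement:
        return tuple(t.size for t in self.tokens)

    @property
    def spec(self) -> ListSpec:
        return make_spec(self.arrangement)

    @property
    def words(self) -> tuple[int, ...]:
        return tuple(w for t in self.tokens for w in t.words)

    @property
    def n_words(self) -> int:
        return sum(t.size for t in self.tokens)

    @property
    def chunk_starts(self) -> tuple[int, ...]:
        return word_starts(self.arrangement)

    def word_chunk_index(self) -> tuple[int, ...]:
        """For each word position (0-based order), the 1-based chunk index."""
        return tuple(
            ci + 1 for ci, t in enumerate(self.tokens) for _ in range(t.size)
        )

    def word_classes(self) -> tuple[str, ...]:
        """Per word position, ``"singleton"`` or ``"chunk"`` (member)."""
        return tuple(
            "singleton" if t.size == 1 else "chunk"
            for t in self.tokens
            for _ in range(t.size)
        )


def sample_trial(
    spec: ListSpec,
    constraint: Constraint = None,
    rng: np.random.Generator | int | None = None,
    word_pool: Sequence[int] | None = None,
) -> TrialList:
    """Sample a trial list: uniform over admissible arrangements, words drawn
    without replacement from ``word_pool`` (default ``0..n_words-1``).

    Reproducible when ``rng`` is a seeded generator or an integer seed.
    """
    rng = np.random.default_rng(rng)
    arrangements = enumerate_arrangements(spec, constraint)
    arrangement = arrangements[int(rng.integers(len(arrangements)))]
    if word_pool is None:
        word_pool = range(spec.n_words)
    pool = list(word_pool)
    if len(set(pool)) < spec.n_words:
        raise ValueError(
            f"word pool has {len(set(pool))} distinct words; need {spec.n_words}"
        )
    chosen = rng.choice(np.asarray(sorted(set(pool))), size=spec.n_words, replace=False)
    words = iter(int(w) for w in chosen)
    tokens = tuple(
        ChunkToken(size, tuple(next(words) for _ in range(size)))
        for size in arrangement
    )
    return TrialList(tokens)


def composite_positions(
    spec: ListSpec,
    constraint: Constraint = None,
    kind: str = "singleton",
) -> dict[int, tuple[Arrangement, ...]]:
    """Map each word position to the arrangements placing a ``kind`` word there.

    ``kind`` is ``"singleton"`` or ``"chunk"`` (member of a multiword chunk).
    Composite serial-position curves average the contributing arrangements
    with equal weight; the weight of each listed arrangement at a position is
    ``1 / len(entry)``.

    Raises
    ------
    ValueError
        If ``kind="singleton"`` and the composition has no singleton (an
        all-multiword list has no singleton curve).
    """
    if kind not in ("singleton", "chunk"):
        raise ValueError(f"kind must be 'singleton' or 'chunk', got {kind!r}")
    if kind == "singleton" and not spec.has_singleton:
        raise ValueError(f"composition {spec.label} contains no singleton")
    if kind == "chunk" and spec.n_multiword == 0:
        raise ValueError(f"composition {spec.label} contains no multiword chunk")
    out: dict[int, list[Arrangement]] = {}
    for arrangement in enumerate_arrangements(spec, constraint):
        for size, start in zip(arrangement, word_starts(arrangement)):
            wanted = (size == 1) if kind == "singleton" else (size > 1)
            if wanted:
                for p in range(start, start + size):
                    out.setdefault(p, []).append(arrangement)
    return {p: tuple(arrs) for p, arrs in sorted(out.items())}
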