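"""Primacy-gradient model of immediate serial recall with chunked lists.

Encoding sets up an activation gradient over *chunks*: the first chunk gets
the peak activation and each successive chunk one step less (a prelearned
pair or triple counts as a single item on the gradient; optionally its step
can be scaled by ``chunk_step_mult``).  Recall proceeds in cycles: zero-mean
Gaussian selection noise is added to the activations of the not-yet-recalled
chunks and the largest wins; the winner's (noise-free) activation plus
omission noise is compared with the omission threshold — above it the chunk's
words are emitted in their within-chunk order, otherwise one "blank" per
word.  The winner is suppressed either way, and the remaining activations are
multiplied by the decay factor after every cycle (once per cycle by default,
or once per *word* of the processed chunk under the ``per_word`` variant).

Because a multiword chunk is selected, emitted and omitted as a unit, chunk
recall is all-or-none by construction, and the response always has exactly
``n_words`` entries.

The default configuration is the five-parameter model (peak activation,
selection noise, omission noise, omission threshold, decay) with a unit step;
``chunk_step_mult`` and ``decay_cycles_per_chunk`` are the two structural
variants.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import (
    Arrangement,
    Constraint,
    ListSpec,
    TrialList,
    composite_positions,
    enumerate_arrangements,
    word_starts,
)
from .scoring import BLANK

__all__ = [
    "ModelParams",
    "RecallTrace",
    "CycleRecord",
    "encode",
    "recall",
    "predict_curves",
    "predict_score_table",
    "reduced_model",
    "REDUCED_FREE_PARAMETERS",
    "closed_form_emission_probs",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the primacy-gradient recall model.

    peak:
        Activation of the first chunk (dimensionless).
    step:
        Activation decrement per preceding chunk; 1 unit by default.
    sigma_select:
        SD of the zero-mean Gaussian selection noise, drawn fresh each cycle.
    sigma_omit:
        SD of the omission noise added to the selected chunk's activation.
    theta:
        Omission threshold; the chunk is emitted iff activation + noise
        exceeds it (strictly).
    decay:
        Multiplicative retention factor applied to the remaining activations
        after each recall cycle, in (0, 1].
    chunk_step_mult:
        Multiplier on the decrement caused by a multiword chunk (1.0 =
        a chunk costs exactly one step, like a singleton).
    decay_cycles_per_chunk:
        ``"one"`` — one decay application per recall cycle; ``"per_word"`` —
        as many applications as the processed chunk has words (a triple
        causes three cycles of decay for the items still to be recalled).
    """

    peak: float = 6.0
    step: float = 1.0
    sigma_select: float = 0.5
    sigma_omit: float = 1.0
    theta: float = 0.0
    decay: float = 1.0
    chunk_step_mult: float = 1.0
    decay_cycles_per_chunk: str = "one"

    def __post_init__(self) -> None:
        if self.sigma_select < 0 or self.sigma_omit < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must lie in (0, 1]")
        if self.chunk_step_mult <= 0:
            raise ValueError("chunk_step_mult must be positive")
        if self.decay_cycles_per_chunk not in ("one", "per_word"):
            raise ValueError("decay_cycles_per_chunk must be 'one' or 'per_word'")

    def replace(self, **changes: Any) -> "ModelParams":
        return replace(self, **changes)


#: Free parameters of the reduced two-parameter configuration.
REDUCED_FREE_PARAMETERS = ("step", "sigma_omit")


def reduced_model(params: ModelParams | None = None, peak: float = 6.0) -> ModelParams:
    """The reduced configuration: omission threshold fixed at zero, no decay,
    no selection noise; step and omission noise are the free parameters (peak
    is held fixed).  Most of the serial-position pattern is carried by
    omissions, which this stripped-down model captures on its own.
    """
    base = params if params is not None else ModelParams(peak=peak)
    return base.replace(theta=0.0, decay=1.0, sigma_select=0.0)


def encode(trial: TrialList | Sequence[int], params: ModelParams) -> np.ndarray:
    """Initial activation gradient over chunks.

    ``a[0] = peak`` and each following chunk sits ``step`` lower (scaled by
    ``chunk_step_mult`` when the preceding chunk is multiword).
    """
    sizes = trial.arrangement if isinstance(trial, TrialList) else tuple(trial)
    if not sizes:
        raise ValueError("cannot encode an empty list")
    drops = [
        params.step * (params.chunk_step_mult if s > 1 else 1.0) for s in sizes[:-1]
    ]
    return params.peak - np.concatenate([[0.0], np.cumsum(drops)])


@dataclass(frozen=True)
class CycleRecord:
    """One recall cycle: who competed, who won, and what happened."""

    chosen: int
    competitors: tuple[float, ...]
    activation: float
    omission_draw: float
    emitted: bool
    post_activations: tuple[float, ...]


@dataclass(frozen=True)
class RecallTrace:
    cycles: tuple[CycleRecord, ...]

    @property
    def selection_order(self) -> tuple[int, ...]:
        return tuple(c.chosen for c in self.cycles)


def recall(
    trial: TrialList,
    params: ModelParams,
    rng: np.random.Generator | int | None = None,
) -> tuple[tuple[int, ...], RecallTrace]:
    """Simulate one paced recall trial.

    Returns the response (word ids and BLANK markers, length ``n_words``) and
    a full per-cycle trace.  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(rng)
    k = len(trial.tokens)
    sizes = np.array(trial.arrangement)
    a = encode(trial, params).astype(float)
    alive = np.ones(k, dtype=bool)
    response: list[int] = []
    cycles: list[CycleRecord] = []
    for _ in range(k):
        eps = (
            rng.normal(0.0, params.sigma_select, size=k)
            if params.sigma_select > 0
            else np.zeros(k)
        )
        v = np.where(alive, a + eps, -np.inf)
        j = int(np.argmax(v))
        omega = rng.normal(0.0, params.sigma_omit) if params.sigma_omit > 0 else 0.0
        u = a[j] + omega
        emitted = bool(u > params.theta)
        if emitted:
            response.extend(trial.tokens[j].words)
        else:
            response.extend([BLANK] * trial.tokens[j].size)
        alive[j] = False
        n_decays = int(sizes[j]) if params.decay_cycles_per_chunk == "per_word" else 1
        post = np.where(alive, a * params.decay**n_decays, a)
        cycles.append(
            CycleRecord(
                chosen=j,
                competitors=tuple(float(x) for x in v),
                activation=float(a[j]),
                omission_draw=float(omega),
                emitted=emitted,
                post_activations=tuple(float(x) for x in post),
            )
        )
        a = post
    return tuple(response), RecallTrace(tuple(cycles))


# ---------------------------------------------------------------------------
# Vectorised Monte-Carlo curves
# ---------------------------------------------------------------------------


def _simulate_selection(
    sizes: Arrangement,
    params: ModelParams,
    n: int,
    rng: np.random.Generator,
    antithetic: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Selection dynamics for ``n`` trials of one arrangement.

    Returns ``order`` (n, k): chunk selected at each cycle, and
    ``act_at_sel`` (n, k): the selected chunk's activation at that cycle.
    Suppression and decay do not depend on the omission outcome, so the
    omission stage can be handled afterwards (sampled or marginalised).
    """
    k = len(sizes)
    sizes_arr = np.asarray(sizes)
    if params.sigma_select > 0:
        if antithetic:
            half = (n + 1) // 2
            eps = rng.standard_normal((half, k, k))
            eps = np.concatenate([eps, -eps], axis=0)[:n]
        else:
            eps = rng.standard_normal((n, k, k))
        eps *= params.sigma_select
    else:
        eps = None
    a = np.broadcast_to(encode(sizes, params), (n, k)).copy()
    alive = np.ones((n, k), dtype=bool)
    order = np.empty((n, k), dtype=np.int64)
    act_at_sel = np.empty((n, k))
    rows = np.arange(n)
    for t in range(k):
        v = a + eps[:, t, :] if eps is not None else a.copy()
        v[~alive] = -np.inf
        j = np.argmax(v, axis=1)
        order[:, t] = j
        act_at_sel[:, t] = a[rows, j]
        alive[rows, j] = False
        if t < k - 1 and params.decay != 1.0:
            if params.decay_cycles_per_chunk == "per_word":
                a = a * params.decay ** sizes_arr[j][:, None]
            else:
                a = a * params.decay
    return order, act_at_sel


def _emission(
    act_at_sel: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Per-cycle emission: probabilities (marginalised) or sampled 0/1."""
    if rng is None:
        if params.sigma_omit > 0:
            return ndtr((act_at_sel - params.theta) / params.sigma_omit)
        return (act_at_sel > params.theta).astype(float)
    omega = rng.standard_normal(act_at_sel.shape) * params.sigma_omit
    return (act_at_sel + omega > params.theta).astype(float)


def _word_scores(
    sizes: Arrangement,
    order: np.ndarray,
    emit: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial expected strict and item scores by word position.

    ``emit`` holds per-cycle emission probabilities (or sampled indicators).
    A word is item-correct iff its chunk is emitted; strict-correct iff in
    addition the chunk's output start equals its list start (chunks write
    their words in within-chunk order, so partial positional overlap with a
    displaced chunk is impossible with distinct word identities).
    """
    n, k = order.shape
    sizes_arr = np.asarray(sizes)
    starts = np.asarray(word_starts(sizes))
    rows = np.arange(n)
    s_sel = sizes_arr[order]  # (n, k) sizes in selection order
    out_start_cycle = 1 + np.concatenate(
        [np.zeros((n, 1), dtype=np.int64), np.cumsum(s_sel, axis=1)[:, :-1]], axis=1
    )
    out_start = np.empty((n, k), dtype=np.int64)
    emit_by_chunk = np.empty((n, k))
    for t in range(k):
        out_start[rows, order[:, t]] = out_start_cycle[:, t]
        emit_by_chunk[rows, order[:, t]] = emit[:, t]
    aligned = out_start == starts
    item_chunk = emit_by_chunk
    strict_chunk = emit_by_chunk * aligned
    word_chunk = np.repeat(np.arange(k), sizes_arr)
    return strict_chunk[:, word_chunk], item_chunk[:, word_chunk]


def _ld_scores_from_batch(
    trial_template: TrialList,
    order: np.ndarray,
    emitted: np.ndarray,
) -> np.ndarray:
    """Item-level Levenshtein credits per word position for sampled trials."""
    from .scoring import ld_item_score

    tokens = trial_template.tokens
    n, k = order.shape
    out = np.empty((n, trial_template.n_words))
    target = trial_template.words
    for i in range(n):
        resp: list[int] = []
        for t in range(k):
            j = int(order[i, t])
            if emitted[i, t]:
                resp.extend(tokens[j].words)
            else:
                resp.extend([BLANK] * tokens[j].size)
        out[i] = ld_item_score(target, resp).as_floats()
    return out


def _allocate(n_iter: int, n_groups: int) -> list[int]:
    base, rem = divmod(n_iter, n_groups)
    return [base + (1 if i < rem else 0) for i in range(n_groups)]


def predict_curves(
    spec: ListSpec,
    constraint: Constraint,
    params: ModelParams,
    n_iter: int,
    seed: int | Sequence[int] = 0,
    schemes: Sequence[str] = ("strict", "item"),
    marginalize_omissions: bool = True,
    antithetic: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo mean scores by composite word position for one condition.

    ``n_iter`` simulated trials are allocated as evenly as possible across the
    admissible arrangements (composite curves weight arrangements equally, so
    a deterministic allocation only removes sampling noise in the weights).
    Singleton and chunk-member slices are reported separately.

    By default the omission stage is replaced by its exact conditional
    probability given the selection sequence (the omission draw is exogenous
    to the dynamics), and selection noise is drawn antithetically — both are
    pure variance-reduction devices: the estimand is unchanged.  The ``LD``
    scheme requires materialised responses and therefore always samples
    omissions.

    Returns a frame with columns scheme, condition, word_class,
    word_position, mean, n; reproducible bit-for-bit under a fixed seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    unknown = set(schemes) - {"strict", "item", "LD"}
    if unknown:
        raise ValueError(f"unknown schemes: {sorted(unknown)}")
    seed_key = [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]
    arrangements = enumerate_arrangements(spec, constraint)
    counts = _allocate(n_iter, len(arrangements))

    # per-arrangement mean score by word position: {scheme: {arr: (means, n)}}
    per_arr: dict[str, dict[Arrangement, tuple[np.ndarray, int]]] = {
        s: {} for s in schemes
    }
    need_ld = "LD" in schemes
    for ai, (arrangement, n_a) in enumerate(zip(arrangements, counts)):
        if n_a == 0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence(seed_key + [ai]))
        order, act = _simulate_selection(arrangement, params, n_a, rng, antithetic)
        emit_rng = None if marginalize_omissions else rng
        emit = _emission(act, params, emit_rng)
        strict_w, item_w = _word_scores(arrangement, order, emit)
        if "strict" in schemes:
            per_arr["strict"][arrangement] = (strict_w.mean(axis=0), n_a)
        if "item" in schemes:
            per_arr["item"][arrangement] = (item_w.mean(axis=0), n_a)
        if need_ld:
            emitted = _emission(act, params, rng) if marginalize_omissions else emit
            template = _template_trial(arrangement)
            ld_w = _ld_scores_from_batch(template, order, emitted.astype(bool))
            per_arr["LD"][arrangement] = (ld_w.mean(axis=0), n_a)

    rows = []
    for kind in ("singleton", "chunk"):
        try:
            comp = composite_positions(spec, constraint, kind=kind)
        except ValueError:
            continue
        for position, arrs in comp.items():
            for scheme in schemes:
                vals = [per_arr[scheme][a][0][position - 1] for a in per_arr[scheme] if a in arrs]
                ns = [per_arr[scheme][a][1] for a in per_arr[scheme] if a in arrs]
                if not vals:
                    continue
                rows.append(
                    (
                        scheme,
                        spec.label,
                        kind,
                        position,
                        float(np.mean(vals)),
                        int(np.sum(ns)),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["scheme", "condition", "word_class", "word_position", "mean", "n"],
    ).sort_values(["scheme", "word_class", "word_position"], ignore_index=True)


def _template_trial(arrangement: Arrangement) -> TrialList:
    """A trial list with canonical word ids 0..n-1 for a given arrangement.

    Scores are invariant under consistent relabelling of word ids, so curves
    computed on the template hold for any sampled vocabulary.
    """
    from .design import ChunkToken

    words = iter(range(sum(arrangement)))
    return TrialList(
        tuple(
            ChunkToken(s, tuple(next(words) for _ in range(s))) for s in arrangement
        )
    )


def predict_score_table(
    designs: Sequence[tuple[ListSpec, Constraint]],
    params: ModelParams,
    n_iter: int,
    seed: int = 0,
    schemes: Sequence[str] = ("strict", "item"),
    **kwargs: Any,
) -> pd.DataFrame:
    """Concatenated :func:`predict_curves` over a design set.

    Each condition gets its own independent substream derived from ``seed``
    and its index in the (ordered) design list.
    """
    tables = [
        predict_curves(
            spec, constraint, params, n_iter, seed=(seed, si), schemes=schemes, **kwargs
        )
        for si, (spec, constraint) in enumerate(designs)
    ]
    return pd.concat(tables, ignore_index=True)


def closed_form_emission_probs(
    sizes: Arrangement, params: ModelParams
) -> np.ndarray:
    """Noiseless-selection emission probabilities, chunk by chunk.

    With ``sigma_select = 0`` chunks are selected in list order, so chunk j
    (1-based) is emitted with probability
    Phi((a_j * decay**E_j - theta) / sigma_omit), where ``E_j`` counts the
    decay applications before cycle j (j-1, or the number of preceding words
    under the ``per_word`` variant).  Degenerates to a step function of the
    threshold when ``sigma_omit = 0``.
    """
    a = encode(sizes, params)
    if params.decay_cycles_per_chunk == "per_word":
        exponents = np.concatenate([[0], np.cumsum(sizes[:-1])])
    else:
        exponents = np.arange(len(sizes))
    decayed = a * params.decay**exponents
    if params.sigma_omit > 0:
        return ndtr((decayed - params.theta) / params.sigma_omit)
    return (decayed > params.theta).astype(float)
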