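"""Synthetic participant corpora under two generating processes.

The study's raw behavioural data are not deposited, so every pipeline stage
is exercised against synthetic corpora whose statistical structure follows
one of the two competing accounts of chunking:

``compression``
    Chunks are recoded into single storage units: the corpus is simulated
    directly with the chunk-atomic primacy model.  Adding multiword chunks
    shortens the chunk gradient, so *all* items — singletons included —
    benefit from chunkier lists.

``redintegration``
    Chunks exist only in long-term memory: the trace in short-term memory is
    word-by-word (every word its own chunk on the gradient), and after recall
    each prelearned chunk with at least one member recalled is *repaired* to
    full recall with completion probability ρ, restoring its members at their
    correct list positions.  The benefit of chunking is then confined to the
    chunks themselves; singleton recall stays flat across list compositions.

A two-alternative forced-choice (2AFC) recognition corpus is derived from the
same generating processes: per word, the retained/forgotten state is taken
from the simulated recall outcome, and a forgotten word is answered correctly
at the guessing rate.  This retention-probability-plus-guessing construction
is a synthetic stand-in — there is no comparable process model of the 2AFC
task — and is labelled as such.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import Corpus, TrialRecord
from .design import (
    ChunkToken,
    Constraint,
    ListSpec,
    TrialList,
    sample_trial,
)
from .model import ModelParams, recall
from .scoring import BLANK, item_score

__all__ = [
    "GeneratorConfig",
    "DiagnosticReport",
    "generate_recall_corpus",
    "generate_2afc_corpus",
    "diagnostic_contrast",
    "exp1_redintegration_config",
    "compression_config",
]

PROCESSES = ("compression", "redintegration")


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic-participant generator.

    ``model_params`` drives the chunk-atomic simulation for the compression
    process, or the word-by-word base simulation for the redintegration
    process.  ``completion_prob`` (ρ) is the redintegration repair
    probability; ``guess_prob`` the 2AFC guessing rate.  Trial counts follow
    the study conditions: 28 participants, 16 trials per condition each
    (eight blocks of eight trials over four conditions).
    """

    process: str
    model_params: ModelParams = field(default_factory=ModelParams)
    completion_prob: float = 0.0
    guess_prob: float = 0.5
    n_participants: int = 28
    trials_per_condition: int = 16
    word_pool_size: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValueError(f"process must be one of {PROCESSES}")
        if not 0 <= self.completion_prob <= 1:
            raise ValueError("completion_prob must lie in [0, 1]")
        if not 0 <= self.guess_prob <= 1:
            raise ValueError("guess_prob must lie in [0, 1]")

    def replace(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)


def compression_config(master_seed: int = 0, **overrides) -> GeneratorConfig:
    """A compression-process generator at the model's standard operating point
    (peak 6, unit step, selection SD 0.5, omission SD 1, threshold 1,
    decay 0.95)."""
    cfg = GeneratorConfig(
        process="compression",
        model_params=ModelParams(
            peak=6.0, step=1.0, sigma_select=0.5, sigma_omit=1.0, theta=1.0, decay=0.95
        ),
        master_seed=master_seed,
    )
    return cfg.replace(**overrides)


def exp1_redintegration_config(master_seed: int = 0, **overrides) -> GeneratorConfig:
    """Redintegration generator calibrated to the flat 2AFC pattern.

    With no decay and a zero threshold the item-retention probability of the
    word at position j is exactly Phi(peak - step*(j-1)); a peak of 0.35 and
    step of 0.15 give a mean singleton retention of about .46 across a
    seven-word list, i.e. 2AFC accuracy (1 + .46)/2 ≈ .73, and a completion
    probability of .56 lifts pair members to about .60 retention, i.e.
    accuracy ≈ .80 — both flat across list compositions because the base
    trace is word-by-word regardless of condition.
    """
    cfg = GeneratorConfig(
        process="redintegration",
        model_params=ModelParams(
            peak=0.35,
            step=0.15,
            sigma_select=0.4,
            sigma_omit=1.0,
            theta=0.0,
            decay=1.0,
        ),
        completion_prob=0.56,
        master_seed=master_seed,
    )
    return cfg.replace(**overrides)


def _singletonized(trial: TrialList) -> TrialList:
    """The same word list with every word treated as its own chunk."""
    return TrialList(tuple(ChunkToken(1, (w,)) for w in trial.words))


def _simulate_response(
    trial: TrialList, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[int, ...]:
    if config.process == "compression":
        response, _ = recall(trial, config.model_params, rng)
        return response
    # redintegration: word-by-word trace, then chunk-completion repair
    response, _ = recall(_singletonized(trial), config.model_params, rng)
    resp = list(response)
    for token, start in zip(trial.tokens, trial.chunk_starts):
        if not token.is_prelearned:
            continue
        present = any(w in resp for w in token.words)
        if present and rng.random() < config.completion_prob:
            for offset, w in enumerate(token.words):
                p = start - 1 + offset
                if resp[p] == w:
                    continue
                if w in resp:
                    # member recalled out of place: swap it home, keeping the
                    # displaced word in the response (repair reconstructs the
                    # chunk's trace without consuming anyone else's)
                    q = resp.index(w)
                    resp[p], resp[q] = resp[q], resp[p]
                else:
                    displaced = resp[p]
                    resp[p] = w
                    if displaced != BLANK and displaced not in token.words:
                        if BLANK in resp:
                            resp[resp.index(BLANK)] = displaced
                        # with no omission slot left the displaced word is lost
    return tuple(resp)


def generate_recall_corpus(
    config: GeneratorConfig,
    designs: Sequence[tuple[ListSpec, Constraint]],
) -> Corpus:
    """Simulate a full serial-recall corpus over a design set.

    Every trial draws its own substream from the master seed (keyed by
    condition, participant and trial index), so the corpus is reproducible
    end to end and stable under changes to the trial counts of *other*
    conditions.
    """
    records = []
    trial_id = 0
    for di, (spec, constraint) in enumerate(designs):
        for participant in range(config.n_participants):
            for t in range(config.trials_per_condition):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.master_seed, di, participant, t]
                    )
                )
                trial = sample_trial(
                    spec,
                    constraint,
                    rng=rng,
                    word_pool=range(config.word_pool_size),
                )
                response = _simulate_response(trial, config, rng)
                records.append(
                    TrialRecord(trial_id, participant, spec.label, trial, response)
                )
                trial_id += 1
    return Corpus(records, master_seed=config.master_seed, process=config.process)


# ---------------------------------------------------------------------------
# 2AFC recognition
# ---------------------------------------------------------------------------

_FOIL_BASE = {"singleton": 100_000, "chunk": 200_000}


def _probe_order(
    trial: TrialList, rng: np.random.Generator, max_tries: int = 200
) -> list[int]:
    """Random probe order with no two members of one chunk probed in a row."""
    chunk_of = trial.word_chunk_index()
    n = trial.n_words
    for _ in range(max_tries):
        order = list(rng.permutation(n))
        ok = all(
            chunk_of[a] != chunk_of[b]
            or trial.tokens[chunk_of[a] - 1].size == 1
            for a, b in zip(order, order[1:])
        )
        if ok:
            return order
    raise RuntimeError("could not find an admissible probe order")


def generate_2afc_corpus(
    config: GeneratorConfig,
    designs: Sequence[tuple[ListSpec, Constraint]],
) -> pd.DataFrame:
    """Simulate 2AFC probe responses for every word of every trial.

    A word answered from memory is always correct; a word not retained is
    correct with probability ``guess_prob``.  Retention is the item-scored
    recall outcome of the generating process (including redintegration
    repair).  Foils are fresh words of the probed word's class (singleton vs
    chunk member), mirroring the same-condition foil rule; members of one
    chunk are never probed successively.
    """
    rows = []
    trial_id = 0
    foil_counter = 0
    for di, (spec, constraint) in enumerate(designs):
        for participant in range(config.n_participants):
            for t in range(config.trials_per_condition):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.master_seed, di, participant, t, 7]
                    )
                )
                trial = sample_trial(
                    spec, constraint, rng=rng, word_pool=range(config.word_pool_size)
                )
                response = _simulate_response(trial, config, rng)
                retained = item_score(trial.words, response)
                classes = trial.word_classes()
                words = trial.words
                for probe_rank, p in enumerate(_probe_order(trial, rng)):
                    correct = bool(retained[p]) or (rng.random() < config.guess_prob)
                    foil = _FOIL_BASE[classes[p]] + foil_counter
                    foil_counter += 1
                    rows.append(
                        (
                            trial_id,
                            participant,
                            spec.label,
                            probe_rank + 1,
                            p + 1,
                            classes[p],
                            words[p],
                            foil,
                            bool(correct),
                        )
                    )
                trial_id += 1
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "participant",
            "condition",
            "probe_rank",
            "word_position",
            "word_class",
            "probe_word",
            "foil_word",
            "correct",
        ],
    )


# ---------------------------------------------------------------------------
# Compression-vs-redintegration diagnostic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticReport:
    """Outcome of the compression-vs-redintegration contrast.

    ``singleton_trend`` is the singleton mean-score difference between the
    condition with the most multiword chunks and the one with the fewest;
    compression predicts it positive, redintegration predicts it flat while
    chunk members outscore singletons (``chunk_advantage``).  Confidence
    intervals are percentile bootstrap over trials.
    """

    condition_means: pd.DataFrame
    singleton_trend: float
    trend_ci: tuple[float, float]
    chunk_advantage: float | None
    advantage_ci: tuple[float, float] | None
    verdict: str
    n_boot: int
    seed: int


def _bootstrap_mean_diff(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, n_boot: int
) -> np.ndarray:
    """Bootstrap distribution of mean(a) - mean(b), resampling each group."""
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    return a[ia].mean(axis=1) - b[ib].mean(axis=1)


def diagnostic_contrast(
    scores: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.99,
    min_trials: int = 20,
) -> DiagnosticReport:
    """Classify a scored corpus as compression- or redintegration-like.

    ``scores`` is a long per-word frame (columns trial_id, condition,
    word_class, score — the :func:`chunkrecall.scoring.score_corpus` output,
    typically under item scoring).  Requires singleton scores in at least two
    conditions differing in their number of multiword chunks.

    Corpora with fewer than ``min_trials`` trials in any contrasted condition
    are reported as indeterminate outright: percentile bootstrap intervals
    built from a handful of trials degenerate (they can exclude zero on the
    strength of two or three observations) and carry no evidential weight.
    """
    from .design import parse_spec

    singles = scores[scores.word_class == "singleton"]
    conds = sorted(
        singles.condition.unique(), key=lambda c: parse_spec(c).n_multiword
    )
    if len(conds) < 2:
        raise ValueError("need singleton scores in at least 2 conditions")

    per_trial = (
        singles.groupby(["condition", "trial_id"])["score"].mean().reset_index()
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    lo_cond, hi_cond = conds[0], conds[-1]
    a = per_trial.loc[per_trial.condition == hi_cond, "score"].to_numpy()
    b = per_trial.loc[per_trial.condition == lo_cond, "score"].to_numpy()
    trend = float(a.mean() - b.mean())
    q = (1 - ci_level) / 2
    boot = _bootstrap_mean_diff(a, b, rng, n_boot)
    trend_ci = (float(np.quantile(boot, q)), float(np.quantile(boot, 1 - q)))

    chunks = scores[scores.word_class == "chunk"]
    advantage = None
    advantage_ci = None
    if len(chunks):
        mixed = sorted(set(chunks.condition) & set(singles.condition))
        c = (
            chunks[chunks.condition.isin(mixed)]
            .groupby(["condition", "trial_id"])["score"]
            .mean()
            .to_numpy()
        )
        s = (
            singles[singles.condition.isin(mixed)]
            .groupby(["condition", "trial_id"])["score"]
            .mean()
            .to_numpy()
        )
        if len(c) and len(s):
            advantage = float(c.mean() - s.mean())
            boot_adv = _bootstrap_mean_diff(c, s, rng, n_boot)
            advantage_ci = (
                float(np.quantile(boot_adv, q)),
                float(np.quantile(boot_adv, 1 - q)),
            )

    if min(len(a), len(b)) < min_trials:
        verdict = "indeterminate"
    elif trend_ci[0] > 0:
        verdict = "compression-signature"
    elif (
        trend_ci[0] <= 0 <= trend_ci[1]
        and advantage_ci is not None
        and advantage_ci[0] > 0
    ):
        verdict = "redintegration-signature"
    else:
        verdict = "indeterminate"

    means = (
        scores.groupby(["condition", "word_class"])["score"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    return DiagnosticReport(
        condition_means=means,
        singleton_trend=trend,
        trend_ci=trend_ci,
        chunk_advantage=advantage,
        advantage_ci=advantage_ci,
        verdict=verdict,
        n_boot=n_boot,
        seed=seed,
    )
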