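"""Synthetic corpora: generating processes, repair, 2AFC, diagnostics."""

import numpy as np
import pytest

from chunkrecall import (
    GeneratorConfig,
    ModelParams,
    chunk_cohesion,
    compression_config,
    diagnostic_contrast,
    exp1_redintegration_config,
    generate_2afc_corpus,
    generate_recall_corpus,
    score_corpus,
)
from chunkrecall.design import parse_spec

TRIPLE_DESIGNS = [(parse_spec(l), None) for l in ("1111111", "11113", "133")]


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(process="magic")
    with pytest.raises(ValueError):
        GeneratorConfig(process="redintegration", completion_prob=1.5)


def test_generation_is_reproducible():
    cfg = compression_config(master_seed=3, n_participants=2, trials_per_condition=4)
    a = generate_recall_corpus(cfg, TRIPLE_DESIGNS)
    b = generate_recall_corpus(cfg, TRIPLE_DESIGNS)
    assert [r.response for r in a] == [r.response for r in b]
    assert [r.trial.words for r in a] == [r.trial.words for r in b]


def test_repair_disabled_equals_base_process_on_singleton_lists():
    """With an all-singleton design the two processes share the generating
    machinery, so identical master seeds give identical corpora regardless
    of the completion probability."""
    designs = [(parse_spec("111111"), None)]
    base = dict(n_participants=2, trials_per_condition=10, master_seed=9)
    comp = generate_recall_corpus(compression_config(**base), designs)
    red = generate_recall_corpus(
        compression_config(**base).replace(process="redintegration", completion_prob=0.7),
        designs,
    )
    assert [r.response for r in comp] == [r.response for r in red]


def test_full_repair_gives_perfect_cohesion():
    cfg = exp1_redintegration_config(
        master_seed=4, n_participants=2, trials_per_condition=30
    ).replace(completion_prob=1.0)
    corpus = generate_recall_corpus(cfg, [(parse_spec("1113"), None)])
    assert chunk_cohesion(corpus.pairs(), 3).pooled == 1.0


def test_zero_repair_breaks_cohesion():
    cfg = exp1_redintegration_config(
        master_seed=4, n_participants=2, trials_per_condition=30
    ).replace(completion_prob=0.0)
    corpus = generate_recall_corpus(cfg, [(parse_spec("1113"), None)])
    assert chunk_cohesion(corpus.pairs(), 3).pooled < 1.0


def test_repair_never_destroys_other_items():
    """Chunk completion reconstructs the chunk's own trace; every other
    recalled word survives the repair (it may move, not vanish)."""
    cfg = exp1_redintegration_config(
        master_seed=8, n_participants=1, trials_per_condition=300
    ).replace(completion_prob=1.0)
    zero = cfg.replace(completion_prob=0.0)
    corpus = generate_recall_corpus(cfg, [(parse_spec("133"), None)])
    base = generate_recall_corpus(zero, [(parse_spec("133"), None)])
    for repaired, raw in zip(corpus, base):
        assert repaired.trial == raw.trial
        raw_words = set(raw.response) - {-1}
        repaired_words = set(repaired.response) - {-1}
        assert raw_words <= repaired_words


# ---------------------------------------------------------------------------
# 2AFC
# ---------------------------------------------------------------------------


def test_2afc_perfect_retention_gives_perfect_accuracy():
    cfg = GeneratorConfig(
        process="compression",
        model_params=ModelParams(
            peak=10, step=0.01, sigma_select=0, sigma_omit=0, theta=-50, decay=1
        ),
        n_participants=2,
        trials_per_condition=10,
        master_seed=1,
    )
    df = generate_2afc_corpus(cfg, [(parse_spec("1222"), None)])
    assert df["correct"].all()


def test_2afc_pure_guessing_hits_the_guess_rate():
    cfg = GeneratorConfig(
        process="compression",
        model_params=ModelParams(
            peak=1, step=0.01, sigma_select=0, sigma_omit=0, theta=50, decay=1
        ),
        guess_prob=0.5,
        n_participants=10,
        trials_per_condition=30,
        master_seed=2,
    )
    df = generate_2afc_corpus(cfg, [(parse_spec("1222"), None)])
    acc = df["correct"].mean()
    se = np.sqrt(0.25 / len(df))
    assert abs(acc - 0.5) < 4 * se


def test_2afc_probe_order_never_tests_chunk_members_successively():
    from chunkrecall.design import sample_trial
    from chunkrecall.synthdata import _probe_order

    rng = np.random.default_rng(0)
    for label in ("1222", "133", "33"):
        for _ in range(50):
            trial = sample_trial(parse_spec(label), rng=rng)
            order = _probe_order(trial, rng)
            assert sorted(order) == list(range(trial.n_words))
            chunk_of = trial.word_chunk_index()
            for a, b in zip(order, order[1:]):
                same_chunk = chunk_of[a] == chunk_of[b]
                assert not (same_chunk and trial.tokens[chunk_of[a] - 1].size > 1)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _item_scores(cfg, designs):
    corpus = generate_recall_corpus(cfg, designs)
    return score_corpus(corpus.pairs(), "item", trial_ids=corpus.trial_ids())


def test_diagnostic_requires_two_conditions():
    cfg = compression_config(master_seed=1, n_participants=1, trials_per_condition=5)
    scores = _item_scores(cfg, [(parse_spec("1113"), None)])
    with pytest.raises(ValueError, match="2 conditions"):
        diagnostic_contrast(scores)


def test_diagnostic_discriminates_processes_at_moderate_n():
    n = 1200
    comp = compression_config(master_seed=21, n_participants=1, trials_per_condition=n)
    red = exp1_redintegration_config(
        master_seed=22, n_participants=1, trials_per_condition=n
    ).replace(completion_prob=0.8)
    rep_c = diagnostic_contrast(_item_scores(comp, TRIPLE_DESIGNS), seed=0)
    rep_r = diagnostic_contrast(_item_scores(red, TRIPLE_DESIGNS), seed=0)
    assert rep_c.verdict == "compression-signature"
    assert rep_c.singleton_trend > 0.1
    assert rep_r.verdict == "redintegration-signature"
    assert rep_r.chunk_advantage > 0.1


def test_diagnostic_underpowered_corpus_is_indeterminate():
    cfg = compression_config(master_seed=5, n_participants=1, trials_per_condition=2)
    rep = diagnostic_contrast(_item_scores(cfg, TRIPLE_DESIGNS), seed=0)
    assert rep.verdict == "indeterminate"


def test_diagnostic_is_seeded():
    cfg = compression_config(master_seed=2, n_participants=1, trials_per_condition=50)
    scores = _item_scores(cfg, TRIPLE_DESIGNS)
    a = diagnostic_contrast(scores, seed=3)
    b = diagnostic_contrast(scores, seed=3)
    assert a.trend_ci == b.trend_ci and a.advantage_ci == b.advantage_ci
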