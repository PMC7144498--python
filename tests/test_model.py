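"""Primacy-gradient simulator: encoding, recall dynamics, variants, curves."""

import numpy as np
import pytest

from chunkrecall import (
    ModelParams,
    closed_form_emission_probs,
    encode,
    predict_curves,
    recall,
    reduced_model,
    sample_trial,
)
from chunkrecall.design import parse_spec
from chunkrecall.model import REDUCED_FREE_PARAMETERS, _simulate_selection, _emission
from chunkrecall.scoring import BLANK, item_score, ld_item_score, strict_score

NOISELESS = ModelParams(peak=6, step=1, sigma_select=0, sigma_omit=0, theta=0, decay=1)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def test_encode_gradient():
    p = ModelParams(peak=4, step=1, sigma_select=0, sigma_omit=0, theta=0)
    assert np.allclose(encode((1, 1, 1, 1), p), [4, 3, 2, 1])
    # a triple with step multiplier 1.5 costs one and a half steps
    assert np.allclose(encode((3, 1), p.replace(chunk_step_mult=1.5)), [4, 2.5])
    # with multiplier 1 a chunk costs exactly one step: same gradient as singles
    assert np.allclose(encode((1, 1, 1, 3), p), encode((1, 1, 1, 1), p))


def test_params_validation():
    with pytest.raises(ValueError):
        ModelParams(decay=0)
    with pytest.raises(ValueError):
        ModelParams(sigma_select=-1)
    with pytest.raises(ValueError):
        ModelParams(decay_cycles_per_chunk="two")


# ---------------------------------------------------------------------------
# recall dynamics
# ---------------------------------------------------------------------------


def test_noiseless_recall_is_perfect():
    trial = sample_trial(parse_spec("111111"), rng=0)
    response, trace = recall(trial, NOISELESS, rng=0)
    assert response == trial.words
    assert trace.selection_order == tuple(range(6))


def test_noiseless_omission_follows_closed_form_threshold():
    params = NOISELESS.replace(theta=2.5)
    trial = sample_trial(parse_spec("111111"), rng=1)
    response, _ = recall(trial, params, rng=0)
    # activations 6,5,4,3,2,1: chunks 5 and 6 fall at or below the threshold
    assert response[:4] == trial.words[:4]
    assert response[4:] == (BLANK, BLANK)
    probs = closed_form_emission_probs((1,) * 6, params)
    assert np.allclose(probs, [1, 1, 1, 1, 0, 0])


def test_chunks_are_all_or_none_and_suppression_holds():
    params = ModelParams(
        peak=4, step=1, sigma_select=1.0, sigma_omit=1.5, theta=1.0, decay=0.9
    )
    rng = np.random.default_rng(7)
    for _ in range(200):
        trial = sample_trial(parse_spec("1113"), rng=rng)
        response, trace = recall(trial, params, rng=rng)
        assert len(response) == trial.n_words
        assert sorted(trace.selection_order) == list(range(len(trial.tokens)))
        for token, start in zip(trial.tokens, trial.chunk_starts):
            segment = [response[p] for p in range(start - 1, start - 1 + token.size)]
            recalled_words = set(response) - {BLANK}
            inside = [w in recalled_words for w in token.words]
            assert all(inside) or not any(inside)


def test_within_chunk_scores_identical_under_all_schemes():
    params = ModelParams(
        peak=5, step=1, sigma_select=0.8, sigma_omit=1.0, theta=0.5, decay=0.95
    )
    rng = np.random.default_rng(11)
    for _ in range(60):
        trial = sample_trial(parse_spec("133"), rng=rng)
        response, _ = recall(trial, params, rng=rng)
        for scorer in (
            lambda t, r: strict_score(t, r),
            lambda t, r: item_score(t, r),
            lambda t, r: ld_item_score(t, r).as_floats(),
        ):
            values = scorer(trial.words, response)
            pos = 0
            for token in trial.tokens:
                chunk_vals = values[pos : pos + token.size]
                assert len(set(np.round(chunk_vals, 12))) == 1
                pos += token.size


def test_recall_is_reproducible():
    trial = sample_trial(parse_spec("1113"), rng=3)
    params = ModelParams()
    r1, t1 = recall(trial, params, rng=99)
    r2, t2 = recall(trial, params, rng=99)
    assert r1 == r2 and t1 == t2


# ---------------------------------------------------------------------------
# Monte-Carlo curves
# ---------------------------------------------------------------------------


def test_predict_curves_deterministic_under_seed(standard_params):
    spec = parse_spec("1113")
    a = predict_curves(spec, None, standard_params, n_iter=5000, seed=17)
    b = predict_curves(spec, None, standard_params, n_iter=5000, seed=17)
    assert a.equals(b)


def test_noiseless_strict_curve_is_step_function():
    params = NOISELESS.replace(theta=2.5)
    curves = predict_curves(parse_spec("111111"), None, params, n_iter=100, seed=0)
    strict = curves[(curves.scheme == "strict")].sort_values("word_position")
    assert list(strict["mean"]) == [1, 1, 1, 1, 0, 0]


def test_monotone_degradation_with_selection_noise(standard_params):
    means = []
    for sigma in (0.2, 0.8, 1.6):
        curves = predict_curves(
            parse_spec("111111"),
            None,
            standard_params.replace(sigma_select=sigma),
            n_iter=20_000,
            seed=5,
        )
        means.append(curves[curves.scheme == "strict"]["mean"].mean())
    assert means[0] > means[1] > means[2]


def test_sampled_omission_rates_match_closed_form():
    """With no selection noise the simulated emission rates agree with
    Phi((a_j * decay^(j-1) - theta) / sigma_omit) within 3 Monte-Carlo SEs."""
    params = ModelParams(
        peak=4, step=1, sigma_select=0.0, sigma_omit=1.0, theta=1.0, decay=0.9
    )
    sizes = (1, 1, 1, 1, 1, 1)
    n = 50_000
    rng = np.random.default_rng(1234)
    order, act = _simulate_selection(sizes, params, n, rng, antithetic=False)
    emitted = _emission(act, params, rng)
    assert np.all(order == np.arange(6))  # noiseless selection keeps list order
    observed = emitted.mean(axis=0)
    expected = closed_form_emission_probs(sizes, params)
    se = np.sqrt(expected * (1 - expected) / n)
    assert np.all(np.abs(observed - expected) <= 3 * se + 1e-12)


def test_chunk_index_equivalence_for_item_scores(standard_params):
    """Item accuracy of a singleton depends only on its chunk index and the
    number of chunks, not on the sizes of the other chunks (step multiplier 1,
    one decay cycle per chunk)."""
    rng_a = np.random.default_rng(42)
    rng_b = np.random.default_rng(42)
    _, act_a = _simulate_selection((1, 3, 1, 1), standard_params, 4000, rng_a, False)
    _, act_b = _simulate_selection((1, 2, 1, 1), standard_params, 4000, rng_b, False)
    # identical selection streams -> identical activations at selection
    assert np.array_equal(act_a, act_b)


def test_per_word_decay_variant():
    params = ModelParams(
        peak=6, step=1, sigma_select=0, sigma_omit=1, theta=1, decay=0.9,
        decay_cycles_per_chunk="per_word",
    )
    one = closed_form_emission_probs((3, 1), params.replace(decay_cycles_per_chunk="one"))
    per_word = closed_form_emission_probs((3, 1), params)
    # the triple before the singleton causes three decay cycles, not one
    assert per_word[1] < one[1]
    assert per_word[0] == one[0]


def test_reduced_model_configuration():
    reduced = reduced_model(ModelParams(theta=3, decay=0.8, sigma_select=1.0))
    assert reduced.theta == 0 and reduced.decay == 1 and reduced.sigma_select == 0
    assert REDUCED_FREE_PARAMETERS == ("step", "sigma_omit")
    # flat gradient -> flat strict curve
    flat = reduced.replace(step=1e-9, peak=0.0, sigma_omit=1.0)
    curves = predict_curves(parse_spec("1111"), None, flat, n_iter=20_000, seed=2)
    strict = curves[curves.scheme == "strict"]["mean"]
    assert strict.max() - strict.min() < 0.03
    # and the omission curve of a sloped reduced model is monotone decreasing
    probs = closed_form_emission_probs((1,) * 6, reduced_model(peak=2.0).replace(sigma_omit=1.0))
    assert np.all(np.diff(probs) < 0)


def test_predict_curves_rejects_bad_input(standard_params):
    with pytest.raises(ValueError):
        predict_curves(parse_spec("1113"), None, standard_params, n_iter=0)
    with pytest.raises(ValueError):
        predict_curves(
            parse_spec("1113"), None, standard_params, n_iter=10, schemes=("bogus",)
        )
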