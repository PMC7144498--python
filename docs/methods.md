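# Methods

This note records the modelling choices, numerical conventions and known
limitations of the package, in the order a reader meets them: list designs,
scoring, the recall model, the Monte-Carlo fitting protocol, and the
synthetic-participant generator.

## List designs

A *condition* is an unordered multiset of chunk sizes over {1, 2, 3} (label
"1222" = one singleton + three pairs, seven words). A concrete trial
realises one ordered arrangement; arrangements are enumerated exhaustively
(distinct orderings of the multiset) and sampled uniformly. The single
placement constraint implemented is "no triple begins at position *p*"
(with seven-word lists and *p* = 5 this is "no list ends in a triple"); it
is applied by filtering the enumeration, and an empty result is an error
rather than a silent fallback.

Serial-position curves for mixed lists are *composite*: each word position
averages the arrangements that put a singleton (or a chunk member) there.
Arrangements are weighted equally, not by empirical trial counts; the
pipeline's Monte-Carlo allocator assigns trials to arrangements as evenly as
possible (deterministic split), which only removes weight-sampling noise.

Word identities are opaque integers drawn without replacement per trial. All
scoring schemes are invariant under consistent relabelling (property-tested),
so no published vocabulary is needed anywhere.

## Scoring

**Strict** scoring keeps omissions ("blanks") positionally — paced spoken
recall makes the response positional by design, so a length mismatch is an
error, never silently aligned. **Item** scoring drops blanks and uses
one-to-one multiset matching: a duplicated response token cannot credit two
targets. The stimuli of the emulated designs never contain duplicate words,
so this choice is invisible there, but it pins down behaviour for stress
tests. **LD** (item-level Levenshtein) credit also strips blanks first, so
omissions surface as deletions, and response insertions cost whole-list
edits but never reduce any individual item's credit.

An *alignment* is an order-preserving matching of identical symbols of
maximum size (equivalently, an embedding of a maximum-length common
subsequence). A column pairing two different symbols is a substitution: it
credits neither item and carries no alignment identity. This convention is
what makes the canonical transposition example come out right — for
`1 2 3 4` vs `1 2 4 3` there are exactly two optimal alignments and items 3
and 4 are matched on one each (credit 1/2). If substitution columns were
treated as alignment columns, a third "substitute both" alignment would
appear and the credits would be 1/3, which contradicts the definitional
example; the reported whole-list `distance` is nevertheless the standard
unit-cost Levenshtein distance (the two conventions agree on it here).

Counting is exact: the number of optimal alignments and the per-item match
counts are computed by forward/backward dynamic programming with
inclusion–exclusion (Python integers, credits as `fractions.Fraction`), so
ties and ratios involve no floating point. The explicit enumerator of all
optimal alignments exists only as a test oracle and is capped, because the
number of alignments grows combinatorially.

One caveat documented rather than "fixed": `distance = 0` implies all
credits are 1, but the converse needs equal lengths — a response consisting
of the full target plus insertions has all credits 1 at positive distance.
Similarly, per-item dominance LD ≤ item holds for duplicate-free targets
(the design domain) and can fail when targets repeat a symbol, because the
item matcher credits first occurrences while alignment marginals spread
credit across duplicates.

Chunk cohesion is P(all members recalled | ≥ 1 member recalled) under item
scoring, pooled and broken down by the chunk's starting position; an empty
denominator is reported as missing, not zero.

## Recall model

Parameters (all dimensionless; defaults in parentheses): peak activation
(6), step (1 — the gradient's unit), selection noise SD (0.5), omission
noise SD (1), omission threshold (0), decay factor per cycle (1 = none),
chunk step multiplier (1), decay cycles per chunk ("one").

Conventions that the verbal description leaves open, fixed as follows:

- Omission noise is added to the chunk's current (decayed) activation, not
  to its selection-noise-perturbed value.
- The threshold comparison is strict (`>`); under Gaussian noise the
  difference is measure zero, and it makes the noiseless limit a clean step
  function of the gradient.
- Suppression follows the omission check whether or not the chunk was
  emitted: omitted chunks are never revisited.
- Decay applies after every cycle, omission cycles included; suppressed
  activations are inert (they never re-enter competition, so their values
  are irrelevant). There is no decay during presentation — the model is a
  recall-stage account.
- Selection noise is fresh every cycle; frozen noise would make the
  transposition structure degenerate.
- A multiword chunk emits its words in within-chunk order; within-chunk
  order errors are impossible, and chunk recall is all-or-none (this is the
  modelling assumption, and the observed near-unity cohesion is its
  empirical licence).
- Argmax ties (possible only at zero selection noise with a flat gradient)
  resolve to the earliest chunk, preserving list order in the degenerate
  case.

With zero selection noise the dynamics are deterministic and chunk *j* is
emitted with probability Φ((*aⱼ*·*d*^(j−1) − θ)/σ_omit); the simulator is
cross-checked against this closed form at 50,000 trials in the tests.

The reduced two-parameter configuration fixes θ = 0, *d* = 1, σ_select = 0
and frees the step and the omission noise with the peak held fixed. "Step
free with peak fixed" is one of two defensible readings of the reduced
model's parameterisation; both are expressible through the free-parameter
mask, and the package defaults to this one.

### Monte-Carlo curve estimator

`predict_curves` estimates condition curves from vectorised batches. Two
variance-reduction devices are on by default, chosen as part of the
estimator's design (they change no estimand):

- **Omission marginalisation.** Suppression and decay do not depend on the
  omission outcome, so the omission draw is exogenous to the selection
  dynamics. Each selected chunk therefore contributes its exact conditional
  emission probability Φ((a − θ)/σ_omit) instead of a sampled indicator
  (conditional Monte Carlo).
- **Antithetic selection noise** (paired ε, −ε across half-batches).

The discrete-response simulator used for corpora and traces samples both
noise sources; the `LD` scheme, which needs materialised responses, always
uses sampled omissions. Per-batch noise tensors are drawn trial-major from
a seed tree keyed by (seed, condition index, arrangement index), so
enlarging the trial count extends rather than reshuffles earlier trials.

## Fitting

The objective is the RMS difference between observed and predicted singleton
composite curves, item and strict schemes jointly: 24 points for the
six-word design pair (111111 + 1113), 28 for the seven-word pair (1111111 +
11113). Conditions with two multiword chunks contribute no singleton curve
and stay out of the target. Chunk-member curves can be added via the
`word_class` argument but are off by default, matching the
singleton-curve-led evaluation.

Each evaluation simulates 50,000 trials per condition ("iterations through
the model" is read as trials per condition; under this reading two
independent-seed evaluations at identical parameters differ by well under
0.001 RMS — measured ≈ 0.0005 at the default operating point — which is the
protocol's stated noise floor). A fixed evaluation seed gives common random
numbers across an optimisation, making the stochastic objective locally
smooth.

Minimisation is Nelder–Mead with box bounds, multi-started from seeded Latin
hypercube draws. A simplex method stands in for a gradient-based one
deliberately: finite-difference gradients of a Monte-Carlo objective at a
0.001 noise floor are unreliable, while the CRN objective is
simplex-friendly. Default bounds are generous boxes around the operating
regime (peak [1, 20], step [0.1, 5], noise SDs [0, 5], θ [−5, 10], decay
[0.5, 1]); convergence tolerances (objective 10⁻⁴, scaled simplex 10⁻³) sit
below the evaluation-noise floor, so the multi-start best is the reported
fit.

Parameters are not individually identifiable: peak, threshold and omission
noise trade off along a ridge (a recovery fit may return peak ≈ 18.6 with
θ ≈ 9.2 for curves generated at peak 6, θ 1). The contract is therefore
*curve-space* recovery: fitted parameters must reproduce the generating
curves (RMS ≤ 0.02 at the package's acceptance level), and the recovery
analysis reports curve RMS, not parameter error. The variant sweep
(per-word decay cycles; chunk step multiplier grid) reports whether fits
differ by more than the evaluation-noise floor rather than declaring a
winner.

Problem sizes used by the shipped analyses and acceptance checks: 200,000
trials for generating synthetic targets, 50,000 per evaluation, 4 starts ×
250 evaluations per fit, 5 recovery seeds.

## Synthetic participants

The generator exists because the emulated study's raw data are not
deposited; it produces corpora with the statistical structure each
theoretical account implies, so that every pipeline stage (scoring,
aggregation, fitting, diagnosis) is exercised end to end.

- **Compression process**: the chunk-atomic model simulates recall directly.
  Operating point: peak 6, step 1, σ_select 0.5, σ_omit 1, θ 1, decay 0.95
  — mid-range accuracy with visible position effects.
- **Redintegration process**: the same model runs word-by-word (every word
  its own chunk), then each prelearned chunk with at least one recalled
  member is *repaired* with completion probability ρ. Repair reconstructs
  the chunk's own trace and nothing else: members recalled out of place are
  swapped home, absent members are written at their positions, and a
  displaced non-member word moves to an omission slot instead of vanishing.
  (A destructive overwrite would make singleton recall fall with the number
  of chunks — an artefact, not redintegration.)

The 2AFC generator reuses the recall processes: a word's retained/forgotten
state is its item-scored recall outcome, a retained word is answered
correctly, and a forgotten one is guessed at the guessing rate (0.5).
Probe order is random subject to members of one chunk never being probed
successively; foils are fresh words of the probed word's class. This
retention-plus-guessing construction is a synthetic stand-in: there is no
process model of 2AFC here, only accuracy aggregation.

The calibrated flat-pattern configuration (`exp1_redintegration_config`) was
derived in closed form, not tuned by simulation: with decay 1 and θ 0, item
retention at position *j* is exactly Φ(peak − step·(j−1)), so peak 0.35 and
step 0.15 give mean singleton retention ≈ .46 → 2AFC accuracy ≈ .73, and
ρ = .56 lifts pair members to ≈ .60 retention → accuracy ≈ .80, flat across
list compositions because the base trace never depends on the condition.

### Diagnostic contrast

`diagnostic_contrast` compares singleton means between the conditions with
the most and fewest multiword chunks (percentile bootstrap over trials,
2,000 resamples, 99% interval) and the chunk-member minus singleton
advantage in mixed lists. Verdicts: trend interval above zero →
compression-signature; trend interval spanning zero with a positive
advantage interval → redintegration-signature; otherwise indeterminate.
Two deliberate guards: the 99% level keeps the false "non-flat" rate of a
truly flat process near 1% (at 95% it is ~5%, too high for a classifier),
and corpora with fewer than 20 trials in a contrasted condition are
indeterminate outright, because percentile intervals built from a handful
of trials can exclude zero on the strength of two observations.

The diagnostic corpora use the unconstrained seven-word triple designs
{1111111, 11113, 133}: the "no triple at position 5" placement constraint
would force the 133 singleton to position 7, confounding condition with
serial position and masking the flat-singleton signature.

## What the synthetic data do and do not show

The generator emulates paced spoken recall of 6–7-word lists with
prelearned chunks: omissions, transpositions, all-or-none chunk recall, and
the two accounts' contrasting singleton signatures. It does not emulate
training and familiarisation, articulatory suppression, phonological
similarity, output latencies, within-chunk order errors, or participant
heterogeneity (all "participants" share one parameter set). Passing tests
therefore demonstrate that the pipeline measures what each generating
process puts in — not that either process describes human data.

## Limitations

- Whether human list randomisation was uniform over arrangements or
  stratified per block is unknown; uniform is assumed.
- The LD scheme's behaviour for stimulus sets with repeated words is a
  convention (see Scoring), exercised only by stress tests.
- Fitted parameter values should never be interpreted individually; only
  their curves are constrained (see Fitting).
- The published fitted-RMS values for the human experiments are not
  reproducible from this package alone, because the observed curves exist
  only as figures; fits here target synthetic curves.
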