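# Methods

## Problem and data model

The package classifies subjects from ordered claim histories
`(w_1, τ_1), …, (w_T, τ_T)`: `w_t` is a categorical service item code and
`τ_t ≥ 0` the number of days since the previous claim. Sequences are
**right-aligned** — the anchor is the last claim before the labeling event
(for positive subjects, the therapy change; for negatives, the end of the
observation window) — so shorter sequences are zero-padded at the
beginning and longer ones keep the `T` most recent events. The span of the
first claim in a history has no natural predecessor; it is taken as given
in the input and passed through unmodified, including after truncation.

Codes are kept as strings (they are identifiers, not numbers) and indexed
lexicographically into a dense vocabulary with index 0 reserved for
padding. The encoded batch invariant — mask false ⟺ item index 0 ⟺ span
0, real events occupying a contiguous suffix — is enforced on
construction and exercised by property tests.

## Cohort construction and labeling

From a pharmacy claim table (subject, year, drug class, concession and
gestational flags) the pipeline: (1) keeps subjects with habitual use of
glucose-lowering drugs, operationalized as DM-drug claims in ≥ 2 distinct
years (the threshold is configurable; "habitual" has no canonical
definition); (2) excludes gestational diabetes; (3) keeps stable
concession-card holders — the card used in ≥ 75% of observed years and,
within a year, for ≥ 75% of that year's claims, both bounds inclusive;
(4) labels subjects 1 when an initial metformin-only period is followed by
any other glucose-lowering drug class (whether or not metformin
continues), 0 when metformin-only throughout, and drops subjects never
metformin-only at the start (e.g. insulin starters) as not eligible.
Drug classes are supplied as data (a code → class map), not hard-coded.

## Coarsened exact matching

Classes are balanced before modeling by CEM on age (mean over observation),
gender, state and sequence length. Continuous covariates are binned (age:
5-year bins; length: 10 equal-width bins by default — the appropriate
coarsening is data-dependent and configurable), categorical ones matched
exactly; strata lacking one class are pruned. Within each retained stratum
we subsample the majority class to the minority count with a seeded RNG, so
the matched cohort is exactly 1:1 rather than weighted: the downstream
models are unweighted, and a balanced cohort makes the accuracy-type
metrics directly comparable across models. Weighted-CEM imbalance
statistics (e.g. the L1 measure) are out of scope.

## Embedding initialization

Each code's descriptor text is lower-cased, stripped of punctuation and
stop words (a bundled standard English list, overridable), split into
unigrams, and the word vectors of in-store unigrams are averaged into the
code's embedding row; tokens absent from the store are skipped rather than
zero-filled (skipping keeps the mean a convex combination of real word
vectors; the alternative would shrink rows toward zero). Codes with no
in-store token fall back to a seeded uniform row in [−0.05, 0.05] — a
standard small-init scale — and are listed in the build report. Row 0 is
the padding row, fixed at zero and re-zeroed after every optimizer step.
E = 50 by default, matching the smallest common pre-trained
word-vector dimension; larger dimensions add cost without clear benefit at
these data sizes.

## Model and numerical choices

* λ is parameterized as `sigmoid(λ_raw)` with `λ_raw` initialized at 0
  (λ = 0.5): the mix of item- and span-stream projections must stay convex,
  and the sigmoid guarantees it without constrained optimization.
* The softmax over time uses masked logits (−10³⁰ at padded steps, max
  shifted) applied independently per hidden unit; masked steps get
  α = ω = 0 exactly.
* The LSTMs gate both hidden and cell state with the step mask
  (`h_t = m_t h_new + (1−m_t) h_prev`, state initialized at zero), which
  makes predictions invariant to the amount of left-padding to 1e-15 —
  tested at 1e-5.
* The span stream feeds τ as a raw scalar per step (days); a `log1p`
  transform is available in the config for heavy-tailed span
  distributions.
* Cross-entropy probabilities are clipped to [1e-7, 1 − 1e-7].
* The attentionless baseline pools the concatenated final forward/backward
  hidden states of the item stream into the same two-layer head, so the
  three recurrent models differ only in the attention strategy.
* Training: Adam (lr 1e-3 default), dropout 0.5 on the head's hidden
  layer, early stopping on validation loss with patience 5 and best-weight
  restore. All RNG streams derive from the config seed; training is
  deterministic on a fixed seed. Defaults H = 32, U = 32, head width
  D = E, batch 32, ≤ 100 epochs.
* The models run on `tangle._autograd`, a reverse-mode autodiff core on
  numpy arrays (broadcast arithmetic, batched matmul, activations,
  reductions, gather, masked softmax) with every operation checked
  against central finite differences in the test suite. An `ε = 1e-8`
  Adam denominator and float64 arithmetic throughout keep the oracle
  comparisons tight (1e-5 tolerances).

## Evaluation protocol

Monte Carlo cross-validation: each split independently draws
test = ⌈0.4 N⌉ subjects, then validation = ⌈0.1 · learning⌉ of the
remaining learning set, train = rest (ceiling rounding reproduces the
6341/705/4698 arithmetic at N = 11744). Splits are redraws, not a
partition, and the identical plans are shared across model kinds.
Validation is used for early stopping (recurrent models) or penalty choice
by ROC AUC (ℓ1-LR; the selection criterion is our choice). Metrics: ROC
AUC plus accuracy/sensitivity/specificity at a fixed 0.5 threshold —
operating-point choice is deliberately out of scope.

Attention analysis: per sequence, `ω̄_t = (1/2H) Σ_j ω_t[j]`; timesteps
with `|ω̄_t|` above the 99th linear-interpolation percentile of the pooled
distribution are flagged as high-attention. Pooling is per class by
default (class-specific attention patterns are the object of interest) and
configurable to pooled-overall.

## Synthetic data

The generator emulates the structure of linked administrative claims
without reproducing any real code distribution. Sequence lengths are
uniform on [8, max_len]; background items uniform over the non-signal
vocabulary; spans geometric with mean 14 days capped at 365 (claims are
bursty; the family is configurable). Labels are Bernoulli(base_rate), and
a three-item signal motif is planted near the sequence end with tight
inter-item spans (each gap ≤ window/(k−1), so the motif spans at most
`signal_window_days`) with probability base_rate + effect_size in class 1
and base_rate in class 0. Sequences without the tight motif receive, with
probability `decoy_rate` = 0.4, the same items with gaps each wider than
the window. The decoy is what makes the signal genuinely *joint* in codes
and timing: with effect 0.6 / base 0.2 / decoy 0.4 the best achievable AUC
from item occurrence alone is (1 + 0.88 − 0.52)/2 = 0.68 while the
timing-aware optimum is (1 + 0.8 − 0.2)/2 = 0.80, so the ordering
time-aware > item-only is a structural property of the design, not a
tuning artifact. Descriptors are 3–8 tokens from a themed pool with the
signal items sharing a token stem (emulating synonym service items);
synthetic word vectors are i.i.d. uniform in [−0.5, 0.5], E = 50.

The pharmacy-table simulator assigns each subject an archetype —
metformin-only, planted transition (metformin first, second drug class
from a random later year), or insulin starter — plus concession-card and
gestational flags, at configurable fractions.

What passing tests on these data do **not** show: robustness to real claim
code frequencies (heavy-tailed, thousands of codes), episode-coning
censoring of pathology items, non-stationary claim rates, or label noise
in therapy-transition ascertainment. Results on synthetic data demonstrate
that the implementation can recover a planted time-dependent signal, not
that it attains any particular performance on real registries.

## Problem sizes used in the shipped checks

The benchmark exercised by the test suite and `scripts/acceptance.py`
uses n = 2000 subjects, vocabulary 50, T = 60, 3 Monte Carlo splits, and a
reduced model (E = 32, H = U = 16, dropout 0.3, batch 64, lr 3e-3,
≤ 10 epochs, patience 3) — sizes chosen so the whole pipeline runs in a
few minutes on a single CPU while leaving the planted-signal ordering
clearly resolvable. Larger settings only sharpen the same comparison.

## Known limitations

* The λ mix is a single global scalar; a per-unit or per-step mix is a
  natural extension the architecture does not currently expose.
* Truncation keeps the most recent `T` events; histories longer than `T`
  lose their oldest claims silently (by design, but worth knowing).
* The ℓ1-LR baseline fits without an intercept, matching its objective
  exactly; on strongly imbalanced unmatched data an intercept would help.
* `cem_match` returns an empty set (with a warning) when no stratum
  contains both classes; downstream stages must tolerate empty cohorts.
* GRU/vanilla-RNN encoder variants and alternative attention baselines
  (e.g. two-level attention models) are out of scope.
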