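# tangle-claims

Predicting an upcoming therapy change from administrative claim histories is
a sequence-classification problem with an awkward twist: the data are not
just *which* services a patient claimed, but *when* — each event carries the
number of days elapsed since the previous claim, and those irregular spans
are themselves informative. This package implements **Tangle**, a time
span-guided neural attention classifier for such interleaved
(item code, day span) sequences, together with everything needed to exercise
it end to end: a synthetic claim-stream generator with a plantable
time-dependent class signal, pharmacy-claim cohort construction and
therapy-transition labeling, coarsened exact matching (CEM) for class
balancing, descriptor-based embedding initialization, linear and recurrent
baselines, and a Monte Carlo cross-validation benchmark harness.

It is aimed at researchers working with administrative health data (e.g.
Medicare/pharmacy claim streams) who want an interpretable, time-aware
sequence model and a reproducible evaluation protocol without access to
restricted registries.

## The model

A subject's history is a right-aligned sequence `(w_1, τ_1), …, (w_T, τ_T)`
where `w_t` is a categorical item code and `τ_t` the day span since the
previous claim. The two streams are modeled separately and fused by the
attention mechanism:

```
x_t   = w_t W_e                                  code embedding, W_e ∈ R^{(V+1)×E}
H_x   = BiLSTM(x_1 … x_T)      ∈ R^{T×2H}        item-stream encoding
H_τ   = BiLSTM(τ_1 … τ_T)      ∈ R^{T×2H}        span-stream encoding
u_x,t = tanh(h_x,t W_x + b_x)                     hidden projections, ∈ R^U
u_τ,t = tanh(h_τ,t W_τ + b_τ)
v_t   = λ u_x,t + (1−λ) u_τ,t                     convex mix, λ = σ(λ_raw) learned
α_t   = softmax_t(v_t W_α)     ∈ R^{2H}           per-unit weights, normalized over t
ω_t   = h_x,t ⊙ α_t                               attention contribution
c̄    = (1/2H) Σ_j (Ωᵀ X)_j    ∈ R^E              context vector
ŷ    = σ(ReLU(c̄ W_0 + b_0) W_1 + b_1)            class probability
```

trained by mean binary cross-entropy with Adam and early stopping. Two
points distinguish this from standard attention: the weights `α_t` form a
2H-vector per timestep (each hidden unit is weighted individually, with the
softmax over time applied per unit), and the span stream guides where the
item-stream attention looks via the learned mixing weight λ. At λ = 1 the
model provably collapses to a span-blind bidirectional attention model — a
property the test suite checks numerically. The attentionless `baseline`
and scalar-weight `attention` variants are provided for comparison, plus an
n-gram bag-of-words ℓ1-logistic-regression (`l1lr`) linear baseline.

The recurrent models run on a small reverse-mode autodiff core
(`tangle._autograd`) written on numpy and gradient-checked against finite
differences; no deep-learning framework is required.

## Worked example

```python
import numpy as np
from tangle import SimConfig, simulate_sequences, ModelConfig
from tangle.evaluation import run_benchmark

ds = simulate_sequences(SimConfig(n_subjects=2000, vocab_size=50, max_len=60,
                                  effect_size=0.6, base_rate=0.2, seed=11))
cfg = ModelConfig(E=32, H=16, U=16, dropout=0.3, max_epochs=10, patience=3,
                  batch_size=64, learning_rate=3e-3, seed=0)
table, _ = run_benchmark(ds.sequences, ["tangle", "baseline"],
                         n_splits=3, seed=3, T=60, config=cfg)
print(table[table.metric == "roc_auc"])
```

prints (one run on the seeds above):

```
      model   metric      mean       std
1  baseline  roc_auc  0.672049  0.011244
5    tangle  roc_auc  0.800734  0.006623
```

The generator plants a three-item motif near the end of class-1 sequences
with tight (≤ 14-day) inter-item spans; the same items also appear with wide
spans as a decoy in either class. An item-only model can therefore detect
the motif but not its timing — that is the gap between 0.67 (attentionless
baseline) and 0.80 (time span-guided attention) above.

The same pipeline is scriptable from the shell:

```
tangle simulate --config sim.yaml --out data/
tangle build-cohort --claims data/pbs_claims.csv --out labeled.csv
tangle match --covariates cov.csv --seed 0 --out matched.csv
tangle embed-init --sequences data/sequences.jsonl --descriptors data/descriptors.csv \
                  --vectors data/word_vectors.txt --out emb.txt
tangle train --sequences data/sequences.jsonl --model tangle --out model/
tangle evaluate --sequences data/sequences.jsonl --out eval/
tangle attention-report --sequences data/sequences.jsonl --model model/tangle.npz --out attn.tsv
```

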