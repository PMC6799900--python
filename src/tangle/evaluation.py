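"""Monte Carlo cross-validation, metrics and attention-contribution analysis.

The evaluation protocol draws ``n_splits`` independent random resplits of
the matched cohort (Monte Carlo cross-validation, not a partition): 40% of
subjects (ceiling) are held out as test, the remaining learning set is
split 90/10 into training and validation (validation again by ceiling).
Every model kind is trained on the identical split plans and summarized by
the mean and standard deviation over splits of ROC AUC, accuracy,
sensitivity and specificity.

The attention-contribution analysis averages a fitted tangle model's
per-unit contributions, omega_bar_t = (1/2H) sum_j omega_t[j], and flags
high-attention timesteps whose |omega_bar_t| exceeds the 99th percentile
of the pooled |omega_bar| distribution (per class by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .claims_io import ClaimSequence, build_vocabulary, encode_batch
from .linear_baseline import fit_l1_lr, nbow_features
from .models import AttentionTrace, ModelConfig, train

__all__ = [
    "SplitPlan",
    "monte_carlo_splits",
    "classification_metrics",
    "attention_contribution",
    "run_benchmark",
]

TEST_FRAC = 0.4
VALIDATION_FRAC = 0.1


@dataclass
class SplitPlan:
    split_id: int
    train_ids: list
    validation_ids: list
    test_ids: list

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.validation_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split sets must be pairwise disjoint")


def monte_carlo_splits(ids: Sequence, n_splits: int, seed: int = 0) -> list[SplitPlan]:
    """Draw independent learning/test resplits with ceiling-sized holdouts.

    test = ceil(0.4 N); validation = ceil(0.1 * learning); train = rest.
    The same seed yields the same plans, shared across models.
    """
    ids = list(ids)
    N = len(ids)
    if N < 10:
        raise ValueError(f"need at least 10 subjects, got {N}")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    n_test = math.ceil(TEST_FRAC * N)
    n_learn = N - n_test
    n_val = math.ceil(VALIDATION_FRAC * n_learn)
    plans = []
    for s in range(n_splits):
        perm = rng.permutation(N)
        test = [ids[i] for i in perm[:n_test]]
        val = [ids[i] for i in perm[n_test:n_test + n_val]]
        tr = [ids[i] for i in perm[n_test + n_val:]]
        plans.append(SplitPlan(s, tr, val, test))
    return plans


def classification_metrics(y, scores, threshold: float = 0.5) -> dict[str, float]:
    """ROC AUC plus thresholded accuracy, sensitivity and specificity."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC undefined: y contains a single class")
    pred = (scores >= threshold).astype(int)
    pos, neg = y == 1, y == 0
    return {
        "roc_auc": float(roc_auc_score(y, scores)),
        "accuracy": float((pred == y).mean()),
        "sensitivity": float((pred[pos] == 1).mean()),
        "specificity": float((pred[neg] == 0).mean()),
    }


def attention_contribution(traces: Sequence[AttentionTrace], percentile: float = 99.0,
                           per_class: bool = True) -> dict:
    """Average attention contributions and the high-attention flag rule.

    Returns a dict with a long-format report DataFrame (sequence_id, t,
    omega_bar, flagged, label) over unmasked timesteps and the percentile
    threshold(s) used.
    """
    if not traces:
        raise ValueError("no attention traces given")
    rows = []
    for tr in traces:
        omega_bar = tr.omega.mean(axis=1)  # (T,)
        for t in np.flatnonzero(tr.mask):
            rows.append({"sequence_id": tr.subject_id, "t": int(t),
                         "omega_bar": float(omega_bar[t]),
                         "label": tr.label})
    report = pd.DataFrame(rows)
    have_labels = report["label"].notna().all() and report["label"].nunique() > 1
    thresholds: dict = {}
    if per_class and have_labels:
        report["flagged"] = False
        for lab, grp in report.groupby("label"):
            thr = float(np.percentile(np.abs(grp["omega_bar"]), percentile))
            thresholds[int(lab)] = thr
            report.loc[grp.index, "flagged"] = np.abs(grp["omega_bar"]) > thr
    else:
        thr = float(np.percentile(np.abs(report["omega_bar"]), percentile))
        thresholds["pooled"] = thr
        report["flagged"] = np.abs(report["omega_bar"]) > thr
    return {"report": report, "thresholds": thresholds}


def _eval_recurrent(kind, sequences, plan, vocab, T, config, W_e):
    by_id = {s.subject_id: s for s in sequences}
    enc = lambda ids: encode_batch([by_id[i] for i in ids], vocab, T)
    model, history = train(kind, enc(plan.train_ids), enc(plan.validation_ids),
                           config, vocab_size=vocab.size, W_e=W_e)
    test = enc(plan.test_ids)
    return model, classification_metrics(test.labels, model.predict_proba(test)), history


def _eval_l1lr(sequences, plan, n, gamma_grid, seed):
    by_id = {s.subject_id: s for s in sequences}
    tr = [by_id[i] for i in plan.train_ids]
    feats = nbow_features(tr, n=n)
    names = feats.feature_names
    Xv = nbow_features([by_id[i] for i in plan.validation_ids], n, names).counts
    Xt = nbow_features([by_id[i] for i in plan.test_ids], n, names).counts
    y = lambda ids: np.asarray([by_id[i].label for i in ids])
    fit = fit_l1_lr(feats.counts, y(plan.train_ids), Xv, y(plan.validation_ids),
                    gamma_grid, seed=seed)
    scores = fit["estimator"].decision_function(Xt)
    return fit, classification_metrics(y(plan.test_ids), scores)


def run_benchmark(sequences: Sequence[ClaimSequence], model_kinds: Sequence[str],
                  n_splits: int = 10, seed: int = 0, T: Optional[int] = None,
                  config: Optional[ModelConfig] = None,
                  W_e: Optional[np.ndarray] = None, bow_n: int = 1,
                  gamma_grid=None):
    """Benchmark model kinds on shared Monte Carlo splits.

    ``model_kinds`` may contain "baseline", "attention", "tangle" and
    "l1lr" (n-BOW logistic regression). Returns ``(table, raw)`` where
    table has one row per model and metric (mean and std over splits) and
    raw holds every per-split metric value.
    """
    sequences = list(sequences)
    if any(s.label is None for s in sequences):
        raise ValueError("benchmark needs labeled sequences")
    vocab = build_vocabulary(sequences)
    if T is None:
        T = max(len(s) for s in sequences)
    config = config or ModelConfig()
    plans = monte_carlo_splits([s.subject_id for s in sequences], n_splits, seed)
    raw = []
    for kind in model_kinds:
        for plan in plans:
            cfg = ModelConfig(**{**config.__dict__, "seed": config.seed + plan.split_id})
            if kind == "l1lr":
                _, metrics = _eval_l1lr(sequences, plan, bow_n, gamma_grid, seed)
            else:
                _, metrics, _ = _eval_recurrent(kind, sequences, plan, vocab, T, cfg, W_e)
            for m, v in metrics.items():
                raw.append({"model": kind, "split": plan.split_id, "metric": m, "value": v})
    raw = pd.DataFrame(raw)
    table = (raw.groupby(["model", "metric"])["value"]
             .agg(mean="mean", std="std").reset_index())
    table["std"] = table["std"].fillna(0.0)
    return table, raw
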