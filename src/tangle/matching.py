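"""Coarsened exact matching (CEM) to balance classes before modeling.

Covariates are coarsened (continuous ones binned, categorical ones kept
exact), subjects are grouped into strata by their coarsened signature, and
strata containing only one class are pruned. Within each retained stratum
the majority class is randomly subsampled to the minority count so the
matched cohort is balanced 1:1, up to strata with odd counts. Matching is
run on age (mean over the observation window), gender, state of residence
and sequence length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["MatchCovariates", "CoarseningSpec", "cem_match", "balance_report"]

COVARIATE_COLUMNS = ["age_years", "gender", "state", "seq_length"]


@dataclass(frozen=True)
class MatchCovariates:
    subject_id: str
    age_years: float
    gender: str
    state: str
    seq_length: int
    label: int

    def __post_init__(self):
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class CoarseningSpec:
    """Per-covariate coarsening rule.

    A rule is ``"exact"`` (categorical), ``{"width": w}`` (fixed-width bins
    anchored at the observed minimum), ``{"bins": n}`` (n equal-width bins
    over the observed range) or ``{"edges": [...]}`` (explicit edges).
    """

    rules: dict[str, Union[str, dict]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CoarseningSpec":
        return cls({
            "age_years": {"width": 5.0},
            "gender": "exact",
            "state": "exact",
            "seq_length": {"bins": 10},
        })


def _coarsen_column(values: pd.Series, rule) -> pd.Series:
    if rule == "exact":
        return values.astype(str)
    v = values.astype(float)
    if "edges" in rule:
        edges = np.asarray(rule["edges"], dtype=float)
    elif "width" in rule:
        w = float(rule["width"])
        lo = np.floor(v.min() / w) * w
        edges = np.arange(lo, v.max() + w, w)
    elif "bins" in rule:
        n = int(rule["bins"])
        lo, hi = v.min(), v.max()
        if hi == lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n + 1)
    else:
        raise ValueError(f"unrecognized coarsening rule {rule!r}")
    if edges[0] > v.min() or edges[-1] < v.max():
        raise ValueError("bin edges must cover the observed range")
    idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(edges) - 2)
    return pd.Series(idx, index=values.index)


def _signatures(df: pd.DataFrame, spec: CoarseningSpec) -> pd.Series:
    rules = {**CoarseningSpec.default().rules, **spec.rules}
    cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    coarse = pd.DataFrame({c: _coarsen_column(df[c], rules[c]) for c in cols})
    return coarse.apply(tuple, axis=1)


def cem_match(covariates, spec: Optional[CoarseningSpec] = None, seed: int = 0) -> set[str]:
    """Return the subject ids retained by coarsened exact matching.

    ``covariates`` is a DataFrame with columns ``subject_id, age_years,
    gender, state, seq_length, label`` or a list of :class:`MatchCovariates`.
    Strata lacking one of the two classes are pruned; within each kept
    stratum the majority class is subsampled (seeded) to the minority count.
    """
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame([c.__dict__ for c in covariates])
    if covariates.empty or covariates["label"].nunique() < 2:
        warnings.warn("cem_match: need both classes present; returning empty set")
        return set()
    spec = spec or CoarseningSpec.default()
    df = covariates.reset_index(drop=True)
    df["_stratum"] = _signatures(df, spec)
    rng = np.random.default_rng(seed)
    retained: list[str] = []
    for _, stratum in df.groupby("_stratum", sort=True):
        by_class = {y: stratum.loc[stratum["label"] == y, "subject_id"].tolist()
                    for y in (0, 1)}
        if not by_class[0] or not by_class[1]:
            continue
        k = min(len(by_class[0]), len(by_class[1]))
        for y in (0, 1):
            ids = by_class[y]
            if len(ids) > k:
                ids = list(rng.choice(ids, size=k, replace=False))
            retained.extend(ids)
    if not retained:
        warnings.warn("cem_match: no stratum contains both classes; empty match")
    return set(retained)


def balance_report(covariates: pd.DataFrame, retained: set[str]) -> pd.DataFrame:
    """Class-conditional covariate means before and after matching."""
    num_cols = [c for c in ("age_years", "seq_length") if c in covariates.columns]
    rows = []
    post = covariates[covariates["subject_id"].isin(retained)]
    for col in num_cols:
        pre_gap = abs(covariates.groupby("label")[col].mean().diff().iloc[-1])
        post_gap = (abs(post.groupby("label")[col].mean().diff().iloc[-1])
                    if post["label"].nunique() == 2 else np.nan)
        rows.append({"covariate": col, "pre_gap": pre_gap, "post_gap": post_gap})
    return pd.DataFrame(rows)
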