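"""Synthetic claim-stream generator with a plantable, time-dependent signal.

Real linked administrative claim data (service items plus pharmacy
dispensings) are access-restricted, so every downstream module is exercised
on simulated data generated here:

* labeled service-claim sequences in which class membership depends
  *jointly* on which item codes occur and on the day spans between them —
  class-1 subjects tend to carry a short motif of signal items with tight
  inter-item spans near the end of their sequence, while a configurable
  fraction of the remaining sequences carries a "decoy": the same item
  codes but with spans far wider than the signal window. A model that
  ignores timing therefore sees a weaker signal than one that uses it;
* pharmacy-like claim tables (subject, year, drug class, concession and
  gestational flags) with a controllable fraction of subjects who start on
  metformin only and later add a second glucose-lowering drug class;
* short textual descriptors per item code drawn from a themed token pool
  (signal items share tokens, emulating synonym service items);
* a synthetic word-vector store over that token pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .claims_io import ClaimEvent, ClaimSequence

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_sequences",
    "simulate_pbs_records",
    "motif_within_window",
]

# Themed pools for synthetic item descriptors.
_SHARED_SIGNAL_TOKENS = ["quantitation", "glycated", "haemoglobin"]
_TOKEN_POOL = [
    "attendance", "practitioner", "general", "consultation", "specialist",
    "referral", "pathology", "collection", "specimen", "blood", "serum",
    "glucose", "monitoring", "management", "chronic", "disease", "review",
    "plan", "assessment", "examination", "diagnostic", "imaging", "service",
    "procedure", "surgery", "anaesthesia", "injection", "vaccination",
    "screening", "test", "quantification", "microbiology", "haematology",
    "biochemistry", "lipids", "renal", "hepatic", "thyroid", "cardiac",
    "podiatry", "optometry", "physiotherapy", "dental", "nursing", "home",
    "telehealth", "after", "hours", "incentive", "bulk", "billed",
]


@dataclass
class SimConfig:
    """Generative conditions for the synthetic cohort.

    ``base_rate`` is both the class-1 prevalence and the background rate at
    which class-0 sequences carry the tight-span motif; the motif rate in
    class 1 is ``base_rate + effect_size``.
    """

    n_subjects: int = 2000
    vocab_size: int = 50
    max_len: int = 60
    signal_items: Optional[list[str]] = None  # default: first 3 codes
    signal_window_days: int = 14
    effect_size: float = 0.6
    base_rate: float = 0.2
    span_distribution: dict = field(
        default_factory=lambda: {"name": "geometric", "mean": 14, "cap": 365}
    )
    decoy_rate: float = 0.4
    min_len: int = 8
    embedding_dim: int = 50
    seed: int = 0
    # pharmacy-table knobs
    transition_frac: float = 0.3
    insulin_start_frac: float = 0.05
    nonconcessional_frac: float = 0.1
    gestational_frac: float = 0.02
    start_year: int = 2008
    end_year: int = 2014

    def __post_init__(self):
        if self.n_subjects < 1 or self.vocab_size < 1 or self.max_len < 1:
            raise ValueError("n_subjects, vocab_size and max_len must be positive")
        if not (0.0 <= self.base_rate <= 1.0 and 0.0 <= self.effect_size <= 1.0):
            raise ValueError("base_rate and effect_size must lie in [0, 1]")
        if self.base_rate + self.effect_size > 1.0:
            raise ValueError("base_rate + effect_size must not exceed 1")
        if self.signal_items is None:
            self.signal_items = [self._code(i) for i in range(min(3, self.vocab_size))]
        if self.vocab_size < len(self.signal_items):
            raise ValueError("vocab_size must be >= number of signal items")
        if not (self.transition_frac + self.insulin_start_frac <= 1.0):
            raise ValueError("transition_frac + insulin_start_frac must be <= 1")
        self.min_len = max(self.min_len, len(self.signal_items) + 2)
        if self.min_len > self.max_len:
            self.min_len = self.max_len

    @staticmethod
    def _code(i: int) -> str:
        return str(10000 + i)

    def codes(self) -> list[str]:
        return [self._code(i) for i in range(self.vocab_size)]


@dataclass
class SyntheticDataset:
    sequences: list[ClaimSequence]
    descriptors: dict[str, str]
    word_vectors: dict[str, np.ndarray]
    truth: pd.DataFrame  # subject_id, label, tight_motif, decoy, motif_start

    def labels(self) -> np.ndarray:
        return np.asarray([s.label for s in self.sequences], dtype=np.int64)


def _draw_span(rng: np.random.Generator, dist: dict, size=None):
    name = dist.get("name", "geometric")
    if name == "geometric":
        mean = float(dist.get("mean", 14))
        cap = int(dist.get("cap", 365))
        # support {0, 1, 2, ...} with the requested mean
        s = rng.geometric(1.0 / (mean + 1.0), size=size) - 1
        return np.minimum(s, cap)
    if name == "poisson":
        return rng.poisson(float(dist.get("mean", 14)), size=size)
    if name == "constant":
        v = int(dist.get("value", 7))
        return np.full(size, v) if size else v
    raise ValueError(f"unknown span distribution {name!r}")


def motif_within_window(seq: ClaimSequence, signal_items: list[str], window: int) -> bool:
    """True if the signal items occur consecutively with total gap <= window."""
    items = seq.items()
    spans = seq.spans()
    k = len(signal_items)
    for p in range(len(items) - k + 1):
        if items[p:p + k] == list(signal_items):
            if sum(spans[p + 1:p + k]) <= window:
                return True
    return False


def simulate_sequences(config: SimConfig) -> SyntheticDataset:
    """Generate labeled right-alignable sequences with the planted signal."""
    rng = np.random.default_rng(config.seed)
    codes = config.codes()
    signal = list(config.signal_items)
    k = len(signal)
    background = [c for c in codes if c not in signal] or codes

    sequences: list[ClaimSequence] = []
    rows = []
    for i in range(config.n_subjects):
        sid = f"subj{i:05d}"
        y = int(rng.random() < config.base_rate)
        L = int(rng.integers(config.min_len, config.max_len + 1))
        items = list(rng.choice(background, size=L))
        spans = [int(v) for v in _draw_span(rng, config.span_distribution, size=L)]

        p_tight = config.base_rate + config.effect_size * y
        tight = bool(rng.random() < p_tight)
        decoy = (not tight) and bool(rng.random() < config.decoy_rate)
        start = None
        if tight or decoy:
            # motif ends within the last few events of the sequence
            offset = int(rng.integers(0, min(4, L - k)))
            start = L - k - offset
            for j in range(k):
                items[start + j] = signal[j]
            if k > 1:
                per_gap = max(config.signal_window_days // (k - 1), 0)
                for j in range(1, k):
                    if tight:
                        spans[start + j] = int(rng.integers(0, per_gap + 1))
                    else:
                        spans[start + j] = int(
                            rng.integers(config.signal_window_days + 1,
                                         3 * config.signal_window_days + 2)
                        )
        seq = ClaimSequence(sid, [ClaimEvent(c, s) for c, s in zip(items, spans)], y)
        sequences.append(seq)
        rows.append({"subject_id": sid, "label": y, "tight_motif": tight,
                     "decoy": decoy, "motif_start": start})

    descriptors = _make_descriptors(codes, signal, rng)
    word_vectors = _make_word_vectors(config.embedding_dim, rng)
    return SyntheticDataset(sequences, descriptors, word_vectors, pd.DataFrame(rows))


def _make_descriptors(codes, signal, rng: np.random.Generator) -> dict[str, str]:
    out = {}
    for c in codes:
        n_extra = int(rng.integers(3, 9))
        toks = list(rng.choice(_TOKEN_POOL, size=n_extra, replace=False))
        if c in signal:
            # signal items share a token stem, like synonym service items
            toks = _SHARED_SIGNAL_TOKENS + toks[: max(n_extra - 3, 1)]
        out[c] = " ".join(toks)
    return out


def _make_word_vectors(dim: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    tokens = sorted(set(_TOKEN_POOL) | set(_SHARED_SIGNAL_TOKENS))
    return {t: rng.uniform(-0.5, 0.5, size=dim) for t in tokens}


# ---------------------------------------------------------------------------
# Pharmacy-like claim tables for the cohort-construction rules
# ---------------------------------------------------------------------------

_PBS_ITEMS = {"metformin": "pbs_met", "other_dm_drug": "pbs_other", "non_dm": "pbs_misc"}


def simulate_pbs_records(config: SimConfig) -> pd.DataFrame:
    """Simulate per-year pharmacy claims for cohort filtering and labeling.

    Each subject is one of three archetypes: metformin-only throughout,
    metformin-first with a later second drug class (a planted therapy
    transition), or a subject who starts on insulin/another drug (never
    metformin-only, hence not eligible for labeling).
    """
    rng = np.random.default_rng(config.seed + 1)
    years = list(range(config.start_year, config.end_year + 1))
    rows = []
    p_roles = [config.transition_frac, config.insulin_start_frac,
               1.0 - config.transition_frac - config.insulin_start_frac]
    for i in range(config.n_subjects):
        sid = f"subj{i:05d}"
        role = rng.choice(["transition", "insulin_start", "metformin_only"], p=p_roles)
        nonconc = rng.random() < config.nonconcessional_frac
        gestational = rng.random() < config.gestational_frac
        trans_year = int(rng.choice(years[1:])) if role == "transition" else None
        # years in which the concession card is not used
        n_off = len(years) // 2 if nonconc else 0
        off_years = set(rng.choice(years, size=n_off, replace=False)) if n_off else set()
        for yr in years:
            n_claims = 1 + int(rng.poisson(4))
            for _ in range(n_claims):
                if role == "insulin_start":
                    cls = "other_dm_drug" if rng.random() < 0.7 else "non_dm"
                elif role == "transition" and yr >= trans_year:
                    r = rng.random()
                    cls = "other_dm_drug" if r < 0.5 else ("metformin" if r < 0.8 else "non_dm")
                else:
                    cls = "metformin" if rng.random() < 0.6 else "non_dm"
                rows.append({
                    "subject_id": sid,
                    "year": yr,
                    "item_code": _PBS_ITEMS[cls],
                    "drug_class": cls,
                    "concessional": yr not in off_years,
                    "gestational_flag": gestational,
                })
    return pd.DataFrame(rows)
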