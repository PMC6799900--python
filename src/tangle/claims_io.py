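"""Claim-sequence data model, parsing, vocabulary and padded encoding.

A subject's service history is an ordered list of ``(item_code, span_days)``
pairs: the item is a categorical service code (e.g. an MBS item number kept
as a string) and the span is the number of days elapsed since the previous
claim. Sequences are *right-aligned* when encoded: the most recent claim
always occupies the last column, shorter sequences are zero-padded at the
beginning, and longer ones keep only the ``T`` most recent events.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ClaimEvent",
    "ClaimSequence",
    "Vocabulary",
    "EncodedBatch",
    "ParseError",
    "parse_interleaved",
    "build_vocabulary",
    "encode_batch",
    "decode_row",
    "read_jsonl",
    "write_jsonl",
    "read_csv",
    "write_csv",
]

PAD_INDEX = 0


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class ClaimEvent:
    item_code: str
    span_days: int

    def __post_init__(self):
        if self.span_days < 0:
            raise ValueError(f"span_days must be >= 0, got {self.span_days}")


@dataclass
class ClaimSequence:
    subject_id: str
    events: list[ClaimEvent]
    label: Optional[int] = None

    def __len__(self):
        return len(self.events)

    def items(self) -> list[str]:
        return [e.item_code for e in self.events]

    def spans(self) -> list[int]:
        return [e.span_days for e in self.events]


@dataclass
class Vocabulary:
    """Dense code -> index map; index 0 is reserved for padding."""

    index: dict[str, int]

    @property
    def size(self) -> int:
        """Number of real codes V (padding excluded)."""
        return len(self.index)

    def __contains__(self, code):
        return code in self.index

    def __getitem__(self, code):
        return self.index[code]

    def codes(self) -> list[str]:
        return sorted(self.index, key=self.index.get)


@dataclass
class EncodedBatch:
    item_indices: np.ndarray  # (N, T) int
    spans: np.ndarray  # (N, T) float
    mask: np.ndarray  # (N, T) bool, True = real event
    labels: Optional[np.ndarray]  # (N,) in {0,1} or None
    T: int
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        bad = (self.item_indices == PAD_INDEX) != ~self.mask
        if bad.any():
            raise ValueError("mask and pad-index inconsistency")

    def __len__(self):
        return self.item_indices.shape[0]

    def subset(self, rows) -> "EncodedBatch":
        rows = np.asarray(rows)
        return EncodedBatch(
            self.item_indices[rows],
            self.spans[rows],
            self.mask[rows],
            None if self.labels is None else self.labels[rows],
            self.T,
            [self.subject_ids[i] for i in rows] if self.subject_ids else [],
        )


def parse_interleaved(tokens: Sequence[str] | str, subject_id: str = "s0",
                      label: Optional[int] = None) -> ClaimSequence:
    """Parse an interleaved ``item span item span ...`` token stream.

    Accepts either a whitespace-separated string or a token list. The
    first token of each pair is the item code, the second the integer
    day span since the previous claim.
    """
    if isinstance(tokens, str):
        tokens = tokens.split()
    tokens = list(tokens)
    if not tokens:
        raise ParseError("empty token stream")
    if len(tokens) % 2 != 0:
        raise ParseError(
            f"odd number of tokens ({len(tokens)}): expected alternating item/span pairs"
        )
    events = []
    for k in range(0, len(tokens), 2):
        item, span_tok = str(tokens[k]), tokens[k + 1]
        try:
            span = int(span_tok)
        except (TypeError, ValueError):
            raise ParseError(f"token {k + 1}: span {span_tok!r} is not an integer") from None
        if span < 0:
            raise ParseError(f"token {k + 1}: span {span} is negative")
        events.append(ClaimEvent(item, span))
    return ClaimSequence(subject_id, events, label)


def build_vocabulary(sequences: Iterable[ClaimSequence]) -> Vocabulary:
    """Map every distinct code to a dense index 1..V, lexicographically."""
    codes = set()
    n = 0
    for seq in sequences:
        n += 1
        codes.update(e.item_code for e in seq.events)
    if n == 0 or not codes:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary({c: i for i, c in enumerate(sorted(codes), start=1)})


def encode_batch(sequences: Sequence[ClaimSequence], vocab: Vocabulary, T: int,
                 oov: str = "error") -> EncodedBatch:
    """Right-align, pad/truncate to length T and integer-encode a batch.

    Truncation keeps the T most recent events (the sequence anchor is the
    last claim). ``oov`` is "error" (raise on unknown codes) or "drop"
    (silently remove those events).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    N = len(sequences)
    items = np.zeros((N, T), dtype=np.int64)
    spans = np.zeros((N, T), dtype=np.float64)
    mask = np.zeros((N, T), dtype=bool)
    labels = [] if all(s.label is not None for s in sequences) else None
    for i, seq in enumerate(sequences):
        evs = seq.events
        if oov == "drop":
            evs = [e for e in evs if e.item_code in vocab]
        else:
            for e in evs:
                if e.item_code not in vocab:
                    raise KeyError(f"unknown item code {e.item_code!r} in {seq.subject_id}")
        if not evs:
            raise ValueError(f"sequence {seq.subject_id} has no encodable events")
        evs = evs[-T:]
        start = T - len(evs)
        for j, e in enumerate(evs):
            items[i, start + j] = vocab[e.item_code]
            spans[i, start + j] = e.span_days
            mask[i, start + j] = True
        if labels is not None:
            labels.append(int(seq.label))
    return EncodedBatch(
        items,
        spans,
        mask,
        None if labels is None else np.asarray(labels, dtype=np.int64),
        T,
        [s.subject_id for s in sequences],
    )


def decode_row(batch: EncodedBatch, row: int, vocab: Vocabulary) -> list[tuple[str, int]]:
    """Invert encoding for one row: drop padding, map indices back to codes."""
    rev = {i: c for c, i in vocab.index.items()}
    out = []
    for t in range(batch.T):
        if batch.mask[row, t]:
            out.append((rev[int(batch.item_indices[row, t])], int(batch.spans[row, t])))
    return out


# ---------------------------------------------------------------------------
# File formats: JSONL (one subject per line) and a flat CSV dialect.
# ---------------------------------------------------------------------------

def write_jsonl(sequences: Iterable[ClaimSequence], path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            rec = {
                "subject_id": s.subject_id,
                "label": s.label,
                "events": [{"item": e.item_code, "span_days": e.span_days} for e in s.events],
            }
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> list[ClaimSequence]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ParseError(f"{path}:{ln}: invalid JSON ({e})") from None
            events = [ClaimEvent(str(e["item"]), int(e["span_days"])) for e in rec["events"]]
            label = rec.get("label")
            out.append(ClaimSequence(str(rec["subject_id"]),
                                     events,
                                     None if label is None else int(label)))
    return out


def write_csv(sequences: Iterable[ClaimSequence], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "item", "span_days", "label"])
        for s in sequences:
            lab = "" if s.label is None else s.label
            for e in s.events:
                w.writerow([s.subject_id, e.item_code, e.span_days, lab])


def read_csv(path) -> list[ClaimSequence]:
    """Read the flat CSV dialect; row order within a subject defines event order."""
    by_subject: dict[str, ClaimSequence] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = str(row["subject_id"])
            if sid not in by_subject:
                lab = row.get("label", "")
                by_subject[sid] = ClaimSequence(sid, [], int(lab) if lab not in ("", None) else None)
                order.append(sid)
            by_subject[sid].events.append(ClaimEvent(str(row["item"]), int(row["span_days"])))
    return [by_subject[s] for s in order]
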