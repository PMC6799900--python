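import numpy as np
import pytest

from tangle.claims_io import ClaimEvent, ClaimSequence, build_vocabulary, encode_batch
from tangle.synthetic_data import SimConfig, simulate_sequences


@pytest.fixture(scope="session")
def small_dataset():
    """300 synthetic subjects with the default planted signal."""
    return simulate_sequences(SimConfig(n_subjects=300, vocab_size=20, max_len=30, seed=42))


@pytest.fixture(scope="session")
def tiny_encoded(small_dataset):
    seqs = small_dataset.sequences[:16]
    vocab = build_vocabulary(seqs)
    return encode_batch(seqs, vocab, 30), vocab


def make_sequence(items, spans, sid="s", label=None):
    return ClaimSequence(sid, [ClaimEvent(str(i), s) for i, s in zip(items, spans)], label)
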