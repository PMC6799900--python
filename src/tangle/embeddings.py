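"""Code-embedding initialization from item-descriptor word vectors.

Service item codes are opaque identifiers, yet distinct codes can denote
near-synonymous services. To give the model a head start on such synonymy,
each code's short text descriptor is cleaned (lower-cased, punctuation and
stop words removed), split into unigrams, and the pre-trained word vectors
of those unigrams are averaged into the code's embedding row. Codes whose
descriptor has no token in the vector store fall back to a small seeded
uniform random row; a build report lists them. Row 0 of the matrix is the
padding row and is identically zero.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from ._stopwords import STOPWORDS
from .claims_io import Vocabulary

__all__ = [
    "WordVectorStore",
    "EmbeddingMatrix",
    "clean_tokens",
    "item_vector",
    "build_embedding_matrix",
    "load_word_vectors",
    "save_word_vectors",
]

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})
RANDOM_SCALE = 0.05  # uniform fallback range [-0.05, 0.05]


@dataclass
class WordVectorStore:
    vectors: dict[str, np.ndarray]
    dim: int

    def __post_init__(self):
        for tok, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has length {v.shape}, expected {self.dim}")
            self.vectors[tok] = v

    def __contains__(self, token):
        return token in self.vectors

    def __getitem__(self, token):
        return self.vectors[token]


@dataclass
class EmbeddingMatrix:
    weights: np.ndarray  # (V+1, E); row 0 = padding
    mode: str
    fallback_items: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.isfinite(self.weights).all():
            raise ValueError("embedding matrix contains non-finite entries")
        if np.any(self.weights[0] != 0.0):
            raise ValueError("padding row (row 0) must be zero")

    @property
    def dim(self):
        return self.weights.shape[1]


def clean_tokens(text: str, stopwords=STOPWORDS) -> list[str]:
    """Lowercase, strip punctuation, drop stop words, split into unigrams."""
    toks = text.lower().translate(_PUNCT_TABLE).split()
    return [t for t in toks if t not in stopwords]


def item_vector(tokens: list[str], store: WordVectorStore):
    """Mean of the store vectors of the in-store tokens; None when none match."""
    hits = [store[t] for t in tokens if t in store]
    if not hits:
        return None
    return np.mean(hits, axis=0)


def build_embedding_matrix(vocab: Vocabulary, descriptors=None,
                           store: WordVectorStore | None = None,
                           mode: str = "glove_init", seed: int = 0,
                           dim: int | None = None,
                           stopwords=STOPWORDS) -> EmbeddingMatrix:
    """Build the (V+1, E) embedding matrix.

    ``mode="glove_init"`` averages descriptor word vectors per code with a
    seeded uniform random fallback for codes whose descriptor is entirely
    out of store; ``mode="random"`` draws every non-padding row uniformly
    in [-0.05, 0.05].
    """
    if mode not in ("glove_init", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "glove_init":
        if store is None or descriptors is None:
            raise ValueError("glove_init mode requires a word-vector store and descriptors")
        if dim is not None and dim != store.dim:
            raise ValueError(f"configured dim {dim} != store dim {store.dim}")
        dim = store.dim
    elif dim is None:
        raise ValueError("random mode requires an explicit dim")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-RANDOM_SCALE, RANDOM_SCALE, size=(vocab.size + 1, dim))
    W[0] = 0.0
    fallback = []
    if mode == "glove_init":
        for code, idx in vocab.index.items():
            vec = item_vector(clean_tokens(descriptors.get(code, ""), stopwords), store)
            if vec is None:
                fallback.append(code)
            else:
                W[idx] = vec
    return EmbeddingMatrix(W, mode, sorted(fallback))


# ---------------------------------------------------------------------------
# GloVe-style text format: one line per token, token then E decimals.
# ---------------------------------------------------------------------------

def load_word_vectors(path) -> WordVectorStore:
    vectors: dict[str, np.ndarray] = {}
    dim = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            tok, vals = parts[0], parts[1:]
            if dim is None:
                dim = len(vals)
            elif len(vals) != dim:
                raise ValueError(f"{path}:{ln}: expected {dim} values, got {len(vals)}")
            vectors[tok] = np.asarray(vals, dtype=float)
    if dim is None:
        raise ValueError(f"{path}: empty word-vector file")
    return WordVectorStore(vectors, dim)


def save_word_vectors(vectors: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for tok in sorted(vectors):
            vals = " ".join(f"{v:.6f}" for v in np.asarray(vectors[tok]))
            fh.write(f"{tok} {vals}\n")
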