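"""Token and character encoders feeding the tagger network.

Two input channels: a pretrained word-embedding lookup (300-dimensional by
convention, any dimension accepted) and a 128-dimensional one-hot character
encoding.  A character whose Unicode code point is below 127 activates the
component at that code point; every other character activates the last
component (index 127), so all ASCII letters, digits, punctuation and symbols
get distinct codes and the long tail of other characters shares one bucket.

Word lookup lower-cases the token first (standard Word2Vec practice);
out-of-vocabulary tokens map to a default vector (all zeros unless the table
says otherwise), which is neutral under concatenation with the learned
character embedding.  The character channel does NOT fold case — letter case
is signal there.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

CHAR_ONEHOT_DIM = 128


def char_index(ch: str) -> int:
    """Index of the nonzero one-hot component for a single character."""
    if len(ch) != 1:
        raise ValueError(f"expected a single character, got {ch!r}")
    cp = ord(ch)
    return cp if cp < CHAR_ONEHOT_DIM - 1 else CHAR_ONEHOT_DIM - 1


def encode_char(ch: str) -> np.ndarray:
    """One-hot encode a single character into a 128-dim binary vector."""
    vec = np.zeros(CHAR_ONEHOT_DIM)
    vec[char_index(ch)] = 1.0
    return vec


def encode_token_chars(token: str) -> np.ndarray:
    """One-hot encode every character of a token; shape (len(token), 128)."""
    if token == "":
        raise ValueError("cannot encode an empty token")
    out = np.zeros((len(token), CHAR_ONEHOT_DIM))
    out[np.arange(len(token)), [char_index(c) for c in token]] = 1.0
    return out


def token_char_indices(token: str) -> np.ndarray:
    """Compact integer form of :func:`encode_token_chars` (used internally)."""
    if token == "":
        raise ValueError("cannot encode an empty token")
    return np.array([char_index(c) for c in token], dtype=np.intp)


@dataclass(eq=False)  # identity semantics: tables are compared/cached by object
class EmbeddingTable:
    """Word → vector lookup with a total default for unseen vocabulary."""

    dim: int
    vectors: dict[str, np.ndarray]
    default: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.default is None:
            self.default = np.zeros(self.dim)
        if self.default.shape != (self.dim,):
            raise ValueError("default vector has wrong dimension")
        for word, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {word!r} has wrong dimension")

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors.get(token.lower(), self.default)


def lookup_word(table: EmbeddingTable, token: str) -> np.ndarray:
    """Lower-cased word lookup; out-of-vocabulary tokens get the default."""
    return table.lookup(token)


def load_embedding_table(path) -> EmbeddingTable:
    """Load a plain-text ``word v1 ... vD`` embedding table (gzip accepted)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with opener(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            word, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
                if dim == 0:
                    raise ValueError(f"{path}:{line_no}: row has no values")
            if len(values) != dim:
                raise ValueError(
                    f"{path}:{line_no}: expected {dim} values, got {len(values)}"
                )
            vectors[word.lower()] = np.array(values, dtype=float)
    if dim is None:
        raise ValueError(f"{path}: empty embedding file")
    return EmbeddingTable(dim=dim, vectors=vectors)


def make_random_table(
    vocab: Iterable[str], dim: int = 300, seed: int = 0
) -> EmbeddingTable:
    """Seeded random table, entries i.i.d. uniform in [-0.1, 0.1].

    Stands in for a large pretrained table in self-contained experiments;
    the word channel then carries arbitrary-but-fixed per-word signal.
    """
    words = sorted({w.lower() for w in vocab})
    if not words:
        raise ValueError("vocab must be nonempty")
    rng = np.random.default_rng(seed)
    vectors = {w: rng.uniform(-0.1, 0.1, size=dim) for w in words}
    return EmbeddingTable(dim=dim, vectors=vectors)
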