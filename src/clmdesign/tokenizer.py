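"""Character-level SMILES tokenization with atomic multi-character symbols.

Greedy longest-match tokenization: two-character element symbols (Cl, Br) and
bracket atoms ``[...]`` are kept as single tokens, everything else is one
character. Three special symbols are reserved: PAD (always index 0), START,
and END. The vocabulary is the sorted set of corpus tokens plus the specials,
so refitting on the same corpus is deterministic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PAD = "<pad>"
START = "^"
END = "$"
SPECIALS = (PAD, START, END)

# bracket atoms are atomic; Cl/Br before single letters
_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Cl|Br|.)")


def split_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into tokens (no specials added)."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"tokenization failed to cover {smiles!r}")
    return tokens


class TokenNotInVocabularyError(KeyError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory; PAD at index 0, then START, END, then the
    sorted corpus tokens. Its size fixes the model's one-hot/output width."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        if self.tokens[0] != PAD:
            raise ValueError("PAD must have index 0")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def start_index(self) -> int:
        return self.tokens.index(START)

    @property
    def end_index(self) -> int:
        return self.tokens.index(END)

    def index(self, token: str) -> int:
        try:
            return self._lookup[token]
        except KeyError:
            raise TokenNotInVocabularyError(f"token {token!r} not in vocabulary")

    @property
    def _lookup(self) -> dict[str, int]:
        # frozen dataclass: cache on the object dict via object.__setattr__
        if "_lookup_cache" not in self.__dict__:
            object.__setattr__(self, "_lookup_cache", {t: i for i, t in enumerate(self.tokens)})
        return self.__dict__["_lookup_cache"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"tokens": list(self.tokens)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        return cls(tuple(json.loads(Path(path).read_text())["tokens"]))

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256("\x00".join(self.tokens).encode()).hexdigest()[:16]


def fit_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Build the vocabulary from a corpus: specials + sorted distinct tokens."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    seen: set[str] = set()
    for smi in corpus:
        seen.update(split_smiles(smi))
    return Vocabulary(SPECIALS + tuple(sorted(seen)))


def tokenize(smiles: str, vocab: Vocabulary) -> list[int]:
    """Encode a SMILES string as [START, tokens..., END] index list."""
    return (
        [vocab.start_index]
        + [vocab.index(t) for t in split_smiles(smiles)]
        + [vocab.end_index]
    )


def detokenize(indices: Sequence[int], vocab: Vocabulary) -> str:
    """Decode an index sequence back to a SMILES string, dropping specials."""
    specials = {vocab.pad_index, vocab.start_index, vocab.end_index}
    return "".join(vocab.tokens[i] for i in indices if i not in specials)


def encode_batch(corpus: Sequence[str], vocab: Vocabulary, max_len: int = 140) -> np.ndarray:
    """Encode a corpus into a right-padded (n, max_len + 2) int array.

    Row layout: START, tokens, END, PAD... — the +2 accommodates the two
    specials around a maximal-length string.
    """
    width = max_len + 2
    out = np.full((len(corpus), width), vocab.pad_index, dtype=np.int64)
    for i, smi in enumerate(corpus):
        seq = tokenize(smi, vocab)
        if len(seq) > width:
            raise ValueError(f"SMILES longer than max_len={max_len}: {smi!r}")
        out[i, : len(seq)] = seq
    return out


def one_hot(indices: np.ndarray, vocab_size: int) -> np.ndarray:
    """One-hot encode an integer array along a trailing axis."""
    eye = np.eye(vocab_size, dtype=np.float32)
    return eye[indices]
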