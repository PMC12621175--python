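"""Decoding molecules from the language model.

Two decoders are provided: deterministic beam search ranked by cumulative
log-probability (no length normalization), used for epoch selection, and
stochastic temperature sampling q_i = exp(z_i/T) / Σ_j exp(z_j/T), used for
design generation. Both stop a sequence at the END token or at the maximum
length of 140 characters.

Decoding is written against a minimal autoregressive interface (vocabulary,
``initial_state``, ``step``) so the same code drives the trained network and
hand-specified probability-table models used to cross-check the decoders
against exhaustive enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .chem import bulk_tanimoto, fingerprint_matrix, morgan_fp, standardize
from .tokenizer import Vocabulary, detokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenerationConfig:
    """Decoding settings: beam width k, sampling temperature T, number of
    samples, maximum SMILES length, and the sampling seed."""

    beam_width: int = 50
    temperature: float = 0.2
    n_samples: int = 2000
    max_len: int = 140
    seed: int = 0

    def __post_init__(self):
        if self.beam_width < 1:
            raise ValueError("beam width must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")


@dataclass(frozen=True)
class BeamHypothesis:
    """A complete decoded sequence with its cumulative log-probability."""

    tokens: tuple[int, ...]  # token indices after START, without END
    score: float
    smiles: str


@runtime_checkable
class AutoregressiveModel(Protocol):
    """What a decoder needs from a sequence model."""

    def vocabulary(self) -> Vocabulary: ...

    def initial_state(self, batch: int): ...

    def step(self, tokens: np.ndarray, state) -> tuple[np.ndarray, object]:
        """Consume one token per batch row; return (logits (batch, V), state)."""
        ...


class NetworkAdapter:
    """Adapts a fitted :class:`~clmdesign.model.SmilesLanguageModel` to the
    decoding interface with efficient incremental state."""

    def __init__(self, model):
        model._require_fitted()
        self._net = model.net_
        self._vocab = model.vocab_
        self._eye = np.eye(self._vocab.size, dtype=np.float32)

    def vocabulary(self) -> Vocabulary:
        return self._vocab

    def initial_state(self, batch: int):
        return self._net.init_state(batch)

    def step(self, tokens: np.ndarray, state):
        return self._net.step(self._eye[tokens], state)


class PrefixTableModel:
    """Reference model defined by explicit conditional distributions.

    ``table`` maps a prefix tuple of token indices (excluding START) to a
    probability vector over the vocabulary. Used to validate decoders against
    brute-force enumeration; not a trained model.
    """

    def __init__(self, vocab: Vocabulary, table: dict[tuple[int, ...], np.ndarray]):
        self._vocab = vocab
        self.table = table

    def vocabulary(self) -> Vocabulary:
        return self._vocab

    def initial_state(self, batch: int):
        return [() for _ in range(batch)]

    def step(self, tokens: np.ndarray, state):
        new_state = []
        logits = np.full((len(tokens), self._vocab.size), -np.inf)
        for r, (tk, prefix) in enumerate(zip(tokens, state)):
            prefix = prefix if tk == self._vocab.start_index else prefix + (int(tk),)
            probs = self.table[prefix]
            with np.errstate(divide="ignore"):
                logits[r] = np.log(probs)
            new_state.append(prefix)
        return logits, new_state


def _adapt(model) -> AutoregressiveModel:
    if hasattr(model, "net_"):
        return NetworkAdapter(model)
    return model


def _gather_state(state, idx: np.ndarray):
    """Reorder per-beam state after pruning: recurrent (h, c) pairs are
    sliced along the batch axis, anything else is indexed per beam."""
    if (
        isinstance(state, list)
        and state
        and isinstance(state[0], tuple)
        and len(state[0]) == 2
        and isinstance(state[0][0], np.ndarray)
    ):
        return [(h[idx], c[idx]) for h, c in state]
    return [state[i] for i in idx]


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    with np.errstate(divide="ignore"):
        return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def beam_search(model, config: GenerationConfig = GenerationConfig()) -> list[BeamHypothesis]:
    """Top-k complete sequences by cumulative log-probability Σ log P(y_i|y_1:i−1).

    No length normalization is applied. A sequence completes at END or at
    ``max_len`` tokens. Ties at equal score are broken lexicographically by
    token indices, making the decoding fully deterministic. PAD and START are
    never extended into a sequence.
    """
    model = _adapt(model)
    vocab = model.vocabulary()
    k = config.beam_width
    V = vocab.size
    banned = np.zeros(V)
    banned[[vocab.pad_index, vocab.start_index]] = -np.inf

    # active: (tokens_tuple, score); parallel arrays of last token and state
    active_tokens: list[tuple[int, ...]] = [()]
    active_scores = np.array([0.0])
    last = np.array([vocab.start_index])
    state = model.initial_state(1)
    finished: list[tuple[float, tuple[int, ...], bool]] = []  # (score, tokens, truncated)

    for _ in range(config.max_len + 1):
        if not active_tokens:
            break
        logits, state = model.step(last, state)
        logp = _log_softmax(logits) + banned

        cand_scores = active_scores[:, None] + logp  # (n_active, V)
        pool: list[tuple[float, tuple[int, ...], int]] = []  # (score, tokens, parent)
        for b, toks in enumerate(active_tokens):
            for v in range(V):
                s = cand_scores[b, v]
                if s == -np.inf:
                    continue
                pool.append((s, toks + (v,), b))
        # merge with already-finished hypotheses; keep overall top-k
        merged = [(s, t, -1) for (s, t, _tr) in finished] + pool
        merged.sort(key=lambda e: (-e[0], e[1]))
        merged = merged[:k]

        new_active_tokens, new_active_scores, new_parents, new_finished = [], [], [], []
        for s, t, parent in merged:
            if parent == -1:
                new_finished.append((s, t, False))
            elif t[-1] == vocab.end_index:
                new_finished.append((s, t[:-1], False))
            elif len(t) >= config.max_len:
                new_finished.append((s, t, True))
            else:
                new_active_tokens.append(t)
                new_active_scores.append(s)
                new_parents.append(parent)
        finished = new_finished
        active_tokens = new_active_tokens
        if not active_tokens:
            break
        state = _gather_state(state, np.array(new_parents))
        last = np.array([t[-1] for t in active_tokens])
        active_scores = np.array(new_active_scores)

    finished.sort(key=lambda e: (-e[0], e[1]))
    out = []
    for s, toks, _truncated in finished[:k]:
        out.append(BeamHypothesis(toks, float(s), detokenize(toks, vocab)))
    return out


def temperature_sample(model, config: GenerationConfig = GenerationConfig(), batch_size: int = 512) -> list[str]:
    """Draw ``n_samples`` SMILES strings with tempered softmax sampling.

    Each position is drawn from softmax(z/T); PAD and START are excluded
    everywhere and END is excluded at the first position (no empty
    molecules). Sequences are truncated at ``max_len``. The returned raw
    multiset keeps invalid SMILES; validity filtering happens downstream in
    prioritization.
    """
    model = _adapt(model)
    vocab = model.vocabulary()
    rng = np.random.default_rng(config.seed)
    V = vocab.size
    banned = np.zeros(V)
    banned[[vocab.pad_index, vocab.start_index]] = -np.inf

    out: list[str] = []
    remaining = config.n_samples
    while remaining > 0:
        B = min(batch_size, remaining)
        remaining -= B
        state = model.initial_state(B)
        last = np.full(B, vocab.start_index)
        alive = np.ones(B, dtype=bool)
        seqs: list[list[int]] = [[] for _ in range(B)]
        for pos in range(config.max_len):
            logits, state = model.step(last, state)
            z = logits / config.temperature + banned
            if pos == 0:
                z[:, vocab.end_index] = -np.inf
            z = z - z.max(axis=1, keepdims=True)
            probs = np.exp(z)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(B)
            draws = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
            for b in range(B):
                if not alive[b]:
                    continue
                if draws[b] == vocab.end_index:
                    alive[b] = False
                else:
                    seqs[b].append(int(draws[b]))
            if not alive.any():
                break
            last = draws
        out.extend(detokenize(s, vocab) for s in seqs)
    return out


def select_epochs(
    model,
    checkpoints,
    reference_corpus: Sequence[str],
    beam_width: int = 50,
    band: tuple[float, float] = (0.3, 0.8),
    max_len: int = 140,
) -> tuple[list[int], pd.DataFrame]:
    """Score each fine-tuning epoch by the mean nearest-neighbor Tanimoto of
    its beam-search designs to the template corpus; return the epochs whose
    aggregate falls inside ``band`` together with the full score table.

    The model's current weights are restored afterwards. Epochs whose beam
    yields no valid molecule score 0 (with a warning).
    """
    if not checkpoints:
        raise ValueError("need at least one checkpoint")
    if len(reference_corpus) == 0:
        raise ValueError("reference corpus must be non-empty")
    saved = model.net_.get_weights()
    ref_fps = fingerprint_matrix(list(reference_corpus))
    rows = []
    try:
        for ckpt in checkpoints:
            model.load_checkpoint(ckpt)
            hyps = beam_search(model, GenerationConfig(beam_width=beam_width, max_len=max_len))
            valid = []
            seen = set()
            for h in hyps:
                rec = standardize(h.smiles, strict=False)
                if rec.is_valid and rec.canonical_smiles not in seen:
                    seen.add(rec.canonical_smiles)
                    valid.append(rec.canonical_smiles)
            if valid:
                sims = [float(np.nanmax(bulk_tanimoto(morgan_fp(s).bits, ref_fps))) for s in valid]
                aggregate = float(np.mean(sims))
            else:
                aggregate = 0.0
                logger.warning("epoch %d: no valid beam designs", ckpt.epoch)
            rows.append({"epoch": ckpt.epoch, "mean_nn_similarity": aggregate,
                         "n_valid_designs": len(valid), "n_designs": len(hyps)})
    finally:
        model.net_.set_weights(saved)
    table = pd.DataFrame(rows)
    lo, hi = band
    selected = table.loc[
        (table.mean_nn_similarity >= lo) & (table.mean_nn_similarity <= hi), "epoch"
    ].tolist()
    return selected, table
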