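"""Training of the SMILES language model: pretraining, two-stage fine-tuning
with layer freezing, SMILES augmentation, and per-epoch checkpointing.

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, ``fit`` trains from scratch, fitted state carries trailing
underscores, and ``get_params``/``set_params`` come from ``BaseEstimator``.
``fine_tune`` continues training a fitted model on a task-specific corpus,
optionally freezing leading recurrent layers so the transferred syntax model
is preserved while the output distribution adapts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator

from . import tokenizer as tok
from .network import (
    Adam,
    ModelSpec,
    Network,
    build_network,
    masked_softmax_cross_entropy,
)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training round.

    Defaults reflect the fine-tuning protocol: learning rate 1e-4 (pretraining
    uses 1e-3), batch size 8, 20 epochs, reduce-on-plateau with factor 0.5,
    patience 3 and floor 5e-5, 10-fold SMILES augmentation, dropout 0.4 on
    each recurrent layer's inputs.
    """

    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 20
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    min_lr: float = 5e-5
    frozen_layers: tuple[int, ...] = ()  # recurrent-layer numbers, 1-based
    augment_fold: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.min_lr > self.learning_rate:
            raise ValueError("min_lr must not exceed learning_rate")


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate when the monitored loss stops
    improving for ``patience`` consecutive epochs; never below ``min_lr``.

    ``update(loss)`` is called once per epoch and returns the learning rate
    to use for the next epoch. The first call establishes the baseline; a
    reduction therefore occurs after ``patience`` non-improving epochs
    following the last improvement.
    """

    def __init__(self, learning_rate: float, factor: float = 0.5, patience: int = 3, min_lr: float = 5e-5):
        self.lr = learning_rate
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    def update(self, loss: float) -> float:
        if loss < self.best:
            self.best = loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.wait = 0
        return self.lr


@dataclass
class Checkpoint:
    """Weights and metadata captured at the end of one training epoch."""

    epoch: int
    weights: list[dict[str, np.ndarray]]
    vocab_ref: str
    training_loss: float

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = {}
        for li, layer in enumerate(self.weights):
            for k, v in layer.items():
                flat[f"{li}/{k}"] = v
        np.savez(directory / f"epoch_{self.epoch:03d}.npz", **flat)
        meta = {"epoch": self.epoch, "vocab_ref": self.vocab_ref, "training_loss": self.training_loss,
                "n_layers": len(self.weights), "keys": [sorted(l) for l in self.weights]}
        (directory / f"epoch_{self.epoch:03d}.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path, epoch: int) -> "Checkpoint":
        directory = Path(directory)
        meta = json.loads((directory / f"epoch_{epoch:03d}.json").read_text())
        data = np.load(directory / f"epoch_{epoch:03d}.npz")
        weights = [
            {k: data[f"{li}/{k}"] for k in keys} for li, keys in enumerate(meta["keys"])
        ]
        return cls(meta["epoch"], weights, meta["vocab_ref"], meta["training_loss"])


def augment(smiles: str, fold: int = 10, seed: int = 0) -> list[str]:
    """Up to ``fold`` distinct SMILES spellings of one molecule via random
    atom renumbering; all outputs canonicalize to the input's canonical form.
    The canonical spelling itself is always included first."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot augment invalid SMILES: {smiles!r}")
    rng = np.random.default_rng(seed)
    canonical = Chem.MolToSmiles(mol)
    out = [canonical]
    seen = {canonical}
    n_atoms = mol.GetNumAtoms()
    for _ in range(10 * fold):
        if len(out) >= fold:
            break
        order = rng.permutation(n_atoms).tolist()
        randomized = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        if randomized not in seen:
            seen.add(randomized)
            out.append(randomized)
    return out


class VocabularyMismatchError(ValueError):
    """A corpus contains tokens outside the model's vocabulary."""


class SmilesLanguageModel(BaseEstimator):
    """Recurrent SMILES language model with transfer-learning support.

    Parameters
    ----------
    hidden_sizes : tuple of int
        Units of the stacked LSTM layers (production setting 1024/512/256).
    dropout : float
        Dropout rate on each LSTM layer's inputs during training.
    learning_rate, batch_size, n_epochs, plateau_factor, plateau_patience,
    min_lr : optimization settings for ``fit`` (pretraining defaults).
    augment_fold : int
        SMILES-augmentation fold applied to the training corpus.
    max_len : int
        Longest SMILES (in characters/tokens) the model reads or writes.
    random_state : int
        Seed for weight initialization, shuffling, dropout and sampling.

    Attributes
    ----------
    vocab_ : Vocabulary fitted on (or supplied with) the training corpus.
    net_ : the underlying :class:`~clmdesign.network.Network`.
    checkpoints_ : list of Checkpoint, one per epoch of the last round.
    losses_ : per-epoch mean training cross-entropy of the last round.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (1024, 512, 256),
        dropout: float = 0.4,
        learning_rate: float = 1e-3,
        batch_size: int = 8,
        n_epochs: int = 20,
        plateau_factor: float = 0.5,
        plateau_patience: int = 3,
        min_lr: float = 5e-5,
        augment_fold: int = 1,
        max_len: int = 140,
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.min_lr = min_lr
        self.augment_fold = augment_fold
        self.max_len = max_len
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _check_corpus(self, corpus: Sequence[str], vocab: tok.Vocabulary):
        bad = []
        for smi in corpus:
            try:
                tok.tokenize(smi, vocab)
            except tok.TokenNotInVocabularyError:
                bad.append(smi)
        if bad:
            raise VocabularyMismatchError(
                f"{len(bad)} molecules contain tokens outside the vocabulary; first offenders: {bad[:5]}"
            )

    def _augmented(self, corpus: Sequence[str], fold: int, seed: int) -> list[str]:
        if fold <= 1:
            return list(corpus)
        out = []
        for i, smi in enumerate(corpus):
            out.extend(augment(smi, fold=fold, seed=seed + i))
        return out

    def _run_epochs(self, corpus, config: TrainConfig, frozen_net_layers: tuple[int, ...]):
        """Shared training loop for fit and fine_tune."""
        variants = self._augmented(corpus, config.augment_fold, config.seed)
        self._check_corpus(variants, self.vocab_)
        X = tok.encode_batch(variants, self.vocab_, max_len=self.max_len)
        rng = np.random.default_rng(config.seed)
        optimizer = Adam(self.net_, config.learning_rate, frozen_layers=frozen_net_layers)
        scheduler = ReduceLROnPlateau(
            config.learning_rate, config.plateau_factor, config.plateau_patience, config.min_lr
        )
        vocab_ref = self.vocab_.content_hash()
        checkpoints: list[Checkpoint] = []
        losses: list[float] = []
        eye = np.eye(self.vocab_.size, dtype=np.float32)
        n = len(X)
        for epoch in range(1, config.epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            epoch_weight = 0.0
            for start in range(0, n, config.batch_size):
                batch = X[order[start : start + config.batch_size]]
                # trim shared trailing padding for speed
                maxlen = int((batch != self.vocab_.pad_index).sum(axis=1).max())
                batch = batch[:, :maxlen]
                inputs, targets = batch[:, :-1], batch[:, 1:]
                mask = (targets != self.vocab_.pad_index).astype(np.float32)
                x = eye[inputs]
                self.net_.zero_grads()
                logits = self.net_.forward(x, mask, training=True)
                loss, dlogits = masked_softmax_cross_entropy(logits, targets, mask)
                self.net_.backward(dlogits)
                optimizer.step()
                epoch_loss += loss * mask.sum()
                epoch_weight += mask.sum()
            mean_loss = float(epoch_loss / epoch_weight)
            losses.append(mean_loss)
            optimizer.learning_rate = scheduler.update(mean_loss)
            checkpoints.append(Checkpoint(epoch, self.net_.get_weights(), vocab_ref, mean_loss))
        return checkpoints, losses

    def fit(self, X: Sequence[str], y=None, vocab: tok.Vocabulary | None = None):
        """Pretrain from scratch on a corpus of canonical SMILES strings."""
        corpus = list(X)
        if not corpus:
            raise ValueError("cannot fit on an empty corpus")
        config = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.n_epochs,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience,
            min_lr=self.min_lr,
            augment_fold=self.augment_fold,
            seed=self.random_state,
        )
        self.vocab_ = vocab if vocab is not None else tok.fit_vocabulary(
            self._augmented(corpus, config.augment_fold, config.seed)
        )
        self._check_corpus(corpus, self.vocab_)
        spec = ModelSpec(self.vocab_.size, tuple(self.hidden_sizes), self.dropout)
        self.spec_ = spec
        self.net_ = build_network(spec, rng=np.random.default_rng(self.random_state))
        self.checkpoints_, self.losses_ = self._run_epochs(corpus, config, frozen_net_layers=())
        return self

    def fine_tune(
        self,
        X: Sequence[str],
        frozen_recurrent: Sequence[int] = (),
        learning_rate: float = 1e-4,
        n_epochs: int = 20,
        augment_fold: int = 10,
        seed: int | None = None,
    ) -> list[Checkpoint]:
        """Continue training on a task-specific corpus.

        ``frozen_recurrent`` lists 1-based recurrent-layer numbers whose
        weights stay bit-identical (stage 1 freezes layer 1; stage 2 freezes
        layers 1 and 2). Returns the per-epoch checkpoints of this round and
        leaves the model holding the final epoch's weights.
        """
        self._require_fitted()
        config = TrainConfig(
            learning_rate=learning_rate,
            batch_size=self.batch_size,
            epochs=n_epochs,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience,
            min_lr=self.min_lr,
            frozen_layers=tuple(frozen_recurrent),
            augment_fold=augment_fold,
            seed=self.random_state if seed is None else seed,
        )
        rec = self.net_.recurrent_indices
        for r in config.frozen_layers:
            if not 1 <= r <= len(rec):
                raise ValueError(f"no recurrent layer {r}; model has {len(rec)}")
        frozen_net_layers = tuple(rec[r - 1] for r in config.frozen_layers)
        self.checkpoints_, self.losses_ = self._run_epochs(list(X), config, frozen_net_layers)
        return self.checkpoints_

    # ------------------------------------------------------------------
    def _require_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not fitted")

    def load_checkpoint(self, checkpoint: Checkpoint):
        """Restore the weights of a previously captured epoch."""
        self._require_fitted()
        if checkpoint.vocab_ref != self.vocab_.content_hash():
            raise VocabularyMismatchError("checkpoint was trained with a different vocabulary")
        self.net_.set_weights(checkpoint.weights)
        return self

    def next_token_logits(self, prefix: Sequence[int]) -> np.ndarray:
        """Logits over the vocabulary after consuming ``prefix`` (token
        indices starting with START). Convenience path for decoding oracles;
        batched decoding lives in :mod:`clmdesign.generation`."""
        self._require_fitted()
        eye = np.eye(self.vocab_.size, dtype=np.float32)
        state = self.net_.init_state(1)
        logits = None
        for idx in prefix:
            logits, state = self.net_.step(eye[None, idx], state)
        return logits[0]

    def sample(self, n_samples: int = 2000, temperature: float = 0.2, random_state: int | None = None) -> list[str]:
        """Temperature sampling; see :func:`clmdesign.generation.temperature_sample`."""
        from .generation import GenerationConfig, temperature_sample

        self._require_fitted()
        cfg = GenerationConfig(
            temperature=temperature,
            n_samples=n_samples,
            max_len=self.max_len,
            seed=self.random_state if random_state is None else random_state,
        )
        return temperature_sample(self, cfg)

    def beam_search(self, k: int = 50):
        """Deterministic beam decoding; see :func:`clmdesign.generation.beam_search`."""
        from .generation import GenerationConfig, beam_search

        self._require_fitted()
        return beam_search(self, GenerationConfig(beam_width=k, max_len=self.max_len))


# -- thin functional wrappers over the estimator -------------------------

def pretrain(corpus: Sequence[str], spec: ModelSpec, config: TrainConfig) -> SmilesLanguageModel:
    """Pretrain a model described by ``spec`` under ``config``; returns the
    fitted estimator (checkpoints in ``.checkpoints_``)."""
    model = SmilesLanguageModel(
        hidden_sizes=spec.hidden_sizes,
        dropout=spec.dropout,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.epochs,
        plateau_factor=config.plateau_factor,
        plateau_patience=config.plateau_patience,
        min_lr=config.min_lr,
        augment_fold=config.augment_fold,
        random_state=config.seed,
    )
    return model.fit(corpus)


def fine_tune(model: SmilesLanguageModel, corpus: Sequence[str], config: TrainConfig) -> list[Checkpoint]:
    """Fine-tune a fitted model under ``config`` (frozen_layers are 1-based
    recurrent layer numbers)."""
    return model.fine_tune(
        corpus,
        frozen_recurrent=config.frozen_layers,
        learning_rate=config.learning_rate,
        n_epochs=config.epochs,
        augment_fold=config.augment_fold,
        seed=config.seed,
    )
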