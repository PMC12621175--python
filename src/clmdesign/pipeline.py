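"""End-to-end orchestration: data → model → designs → reports.

Stages: synthetic data (or user corpora) → standardization → vocabulary →
pretraining → staged fine-tuning with layer freezing → beam-search epoch
selection → temperature sampling → prioritization (frequency, template
similarity, optional docking) → chemical-space reports (t-SNE embedding and
spiked virtual screen). Every stage writes its artifacts into the workspace
and is skipped on rerun when its outputs already exist, so an interrupted
run resumes from the last completed stage. A single seed drives all
randomness; non-docking outputs are fully determined by (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, tokenizer as tok
from .chemspace import EmbeddingConfig, embed_tsne, virtual_screen
from .generation import GenerationConfig, select_epochs, temperature_sample
from .model import Checkpoint, SmilesLanguageModel
from .prioritization import (
    DockingAdapter,
    DockingConfig,
    frequency_rank,
    similarity_prioritize,
    write_rank_table,
)
from .synthetic import make_study

logger = logging.getLogger(__name__)


@dataclass
class FineTuneStage:
    corpus: str  # "finetune_1" / "finetune_2" or a .smi path
    frozen_recurrent: tuple[int, ...]
    epochs: int = 20


@dataclass
class RunConfig:
    """Full pipeline configuration; (config, seed) determine all
    non-docking outputs."""

    workspace: str = "clm_run"
    seed: int = 7
    # synthetic study sizes
    pretrain_n: int = 2000
    finetune1_n: int = 120
    finetune2_n: int = 10
    # model + optimization (desk-scale defaults; see docs/methods.md)
    hidden_sizes: tuple[int, ...] = (128, 96, 64)
    dropout: float = 0.2
    batch_size: int = 8
    pretrain_epochs: int = 10
    pretrain_lr: float = 1e-3
    pretrain_augment_fold: int = 3
    finetune_lr: float = 1e-4
    augment_fold: int = 10
    max_len: int = 140
    stages: tuple[FineTuneStage, ...] = (
        FineTuneStage("finetune_1", (1,), 12),
        FineTuneStage("finetune_2", (1, 2), 12),
    )
    # generation + ranking
    beam_width: int = 50
    selection_band: tuple[float, float] = (0.3, 0.8)
    temperature: float = 0.2
    n_samples_per_epoch: int = 2000
    top_n_similar: int = 1000
    # chemspace
    perplexity: float = 30.0
    tsne_background_n: int = 300
    vscreen_retained_n: int = 1000
    # docking (off by default; needs an engine and receptor files)
    docking_enabled: bool = False
    receptor_files: dict = field(default_factory=dict)
    crystal_ligand_files: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = [dataclasses.asdict(s) for s in self.stages]
        Path(path).write_text(json.dumps(d, indent=1, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["stages"] = tuple(FineTuneStage(s["corpus"], tuple(s["frozen_recurrent"]), s.get("epochs", 20)) for s in d["stages"])
        for key in ("hidden_sizes", "selection_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, hint: str):
        super().__init__(f"stage {stage!r} failed: {hint}")
        self.stage = stage


def _read_corpus(path: Path) -> list[str]:
    return [r.canonical_smiles for r in chem.build_corpus(chem.read_smi(path))]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of key artifacts.

    The returned dict carries the rank table, the epoch-selection table, the
    selected epochs, the t-SNE frame and the virtual-screen consensus, plus
    paths of everything written.
    """
    ws = Path(config.workspace)
    ws.mkdir(parents=True, exist_ok=True)
    config.to_json(ws / "config.json")
    artifacts: dict = {"workspace": ws}

    # -- stage: synthetic data -----------------------------------------
    data_dir = ws / "data"
    if not (data_dir / "manifest.tsv").exists():
        study = make_study(config.pretrain_n, config.finetune1_n, config.finetune2_n, seed=config.seed)
        study.write(data_dir)
    corpora = {
        name: _read_corpus(data_dir / f"{name}.smi")
        for name in ("pretrain", "finetune_1", "finetune_2")
    }
    artifacts["corpora"] = corpora

    model = SmilesLanguageModel(
        hidden_sizes=config.hidden_sizes,
        dropout=config.dropout,
        learning_rate=config.pretrain_lr,
        batch_size=config.batch_size,
        n_epochs=config.pretrain_epochs,
        augment_fold=config.pretrain_augment_fold,
        max_len=config.max_len,
        random_state=config.seed,
    )

    # -- stage: vocabulary ----------------------------------------------
    # fit on exactly the spellings training will see: the augmented
    # pretraining corpus plus each fine-tuning stage's augmented corpus
    # (the per-stage seeds reproduce the training-time augmentation)
    vocab_path = ws / "vocab.json"
    if vocab_path.exists():
        vocab = tok.Vocabulary.from_json(vocab_path)
    else:
        pool = model._augmented(corpora["pretrain"], config.pretrain_augment_fold, config.seed)
        for si, stage in enumerate(config.stages, start=1):
            stage_corpus = corpora.get(stage.corpus) or _read_corpus(Path(stage.corpus))
            pool.extend(model._augmented(stage_corpus, config.augment_fold, config.seed + si))
        vocab = tok.fit_vocabulary(pool)
        vocab.to_json(vocab_path)

    # -- stage: pretraining ----------------------------------------------
    pre_dir = ws / "checkpoints" / "pretrain"
    last = pre_dir / f"epoch_{config.pretrain_epochs:03d}.npz"
    if last.exists():
        model.fit(corpora["pretrain"][:1], vocab=vocab)  # build structure only
        ckpt = Checkpoint.load(pre_dir, config.pretrain_epochs)
        model.load_checkpoint(ckpt)
        model.n_epochs = config.pretrain_epochs
    else:
        try:
            model.fit(corpora["pretrain"], vocab=vocab)
        except Exception as exc:
            raise StageError("pretrain", f"{exc}; check vocabulary covers the corpus") from exc
        for ckpt in model.checkpoints_:
            ckpt.save(pre_dir)
    artifacts["model"] = model

    # -- stage: fine-tuning rounds ---------------------------------------
    stage_checkpoints: list[Checkpoint] = []
    for si, stage in enumerate(config.stages, start=1):
        st_dir = ws / "checkpoints" / f"stage{si}"
        corpus = corpora.get(stage.corpus) or _read_corpus(Path(stage.corpus))
        last = st_dir / f"epoch_{stage.epochs:03d}.npz"
        if last.exists():
            stage_checkpoints = [Checkpoint.load(st_dir, e) for e in range(1, stage.epochs + 1)]
            model.load_checkpoint(stage_checkpoints[-1])
        else:
            try:
                stage_checkpoints = model.fine_tune(
                    corpus,
                    frozen_recurrent=stage.frozen_recurrent,
                    learning_rate=config.finetune_lr,
                    n_epochs=stage.epochs,
                    augment_fold=config.augment_fold,
                    seed=config.seed + si,
                )
            except Exception as exc:
                raise StageError(f"finetune_stage{si}", str(exc)) from exc
            for ckpt in stage_checkpoints:
                ckpt.save(st_dir)

    # -- stage: epoch selection ------------------------------------------
    sel_path = ws / "epoch_selection.tsv"
    selected_path = ws / "selected_epochs.json"
    if selected_path.exists():
        selected = json.loads(selected_path.read_text())
        sel_table = pd.read_csv(sel_path, sep="\t")
    else:
        selected, sel_table = select_epochs(
            model,
            stage_checkpoints,
            corpora["finetune_2"],
            beam_width=config.beam_width,
            band=config.selection_band,
            max_len=config.max_len,
        )
        if not selected:  # fall back to the best-scoring epoch
            selected = [int(sel_table.loc[sel_table.mean_nn_similarity.idxmax(), "epoch"])]
            logger.warning("no epoch inside the selection band; using best epoch %s", selected)
        sel_table.to_csv(sel_path, sep="\t", index=False)
        selected_path.write_text(json.dumps(selected))
    artifacts["selected_epochs"] = selected
    artifacts["epoch_table"] = sel_table

    # -- stage: temperature sampling (pooled over selected epochs) -------
    samples_path = ws / "samples.smi"
    if samples_path.exists():
        samples = [l.split("\t")[0] for l in samples_path.read_text().splitlines()]
    else:
        samples = []
        by_epoch = {c.epoch: c for c in stage_checkpoints}
        for j, ep in enumerate(selected):
            model.load_checkpoint(by_epoch[ep])
            samples.extend(
                temperature_sample(
                    model,
                    GenerationConfig(
                        temperature=config.temperature,
                        n_samples=config.n_samples_per_epoch,
                        max_len=config.max_len,
                        seed=config.seed + 1000 + j,
                    ),
                )
            )
        with open(samples_path, "w") as fh:
            for i, s in enumerate(samples):
                fh.write(f"{s}\t{i}\n")
    artifacts["samples"] = samples

    # -- stage: prioritization -------------------------------------------
    rank_path = ws / "rank_table.tsv"
    if rank_path.exists():
        ranked = pd.read_csv(rank_path, sep="\t")
    else:
        try:
            table = frequency_rank(samples, training_corpora=list(corpora.values()))
        except Exception as exc:
            raise StageError("rank", str(exc)) from exc
        table = similarity_prioritize(table, corpora["finetune_2"], top_n=config.top_n_similar)
        if config.docking_enabled:
            adapter = DockingAdapter(
                DockingConfig(),
                {k: Path(v) for k, v in config.receptor_files.items()},
                {k: Path(v) for k, v in config.crystal_ligand_files.items()},
            )
            table = adapter.dock_designs(table, seed=config.seed)
        write_rank_table(table, rank_path)
        ranked = pd.read_csv(rank_path, sep="\t")
    artifacts["rank_table"] = ranked

    # -- stage: chemical-space reports ------------------------------------
    tsne_path = ws / "tsne.tsv"
    designs = ranked.sort_values(["frequency", "smiles"], ascending=[False, True])["smiles"].head(10).tolist()
    if not tsne_path.exists():
        rng = np.random.default_rng(config.seed)
        bg = list(corpora["pretrain"])
        if len(bg) > config.tsne_background_n:
            bg = [bg[i] for i in rng.choice(len(bg), config.tsne_background_n, replace=False)]
        mols = bg + corpora["finetune_1"] + corpora["finetune_2"] + designs
        labels = (
            ["pretrain"] * len(bg)
            + ["finetune_1"] * len(corpora["finetune_1"])
            + ["finetune_2"] * len(corpora["finetune_2"])
            + ["design"] * len(designs)
        )
        perp = min(config.perplexity, max(2.0, (len(mols) - 1) / 4))
        frame = embed_tsne(mols, labels, EmbeddingConfig(perplexity=perp, seed=config.seed))
        frame.to_csv(tsne_path, sep="\t", index=False)
    artifacts["tsne"] = pd.read_csv(tsne_path, sep="\t")

    vs_path = ws / "vscreen.tsv"
    if not vs_path.exists():
        result = virtual_screen(
            corpora["pretrain"],
            designs,
            corpora["finetune_1"],
            retained_n=min(config.vscreen_retained_n, len(corpora["pretrain"])),
            spike_ids=[f"design_{i+1}" for i in range(len(designs))],
        )
        result.consensus.to_csv(vs_path, sep="\t", index=False)
    artifacts["vscreen"] = pd.read_csv(vs_path, sep="\t")

    (ws / "run_summary.json").write_text(
        json.dumps(
            {
                "seed": config.seed,
                "selected_epochs": selected,
                "n_samples": len(samples),
                "n_unique_designs": int(ranked.shape[0]),
                "vocab_hash": vocab.content_hash(),
            },
            indent=1,
        )
    )
    return artifacts
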