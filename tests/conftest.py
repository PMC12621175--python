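"""Shared fixtures: a small synthetic study and models trained on it.

Training fixtures are session-scoped because they are the expensive part of
the suite; tests must not mutate them (fine-tuning tests deep-copy first).
"""

from __future__ import annotations

import copy

import pytest
from rdkit import RDLogger

from clmdesign import tokenizer as tok
from clmdesign.model import SmilesLanguageModel, augment
from clmdesign.pipeline import FineTuneStage, RunConfig, run_pipeline
from clmdesign.synthetic import make_study

RDLogger.DisableLog("rdApp.*")

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    return make_study(200, 60, 8, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def corpora(study):
    return {
        "pretrain": [r.canonical_smiles for r in study.pretrain],
        "finetune_1": [r.canonical_smiles for r in study.finetune_1],
        "finetune_2": [r.canonical_smiles for r in study.finetune_2],
    }


@pytest.fixture(scope="session")
def full_vocab(corpora):
    """Vocabulary covering all corpora plus their augmented spellings."""
    pool = list(corpora["pretrain"])
    every = corpora["pretrain"] + corpora["finetune_1"] + corpora["finetune_2"]
    for i, smi in enumerate(every):
        pool.extend(augment(smi, fold=5, seed=i))
    return tok.fit_vocabulary(pool)


@pytest.fixture(scope="session")
def pretrained(corpora, full_vocab):
    """Language model pretrained on the diverse synthetic corpus."""
    model = SmilesLanguageModel(
        hidden_sizes=(96, 64, 48),
        dropout=0.0,
        n_epochs=16,
        batch_size=8,
        augment_fold=3,
        random_state=0,
    )
    model.fit(corpora["pretrain"], vocab=full_vocab)
    return model


@pytest.fixture(scope="session")
def finetuned(pretrained, corpora):
    """Two-stage fine-tuned copy of the pretrained model.

    Returns (model, stage2_checkpoints); the pretrained fixture is left
    untouched.
    """
    model = copy.deepcopy(pretrained)
    model.fine_tune(corpora["finetune_1"], frozen_recurrent=(1,), n_epochs=8, augment_fold=5, seed=11)
    stage2 = model.fine_tune(corpora["finetune_2"], frozen_recurrent=(1, 2), n_epochs=8, augment_fold=5, seed=12)
    return model, stage2


def smoke_config(workspace: str) -> RunConfig:
    """Desk-scale pipeline configuration used by the end-to-end tests."""
    return RunConfig(
        workspace=workspace,
        seed=STUDY_SEED,
        pretrain_n=200,
        finetune1_n=45,
        finetune2_n=6,
        hidden_sizes=(96, 64, 48),
        dropout=0.0,
        batch_size=8,
        pretrain_epochs=12,
        pretrain_augment_fold=3,
        augment_fold=5,
        stages=(FineTuneStage("finetune_1", (1,), 4), FineTuneStage("finetune_2", (1, 2), 4)),
        beam_width=8,
        selection_band=(0.05, 0.95),
        temperature=0.2,
        n_samples_per_epoch=60,
        top_n_similar=100,
        perplexity=10.0,
        tsne_background_n=60,
        vscreen_retained_n=50,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline execution in a session-scoped workspace."""
    ws = tmp_path_factory.mktemp("pipeline") / "run"
    config = smoke_config(str(ws))
    artifacts = run_pipeline(config)
    return config, artifacts
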