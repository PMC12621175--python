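"""Training behavior: schedule, augmentation, freezing, convergence."""

import copy

import numpy as np
import pytest
from rdkit import Chem

from clmdesign.generation import GenerationConfig, beam_search
from clmdesign.model import (
    Checkpoint,
    ReduceLROnPlateau,
    SmilesLanguageModel,
    VocabularyMismatchError,
    augment,
)


class TestPlateauSchedule:
    def test_constant_loss_halves_after_patience(self):
        """Hand simulation: first epoch sets the baseline; after 3 further
        stagnant epochs the rate halves; the floor is never undercut."""
        sched = ReduceLROnPlateau(1e-4, factor=0.5, patience=3, min_lr=5e-5)
        rates = [sched.update(1.0) for _ in range(8)]
        #           base   w1    w2    halve  w1    w2    halve->floor ...
        assert rates == [1e-4, 1e-4, 1e-4, 5e-5, 5e-5, 5e-5, 5e-5, 5e-5]

    def test_improving_loss_keeps_rate(self):
        sched = ReduceLROnPlateau(1e-3, factor=0.5, patience=2, min_lr=1e-5)
        rates = [sched.update(loss) for loss in (3.0, 2.5, 2.0, 1.5, 1.0)]
        assert all(r == 1e-3 for r in rates)

    def test_reduction_resets_wait_counter(self):
        sched = ReduceLROnPlateau(8e-4, factor=0.5, patience=2, min_lr=1e-5)
        losses = [1.0, 1.0, 1.0, 1.0, 1.0]  # baseline + 4 stagnant epochs
        rates = [sched.update(l) for l in losses]
        assert rates == [8e-4, 8e-4, 4e-4, 4e-4, 2e-4]


class TestAugment:
    def test_methane_has_single_spelling(self):
        assert augment("C", fold=10, seed=0) == ["C"]

    def test_all_variants_canonicalize_back(self):
        for smi in ("CCO", "Cc1ccccc1", "CS(=O)(=O)c1cccc(Br)c1"):
            canonical = Chem.CanonSmiles(smi)
            variants = augment(smi, fold=10, seed=3)
            assert 1 <= len(variants) <= 10
            assert all(Chem.CanonSmiles(v) == canonical for v in variants)

    def test_toluene_yields_multiple_distinct_spellings(self):
        variants = augment("Cc1ccccc1", fold=10, seed=1)
        assert 1 < len(variants) <= 10
        assert len(set(variants)) == len(variants)

    def test_deterministic_under_seed(self):
        assert augment("CCN(CC)c1ccccc1", 10, seed=5) == augment("CCN(CC)c1ccccc1", 10, seed=5)

    def test_invalid_molecule_raises(self):
        with pytest.raises(ValueError):
            augment("x(y", 5)


class TestTraining:
    def test_loss_decreases_over_pretraining(self, pretrained):
        assert pretrained.losses_[4] < pretrained.losses_[0]
        assert pretrained.losses_[-1] < pretrained.losses_[4]

    def test_checkpoints_one_per_epoch(self, pretrained):
        assert [c.epoch for c in pretrained.checkpoints_] == list(range(1, pretrained.n_epochs + 1))

    def test_sampling_validity_after_pretraining(self, pretrained):
        """A converged desk-scale model emits mostly valid SMILES at T=0.2."""
        samples = pretrained.sample(200, temperature=0.2, random_state=1)
        n_valid = sum(Chem.MolFromSmiles(s) is not None for s in samples)
        assert n_valid >= 0.8 * len(samples)

    def test_single_molecule_memorization(self):
        model = SmilesLanguageModel(
            hidden_sizes=(16, 12, 8), dropout=0.0, n_epochs=150, batch_size=1, random_state=0
        )
        model.fit(["CCO"])
        assert model.losses_[-1] < 0.2
        top = beam_search(model, GenerationConfig(beam_width=1, max_len=10))
        assert top[0].smiles == "CCO"

    def test_same_seed_reproduces_losses(self, corpora, full_vocab):
        kwargs = dict(hidden_sizes=(24, 16, 12), dropout=0.2, n_epochs=2, batch_size=8, random_state=9)
        m1 = SmilesLanguageModel(**kwargs).fit(corpora["finetune_1"], vocab=full_vocab)
        m2 = SmilesLanguageModel(**kwargs).fit(corpora["finetune_1"], vocab=full_vocab)
        assert m1.losses_ == m2.losses_

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            SmilesLanguageModel().fit([])


@pytest.fixture(scope="module")
def tiny_trained(corpora, full_vocab):
    model = SmilesLanguageModel(
        hidden_sizes=(24, 16, 12), dropout=0.0, n_epochs=2, batch_size=8, random_state=1
    )
    model.fit(corpora["finetune_1"][:20], vocab=full_vocab)
    return model


class TestFineTuning:
    @pytest.mark.parametrize("frozen", [(1,), (1, 2)])
    def test_frozen_recurrent_weights_bit_identical(self, tiny_trained, corpora, frozen):
        model = copy.deepcopy(tiny_trained)
        rec = model.net_.recurrent_indices
        before = model.net_.get_weights()
        model.fine_tune(corpora["finetune_2"], frozen_recurrent=frozen, n_epochs=2, augment_fold=2, seed=4)
        after = model.net_.get_weights()
        for r in frozen:
            li = rec[r - 1]
            for k in ("Wx", "Wh", "b"):
                assert np.array_equal(before[li][k], after[li][k])
        # at least one unfrozen recurrent layer moved
        free = [rec[i] for i in range(len(rec)) if (i + 1) not in frozen]
        assert any(
            not np.array_equal(before[li]["Wx"], after[li]["Wx"]) for li in free
        )

    def test_out_of_vocabulary_corpus_rejected(self, tiny_trained):
        model = copy.deepcopy(tiny_trained)
        with pytest.raises(VocabularyMismatchError):
            model.fine_tune(["C[Se]C"], n_epochs=1, augment_fold=1)

    def test_invalid_frozen_layer_number(self, tiny_trained):
        model = copy.deepcopy(tiny_trained)
        with pytest.raises(ValueError):
            model.fine_tune(["CCO"], frozen_recurrent=(7,), n_epochs=1, augment_fold=1)


class TestCheckpoints:
    def test_save_load_reproduces_distributions(self, tmp_path, finetuned):
        model, checkpoints = finetuned
        ck = checkpoints[-1]
        ck.save(tmp_path)
        loaded = Checkpoint.load(tmp_path, ck.epoch)
        assert loaded.training_loss == pytest.approx(ck.training_loss)
        model.load_checkpoint(loaded)
        prefix = [model.vocab_.start_index, model.vocab_.index("C")]
        direct = model.next_token_logits(prefix)
        model.load_checkpoint(ck)
        assert np.allclose(direct, model.next_token_logits(prefix))

    def test_vocabulary_mismatch_detected(self, finetuned):
        model, checkpoints = finetuned
        bad = Checkpoint(1, checkpoints[-1].weights, "deadbeef", 1.0)
        with pytest.raises(VocabularyMismatchError):
            model.load_checkpoint(bad)
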