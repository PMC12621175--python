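"""Decoders checked against closed forms and exhaustive enumeration."""

import math

import numpy as np
import pytest
from scipy import stats

from clmdesign import tokenizer as tok
from clmdesign.chem import nearest_neighbor_sims
from clmdesign.generation import (
    BeamHypothesis,
    GenerationConfig,
    PrefixTableModel,
    beam_search,
    select_epochs,
    temperature_sample,
)
from clmdesign.model import Checkpoint, SmilesLanguageModel
from clmdesign.network import ModelSpec, build_network

VOCAB = tok.Vocabulary((tok.PAD, tok.START, tok.END, "C", "O"))
END, C, O = VOCAB.end_index, VOCAB.index("C"), VOCAB.index("O")


def make_table(assignments):
    """Helper: build dense probability vectors over the toy vocabulary."""
    table = {}
    for prefix, probs in assignments.items():
        row = np.zeros(VOCAB.size)
        for token, p in probs.items():
            row[token] = p
        table[prefix] = row
    return table


def enumerate_complete(table, max_len):
    """Brute-force oracle: every complete sequence with its cumulative
    log-probability, sorted exactly the way beam search sorts."""
    out = []

    def rec(prefix, logp):
        probs = table[prefix]
        for v in range(VOCAB.size):
            p = probs[v]
            if p <= 0 or v in (VOCAB.pad_index, VOCAB.start_index):
                continue
            lp = logp + math.log(p)
            if v == END:
                out.append((lp, prefix))
            elif len(prefix) + 1 >= max_len:
                out.append((lp, prefix + (v,)))
            else:
                rec(prefix + (v,), lp)

    rec((), 0.0)
    out.sort(key=lambda e: (-e[0], e[1]))
    return out


def random_table(rng, max_len):
    """Dense random conditional tables over {C, O, END} up to max_len."""
    table = {}

    def rec(prefix):
        probs = rng.dirichlet(np.ones(3))
        table[prefix] = make_table({prefix: {END: probs[0], C: probs[1], O: probs[2]}})[prefix]
        if len(prefix) < max_len:
            rec(prefix + (C,))
            rec(prefix + (O,))

    rec(())
    return table


class TestBeamSearch:
    def test_hand_table_matches_enumeration_at_k2(self):
        table = make_table(
            {
                (): {C: 0.7, O: 0.3},
                (C,): {END: 0.8, C: 0.2},
                (O,): {END: 0.9, O: 0.1},
                (C, C): {END: 1.0},
                (O, O): {END: 1.0},
            }
        )
        model = PrefixTableModel(VOCAB, table)
        hyps = beam_search(model, GenerationConfig(beam_width=2, max_len=3))
        oracle = enumerate_complete(table, 3)[:2]
        assert [(h.score, h.tokens) for h in hyps] == [
            (pytest.approx(lp), t) for lp, t in oracle
        ]
        assert hyps[0].smiles == "C"  # P = 0.7 * 0.8 = 0.56

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_tables_match_enumeration_with_wide_beam(self, seed):
        rng = np.random.default_rng(seed)
        max_len = 4
        table = random_table(rng, max_len)
        oracle = enumerate_complete(table, max_len)
        model = PrefixTableModel(VOCAB, table)
        hyps = beam_search(model, GenerationConfig(beam_width=len(oracle) + 50, max_len=max_len))
        assert len(hyps) == len(oracle)
        for h, (lp, t) in zip(hyps, oracle):
            assert h.tokens == t
            assert h.score == pytest.approx(lp)

    def test_scores_monotonically_non_increasing(self, finetuned):
        model, _ = finetuned
        hyps = beam_search(model, GenerationConfig(beam_width=10, max_len=60))
        scores = [h.score for h in hyps]
        assert scores == sorted(scores, reverse=True)
        assert all(s <= 0 for s in scores)

    def test_k1_equals_greedy_argmax(self):
        table = make_table(
            {
                (): {C: 0.6, O: 0.4},
                (C,): {END: 0.5, O: 0.5},  # tie: END (lower index) wins
                (C, O): {END: 1.0},
            }
        )
        model = PrefixTableModel(VOCAB, table)
        hyps = beam_search(model, GenerationConfig(beam_width=1, max_len=3))
        assert len(hyps) == 1
        # greedy rollout: C then the tie resolves to END by index order
        assert hyps[0].tokens == (C,)

    def test_deterministic(self, finetuned):
        model, _ = finetuned
        cfg = GenerationConfig(beam_width=5, max_len=50)
        a = beam_search(model, cfg)
        b = beam_search(model, cfg)
        assert [(h.smiles, h.score) for h in a] == [(h.smiles, h.score) for h in b]


class TestTemperatureSampling:
    def test_closed_form_tempering(self):
        # logits (0, ln 2) at T = 0.2 -> probabilities (1/33, 32/33)
        z = np.array([0.0, math.log(2.0)])
        q = np.exp(z / 0.2) / np.exp(z / 0.2).sum()
        assert q == pytest.approx([1 / 33, 32 / 33])

    def test_sampling_frequencies_match_tempered_softmax(self):
        table = make_table({(): {C: 1 / 3, O: 2 / 3}, (C,): {END: 1.0}, (O,): {END: 1.0}})
        model = PrefixTableModel(VOCAB, table)
        n = 20_000
        out = temperature_sample(model, GenerationConfig(temperature=0.2, n_samples=n, max_len=2, seed=5))
        f_o = sum(1 for s in out if s == "O") / n
        # tempered probability of O is 32/33; binomial 4-sigma envelope
        p = 32 / 33
        assert abs(f_o - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_t1_recovers_untempered_distribution(self):
        probs = {C: 0.35, O: 0.65}
        table = make_table({(): probs, (C,): {END: 1.0}, (O,): {END: 1.0}})
        model = PrefixTableModel(VOCAB, table)
        n = 10_000
        out = temperature_sample(model, GenerationConfig(temperature=1.0, n_samples=n, max_len=2, seed=6))
        counts = [sum(1 for s in out if s == "C"), sum(1 for s in out if s == "O")]
        res = stats.chisquare(counts, [0.35 * n, 0.65 * n])
        assert res.pvalue > 0.01

    def test_low_temperature_limit_is_argmax(self):
        table = make_table({(): {C: 0.4, O: 0.6}, (C,): {END: 1.0}, (O,): {END: 1.0}})
        model = PrefixTableModel(VOCAB, table)
        out = temperature_sample(model, GenerationConfig(temperature=1e-6, n_samples=2000, max_len=2, seed=7))
        assert sum(1 for s in out if s == "O") >= 0.999 * len(out)

    def test_tempering_preserves_argmax(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            z = rng.normal(size=9)
            for t in (0.1, 0.5, 1.0, 5.0):
                assert np.argmax(np.exp(z / t)) == np.argmax(z)

    def test_same_seed_identical_multiset(self, finetuned):
        model, _ = finetuned
        cfg = GenerationConfig(temperature=0.2, n_samples=50, max_len=60, seed=42)
        assert temperature_sample(model, cfg) == temperature_sample(model, cfg)

    def test_sample_count_and_truncation(self):
        # a model that never emits END: every draw truncates at max_len
        table = {(): make_table({(): {C: 1.0}})[()]}
        table.update({(C,) * k: table[()] for k in range(1, 6)})
        model = PrefixTableModel(VOCAB, table)
        out = temperature_sample(model, GenerationConfig(temperature=1.0, n_samples=25, max_len=5, seed=1))
        assert len(out) == 25
        assert all(s == "C" * 5 for s in out)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GenerationConfig(temperature=0.0)
        with pytest.raises(ValueError):
            GenerationConfig(beam_width=0)


class TestEpochSelection:
    def test_memorizing_checkpoint_scores_one(self):
        model = SmilesLanguageModel(
            hidden_sizes=(16, 12, 8), dropout=0.0, n_epochs=150, batch_size=1, random_state=0
        )
        model.fit(["CCO"])
        selected, table = select_epochs(
            model, model.checkpoints_[-1:], ["CCO"], beam_width=1, band=(0.99, 1.0), max_len=10
        )
        assert table.mean_nn_similarity.iloc[0] == pytest.approx(1.0)
        assert selected == [model.checkpoints_[-1].epoch]

    def test_trained_beats_untrained(self, finetuned, corpora, full_vocab):
        model, stage2 = finetuned
        untrained = SmilesLanguageModel(hidden_sizes=(96, 64, 48), random_state=3)
        untrained.vocab_ = full_vocab
        untrained.spec_ = ModelSpec(full_vocab.size, (96, 64, 48), 0.0)
        untrained.net_ = build_network(untrained.spec_, rng=np.random.default_rng(3))
        random_ckpt = Checkpoint(1, untrained.net_.get_weights(), full_vocab.content_hash(), 99.0)
        _, t_untrained = select_epochs(
            untrained, [random_ckpt], corpora["finetune_2"], beam_width=8, band=(0, 1), max_len=60
        )
        _, t_trained = select_epochs(
            model, stage2[-1:], corpora["finetune_2"], beam_width=8, band=(0, 1), max_len=60
        )
        assert t_trained.mean_nn_similarity.iloc[0] > t_untrained.mean_nn_similarity.iloc[0]

    def test_weights_restored_after_selection(self, finetuned, corpora):
        model, stage2 = finetuned
        before = model.net_.get_weights()
        select_epochs(model, stage2[:2], corpora["finetune_2"], beam_width=4, band=(0, 1), max_len=50)
        after = model.net_.get_weights()
        for wb, wa in zip(before, after):
            for k in wb:
                assert np.array_equal(wb[k], wa[k])

    def test_empty_inputs_rejected(self, finetuned):
        model, stage2 = finetuned
        with pytest.raises(ValueError):
            select_epochs(model, [], ["CCO"])
        with pytest.raises(ValueError):
            select_epochs(model, stage2, [])
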