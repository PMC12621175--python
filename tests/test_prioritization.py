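"""Frequency/similarity ranking, docking aggregation, engine adapter."""

import os
import stat

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clmdesign.prioritization import (
    AllInvalidError,
    DockingAdapter,
    DockingConfig,
    DockingUnavailableError,
    aggregate_dock,
    frequency_rank,
    parse_engine_affinity,
    similarity_prioritize,
    write_rank_table,
)


class TestFrequencyRank:
    def test_canonical_merging_and_ordering(self):
        samples = ["CCO", "OCC", "CCO", "OCC", "CCO", "CCN"]
        table = frequency_rank(samples)
        assert table.loc[0, "smiles"] == "CCO"
        assert table.loc[0, "frequency"] == 5
        assert table.loc[0, "freq_rank"] == 1
        assert table.loc[1, "smiles"] == "CCN"
        assert table.loc[1, "frequency"] == 1

    def test_single_sample(self):
        table = frequency_rank(["CCO"])
        assert len(table) == 1
        assert table.loc[0, "freq_rank"] == 1

    def test_frequency_conservation(self):
        samples = ["CCO"] * 3 + ["CCN"] * 2 + ["bad(("] * 4 + ["c1ccccc1"]
        table = frequency_rank(samples)
        assert table.frequency.sum() == 6  # valid draws only
        assert table.attrs["n_invalid"] == 4

    def test_rerank_bit_identical(self):
        samples = ["CCO", "CCN", "OCC", "c1ccccc1", "CCN"]
        assert frequency_rank(samples).equals(frequency_rank(samples))

    def test_novelty_flag_against_training_corpora(self):
        table = frequency_rank(["CCO", "CCN"], training_corpora=[["OCC"]])
        flags = dict(zip(table.smiles, table.novel))
        assert flags == {"CCO": False, "CCN": True}

    def test_tie_broken_lexicographically(self):
        table = frequency_rank(["CCN", "CCO"])
        assert list(table.smiles) == ["CCN", "CCO"]

    def test_all_invalid_raises(self):
        with pytest.raises(AllInvalidError):
            frequency_rank(["not_a_smiles"])
        with pytest.raises(AllInvalidError):
            frequency_rank([])


class TestSimilarityPrioritize:
    def test_template_identity_scores_one(self):
        table = frequency_rank(["CCO", "c1ccccc1"])
        out = similarity_prioritize(table, ["CCO"], top_n=10)
        assert out.loc[out.smiles == "CCO", "nn_similarity"].iloc[0] == pytest.approx(1.0)
        assert out.loc[0, "smiles"] == "CCO"

    def test_top_n_matches_exhaustive_sort(self, corpora):
        designs = corpora["pretrain"][:10]
        templates = corpora["finetune_2"]
        table = frequency_rank(designs)
        out = similarity_prioritize(table, templates, top_n=3)
        from clmdesign.chem import nearest_neighbor_sims

        sims = nearest_neighbor_sims(list(table.smiles), templates)
        expected = sorted(sims, reverse=True)[:3]
        assert list(out.nn_similarity) == pytest.approx(expected)

    def test_top_n_larger_than_designs_keeps_all(self):
        table = frequency_rank(["CCO", "CCN"])
        out = similarity_prioritize(table, ["CCO"], top_n=100)
        assert len(out) == 2
        assert list(out.sim_rank) == [1, 2]

    def test_nonpositive_top_n_rejected(self):
        table = frequency_rank(["CCO"])
        with pytest.raises(ValueError):
            similarity_prioritize(table, ["CCO"], top_n=0)


class TestAggregateDock:
    def test_kcal_scale_affinities(self):
        assert aggregate_dock(-14.0, -15.1) == pytest.approx(-np.sqrt(14.0 * 15.1))
        assert aggregate_dock(-14.0, -15.1) == pytest.approx(-14.54, abs=0.01)

    def test_idempotent_on_equal_scores(self):
        assert aggregate_dock(-9.3, -9.3) == pytest.approx(-9.3)

    def test_mixed_signs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_dock(-14.0, 2.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=30.0),
        st.floats(min_value=0.1, max_value=30.0),
    )
    def test_geometric_mean_bound(self, a, b):
        agg = aggregate_dock(-a, -b)
        assert -max(a, b) - 1e-9 <= agg <= -min(a, b) + 1e-9


ENGINE_OUTPUT = """\
Using random seed: 7

mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
1       -9.4       0.000      0.000
2       -8.7       1.912      3.004
"""


class TestDockingAdapter:
    def test_affinity_parsed_from_result_table(self):
        assert parse_engine_affinity(ENGINE_OUTPUT) == pytest.approx(-9.4)

    def test_unparseable_output_rejected(self):
        with pytest.raises(ValueError):
            parse_engine_affinity("engine exploded")

    def test_missing_engine_degrades_gracefully(self):
        adapter = DockingAdapter(DockingConfig(engine="no-such-docking-engine"))
        table = frequency_rank(["CCO", "CCN"])
        out = adapter.dock_designs(table)
        assert out.dock_alpha.isna().all()
        assert out.dock_aggregate.isna().all()
        # frequency ranking untouched
        assert list(out.freq_rank) == list(table.freq_rank)

    def test_missing_engine_redock_raises(self):
        adapter = DockingAdapter(DockingConfig(engine="no-such-docking-engine"))
        with pytest.raises(DockingUnavailableError):
            adapter.redock()

    def test_fake_engine_scores_flow_through(self, tmp_path):
        """A stand-in engine executable (synthetic, prints a canned result
        table) exercises the invocation, parsing and aggregation path."""
        fake = tmp_path / "smina"
        fake.write_text(
            "#!/bin/sh\n"
            "echo 'mode |   affinity | dist from best mode'\n"
            "echo '-----+------------+----------'\n"
            "echo '1       -10.0       0.000      0.000'\n"
        )
        fake.chmod(fake.stat().st_mode | stat.S_IEXEC)
        receptor = tmp_path / "receptor.pdb"
        receptor.write_text("HEADER synthetic receptor\n")
        ligand = tmp_path / "crystal.sdf"
        ligand.write_text("synthetic\n")
        old_path = os.environ["PATH"]
        os.environ["PATH"] = f"{tmp_path}{os.pathsep}{old_path}"
        try:
            adapter = DockingAdapter(
                DockingConfig(),
                {"alpha": receptor, "beta": receptor},
                {"alpha": ligand, "beta": ligand},
            )
            table = frequency_rank(["CCO"])
            out = adapter.dock_designs(table)
        finally:
            os.environ["PATH"] = old_path
        assert out.loc[0, "dock_alpha"] == pytest.approx(-10.0)
        assert out.loc[0, "dock_beta"] == pytest.approx(-10.0)
        assert out.loc[0, "dock_aggregate"] == pytest.approx(-10.0)


class TestRankTableIO:
    def test_written_columns_and_round_trip(self, tmp_path):
        table = similarity_prioritize(frequency_rank(["CCO", "CCN"]), ["CCO"], top_n=5)
        path = tmp_path / "ranks.tsv"
        write_rank_table(table, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["smiles", "frequency", "freq_rank", "nn_similarity", "sim_rank", "novel"]
        assert list(back.smiles) == list(table.smiles)
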