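"""Design prioritization: sampling frequency, template similarity, docking.

The sampling frequency of a canonical molecule across all draws serves as an
intrinsic quality measure; the most template-like designs are additionally
scored by docking against both receptor subtypes (LXRα 3IPQ, LXRβ 5JY3 in
the production setting), aggregated as the geometric mean of the two
affinities. The docking engine (smina) is wrapped, not re-implemented, and
the pipeline degrades gracefully when it is absent.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import bulk_tanimoto, fingerprint_matrix, morgan_fp, standardize

logger = logging.getLogger(__name__)


class AllInvalidError(ValueError):
    """Every sampled string failed to parse as a molecule."""


class DockingUnavailableError(RuntimeError):
    """The external docking engine is not installed or not runnable."""


def frequency_rank(samples: Sequence[str], training_corpora: Sequence[Sequence[str]] = ()) -> pd.DataFrame:
    """Group raw sampled strings by canonical SMILES and rank by frequency.

    Invalid SMILES are dropped (their count is stored in ``df.attrs
    ['n_invalid']``); ties in frequency are broken by lexicographic canonical
    SMILES. Designs whose canonical form occurs in any training corpus are
    flagged non-novel.

    Returns a DataFrame with columns smiles, frequency, freq_rank, novel.
    """
    if len(samples) == 0:
        raise AllInvalidError("empty sample multiset")
    counts: dict[str, int] = {}
    n_invalid = 0
    for s in samples:
        rec = standardize(s, strict=False)
        if not rec.is_valid:
            n_invalid += 1
            continue
        counts[rec.canonical_smiles] = counts.get(rec.canonical_smiles, 0) + 1
    if not counts:
        raise AllInvalidError(f"all {len(samples)} sampled strings are invalid SMILES")
    known = set()
    for corpus in training_corpora:
        for smi in corpus:
            rec = standardize(smi, strict=False)
            if rec.is_valid:
                known.add(rec.canonical_smiles)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(
        {
            "smiles": [s for s, _ in rows],
            "frequency": [c for _, c in rows],
            "freq_rank": np.arange(1, len(rows) + 1),
            "novel": [s not in known for s, _ in rows],
        }
    )
    df.attrs["n_invalid"] = n_invalid
    return df


def similarity_prioritize(rank_table: pd.DataFrame, template_set: Sequence[str], top_n: int = 1000) -> pd.DataFrame:
    """Annotate each design with its nearest-neighbor Tanimoto to the
    template set and keep the ``top_n`` most similar designs."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if len(template_set) == 0:
        raise ValueError("template set must be non-empty")
    ref = fingerprint_matrix([standardize(s).canonical_smiles for s in template_set])
    sims = np.array(
        [float(np.nanmax(bulk_tanimoto(morgan_fp(s).bits, ref))) for s in rank_table["smiles"]]
    )
    out = rank_table.copy()
    out["nn_similarity"] = sims
    out = out.sort_values(
        ["nn_similarity", "smiles"], ascending=[False, True], kind="mergesort"
    ).head(top_n)
    out["sim_rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def aggregate_dock(score_alpha: float, score_beta: float) -> float:
    """Geometric-mean aggregate of two docking affinities.

    Affinities are negative (more negative = better); the aggregate of two
    negative scores is the negated geometric mean of their magnitudes,
    −sqrt(|a|·|b|). Mixed-sign inputs have no defined aggregate and raise.
    """
    if score_alpha * score_beta < 0:
        raise ValueError(
            f"mixed-sign docking scores ({score_alpha}, {score_beta}): aggregate undefined"
        )
    mag = float(np.sqrt(abs(score_alpha) * abs(score_beta)))
    return -mag if score_alpha <= 0 else mag


@dataclass(frozen=True)
class DockingConfig:
    """Engine settings: autobox around the bound ligand with box size 8,
    exhaustiveness 16; redocking runs ``repeats`` independent repeats."""

    receptor_alpha: str = "3IPQ"
    receptor_beta: str = "5JY3"
    autobox_size: int = 8
    exhaustiveness: int = 16
    repeats: int = 5
    engine: str = "smina"

    def __post_init__(self):
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")


_AFFINITY_RE = re.compile(r"^\s*1\s+(-?\d+\.\d+)", re.MULTILINE)


def parse_engine_affinity(stdout: str) -> float:
    """Best-pose affinity (mode 1) from the engine's result table."""
    m = _AFFINITY_RE.search(stdout)
    if m is None:
        raise ValueError("no docking result table in engine output")
    return float(m.group(1))


def _prepare_ligand_sdf(smiles: str, path: Path, seed: int = 0xF00D) -> None:
    """Embed a single lowest-energy conformer with hydrogens for docking."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot prepare invalid SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError(f"3D embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol)
    with Chem.SDWriter(str(path)) as w:
        w.write(mol)


class DockingAdapter:
    """Thin wrapper around the smina command line.

    ``receptor_files``/``crystal_ligand_files`` map receptor labels (e.g.
    "alpha"/"beta") to prepared PDB(QT) receptor structures and their
    cocrystallized ligand files; the grid is autoboxed around the crystal
    ligand.
    """

    def __init__(self, config: DockingConfig, receptor_files: dict[str, Path] | None = None,
                 crystal_ligand_files: dict[str, Path] | None = None):
        self.config = config
        self.receptor_files = receptor_files or {}
        self.crystal_ligand_files = crystal_ligand_files or {}

    def engine_path(self) -> str | None:
        return shutil.which(self.config.engine)

    def available(self) -> bool:
        return self.engine_path() is not None and bool(self.receptor_files)

    def _run_engine(self, receptor: Path, ligand: Path, autobox_ligand: Path, seed: int) -> float:
        cmd = [
            self.config.engine,
            "--receptor", str(receptor),
            "--ligand", str(ligand),
            "--autobox_ligand", str(autobox_ligand),
            "--autobox_add", str(self.config.autobox_size),
            "--exhaustiveness", str(self.config.exhaustiveness),
            "--seed", str(seed),
            "--out", str(ligand.with_suffix(".docked.sdf")),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"engine failed: {proc.stderr[-500:]}")
        return parse_engine_affinity(proc.stdout)

    def dock_designs(self, designs: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
        """Dock each design against both receptors and aggregate.

        When the engine (or receptor input) is missing, the docking columns
        are added as NaN and a diagnostic is logged: frequency and similarity
        ranks are unaffected. Per-molecule engine failures are recorded and
        exclude the molecule from the docking ranking only.
        """
        out = designs.copy()
        out["dock_alpha"] = np.nan
        out["dock_beta"] = np.nan
        out["dock_aggregate"] = np.nan
        if not self.available():
            logger.warning(
                "docking skipped: engine %r or receptor structures unavailable", self.config.engine
            )
            return out
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            for i, smi in enumerate(out["smiles"]):
                try:
                    lig = tmp / f"design_{i}.sdf"
                    _prepare_ligand_sdf(smi, lig)
                    scores = {}
                    for label in ("alpha", "beta"):
                        scores[label] = self._run_engine(
                            self.receptor_files[label], lig, self.crystal_ligand_files[label], seed
                        )
                    out.loc[out.index[i], ["dock_alpha", "dock_beta"]] = (scores["alpha"], scores["beta"])
                    out.loc[out.index[i], "dock_aggregate"] = aggregate_dock(scores["alpha"], scores["beta"])
                except Exception as exc:  # engine failure: exclude from docking rank only
                    logger.warning("docking failed for %s: %s", smi, exc)
        return out

    def redock(self, seed: int = 0) -> pd.DataFrame:
        """Re-dock each receptor's cocrystallized ligand ``repeats`` times;
        report mean ± sd of the best-pose score and of the heavy-atom
        symmetry-aware RMSD to the crystal pose."""
        if not self.available():
            raise DockingUnavailableError(
                f"docking engine {self.config.engine!r} is not installed or receptors missing"
            )
        from rdkit.Chem import rdMolAlign

        rows = []
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            for label in ("alpha", "beta"):
                crystal = self.crystal_ligand_files[label]
                ref = Chem.MolFromMolFile(str(crystal), removeHs=True)
                scores, rmsds = [], []
                for r in range(self.config.repeats):
                    lig = tmp / f"redock_{label}_{r}.sdf"
                    shutil.copy(crystal, lig)
                    score = self._run_engine(self.receptor_files[label], lig, crystal, seed + r)
                    posed = Chem.MolFromMolFile(str(lig.with_suffix(".docked.sdf")), removeHs=True)
                    scores.append(score)
                    rmsds.append(rdMolAlign.CalcRMS(posed, ref))
                rows.append(
                    {
                        "receptor": label,
                        "score_mean": float(np.mean(scores)),
                        "score_sd": float(np.std(scores)),
                        "rmsd_mean": float(np.mean(rmsds)),
                        "rmsd_sd": float(np.std(rmsds)),
                    }
                )
        return pd.DataFrame(rows)


def write_rank_table(df: pd.DataFrame, path) -> None:
    """Persist a rank table as TSV with the standard column order."""
    cols = [c for c in ["smiles", "frequency", "freq_rank", "nn_similarity", "sim_rank",
                        "dock_alpha", "dock_beta", "dock_aggregate", "novel"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)
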