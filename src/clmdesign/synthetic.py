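"""Desk-scale synthetic SMILES corpora with the structure the pipeline assumes.

Real chemical-language-model studies pretrain on a large diverse corpus
(hundreds of thousands of ChEMBL molecules), fine-tune on a mid-size
target-focused set drawn from a handful of ligand chemotypes, and finally on
a small template set spanning several of those chemotypes. This module
emulates that three-corpus structure at desk scale with combinatorial
scaffold families: a core with attachment points enumerated against
substituent pools. Families are built from drug-like cores (aryl amides,
biaryl sulfones, arylpiperazines and friends) so token statistics resemble
real drug-like SMILES.

The key statistical property the pipeline relies on — molecules within a
family are mutually more similar (Morgan/Tanimoto) than molecules across
families — is an emergent consequence of the shared cores and is asserted by
the test suite on every generated study.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, build_corpus, standardize

#: substituent pools are written so that prefixing an attachment dummy
#: ("[*:k]") yields a valid fragment SMILES.
_SMALL_GROUPS = (
    "C", "CC", "CCC", "C(C)C", "OC", "OCC", "F", "Cl", "Br",
    "C(F)(F)F", "OC(F)(F)F", "C#N", "CO", "N(C)C", "S(C)(=O)=O",
)
_N_GROUPS = ("C", "CC", "CCO", "C(C)C", "Cc1ccccc1", "CCN(C)C", "CCOC", "C(=O)C")
_ARYL_GROUPS = ("c1ccccc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccc(C)cc1", "c1ccc(OC)cc1", "c1ccncc1")


@dataclass(frozen=True)
class ScaffoldFamily:
    """A combinatorial family: a core with numbered attachment points and a
    substituent pool per point."""

    family_id: str
    core_smiles: str  # contains [*:1] .. [*:k]
    substituents: tuple[tuple[str, ...], ...]  # pool per attachment point

    @property
    def n_sites(self) -> int:
        return len(self.substituents)

    @property
    def capacity(self) -> int:
        """Upper bound on distinct products (combinations of pool picks)."""
        out = 1
        for pool in self.substituents:
            out *= len(pool)
        return out


class FamilyCapacityError(ValueError):
    """The family cannot yield the requested number of distinct products."""


def _assemble(family: ScaffoldFamily, picks: Sequence[str]) -> str:
    mol = Chem.MolFromSmiles(family.core_smiles)
    if mol is None:
        raise ValueError(f"invalid core SMILES: {family.core_smiles!r}")
    for site, group in enumerate(picks, start=1):
        frag = Chem.MolFromSmiles(f"[*:{site}]{group}")
        if frag is None:
            raise ValueError(f"invalid substituent {group!r}")
        mol = Chem.CombineMols(mol, frag)
    product = Chem.molzip(mol)
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


def enumerate_family(family: ScaffoldFamily, n: int, seed: int = 0) -> list[MoleculeRecord]:
    """Draw ``n`` distinct valid members of a family, deterministic in seed.

    All pool combinations are enumerated, assembled, canonicalized and
    deduplicated; ``n`` products are then sampled without replacement. Raises
    :class:`FamilyCapacityError` (stating the achievable maximum) when the
    family cannot produce ``n`` distinct molecules.
    """
    if family.n_sites < 1:
        raise ValueError("family core needs at least one attachment point")
    if n == 0:
        return []
    seen: set[str] = set()
    products: list[str] = []
    for picks in itertools.product(*family.substituents):
        smi = _assemble(family, picks)
        rec = standardize(smi)
        if rec.canonical_smiles not in seen and len(rec.canonical_smiles) <= 140:
            seen.add(rec.canonical_smiles)
            products.append(rec.canonical_smiles)
    if n > len(products):
        raise FamilyCapacityError(
            f"family {family.family_id!r} yields at most {len(products)} distinct molecules, requested {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(products), size=n, replace=False)
    return [
        MoleculeRecord(products[i], products[i], f"{family.family_id}_{j}")
        for j, i in enumerate(sorted(chosen))
    ]


# ---------------------------------------------------------------------------
# Default family library

def default_pretrain_families() -> list[ScaffoldFamily]:
    """Ten diverse drug-like chemotypes for the pretraining corpus."""
    return [
        ScaffoldFamily("benzanilide", "O=C(Nc1ccc([*:1])cc1)c1ccc([*:2])cc1", (_SMALL_GROUPS, _SMALL_GROUPS)),
        ScaffoldFamily("indole", "[*:1]c1ccc2c(c1)c([*:2])c[nH]2", (_SMALL_GROUPS, _SMALL_GROUPS)),
        ScaffoldFamily("benzimidazole", "[*:1]c1ccc2nc([*:2])[nH]c2c1", (_SMALL_GROUPS, _ARYL_GROUPS)),
        ScaffoldFamily("quinoline", "[*:1]c1ccc2ncc([*:2])cc2c1", (_SMALL_GROUPS, _SMALL_GROUPS)),
        ScaffoldFamily("pyridinamide", "O=C(N[*:1])c1ccc([*:2])nc1", (_N_GROUPS, _SMALL_GROUPS)),
        ScaffoldFamily("benzofuran", "[*:1]c1ccc2cc([*:2])oc2c1", (_SMALL_GROUPS, _SMALL_GROUPS)),
        ScaffoldFamily("diarylurea", "O=C(Nc1ccc([*:1])cc1)N([*:2])c1ccccc1", (_SMALL_GROUPS, _N_GROUPS)),
        ScaffoldFamily("benzenesulfonamide", "O=S(=O)(N([*:1])C)c1ccc([*:2])cc1", (_N_GROUPS, _SMALL_GROUPS)),
        ScaffoldFamily("phenoxyacetamide", "O=C(N([*:1])C)COc1ccc([*:2])cc1", (_N_GROUPS, _SMALL_GROUPS)),
        ScaffoldFamily("morpholinoaryl", "[*:1]c1ccc(N2CCOCC2)cc1[*:2]", (_SMALL_GROUPS, _SMALL_GROUPS)),
    ]


def default_finetune_families() -> list[ScaffoldFamily]:
    """Three target-focused chemotypes for the fine-tuning corpora, echoing
    nuclear-receptor ligand series (aryl amide, biaryl methylsulfone,
    arylpiperazine)."""
    return [
        ScaffoldFamily(
            "ft_arylamide",
            "CCN(C(=O)c1ccc([*:1])cc1)c1ccc([*:2])cc1",
            (_SMALL_GROUPS, _SMALL_GROUPS),
        ),
        ScaffoldFamily(
            "ft_biarylsulfone",
            "CS(=O)(=O)c1cccc(-c2ccc([*:1])cc2[*:2])c1",
            (_SMALL_GROUPS, _SMALL_GROUPS),
        ),
        ScaffoldFamily(
            "ft_arylpiperazine",
            "[*:1]c1ccc(N2CCN([*:2])CC2)c(C(F)(F)F)c1",
            (_SMALL_GROUPS, _N_GROUPS),
        ),
    ]


@dataclass
class SyntheticStudy:
    """Three corpora with per-molecule family labels and the study seed."""

    pretrain: list[MoleculeRecord]
    finetune_1: list[MoleculeRecord]
    finetune_2: list[MoleculeRecord]
    families: dict[str, str]  # canonical smiles -> family id
    seed: int

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, corpus in [
            ("pretrain", self.pretrain),
            ("finetune_1", self.finetune_1),
            ("finetune_2", self.finetune_2),
        ]:
            with open(directory / f"{name}.smi", "w") as fh:
                for rec in corpus:
                    fh.write(f"{rec.canonical_smiles}\t{rec.source_id}\n")
        with open(directory / "manifest.tsv", "w") as fh:
            fh.write("id\tsmiles\tfamily\tsplit\n")
            for split, corpus in [
                ("pretrain", self.pretrain),
                ("finetune_1", self.finetune_1),
                ("finetune_2", self.finetune_2),
            ]:
                for rec in corpus:
                    fam = self.families.get(rec.canonical_smiles, "?")
                    fh.write(f"{rec.source_id}\t{rec.canonical_smiles}\t{fam}\t{split}\n")


def make_study(
    pretrain_n: int = 2000,
    finetune1_n: int = 120,
    finetune2_n: int = 10,
    seed: int = 7,
    pretrain_families: Sequence[ScaffoldFamily] | None = None,
    finetune_families: Sequence[ScaffoldFamily] | None = None,
) -> SyntheticStudy:
    """Generate the three-corpus study.

    The pretraining corpus is drawn evenly from the diverse families; the
    mid-size fine-tuning set I evenly from the target-focused families; the
    template set II is a subset of set I spanning at least two families (so
    downstream scaffold-fusion probes are meaningful). Set II never overlaps
    the pretraining corpus. All corpora pass the standard corpus filters
    unchanged and all randomness derives from ``seed``.
    """
    pre_fams = list(pretrain_families or default_pretrain_families())
    ft_fams = list(finetune_families or default_finetune_families())
    if finetune2_n > finetune1_n:
        raise ValueError("template set cannot exceed fine-tuning set I")
    if finetune2_n < 2 or len(ft_fams) < 2:
        raise ValueError("template set needs >= 2 molecules from >= 2 families")

    families: dict[str, str] = {}
    rng = np.random.default_rng(seed)

    def draw(fams: Sequence[ScaffoldFamily], total: int, allow_short: bool = False) -> list[MoleculeRecord]:
        per = int(np.ceil(total / len(fams)))
        out: list[MoleculeRecord] = []
        for fam in fams:
            want = min(per, total - len(out))
            if want <= 0:
                break
            fam_seed = int(rng.integers(2**31))
            try:
                recs = enumerate_family(fam, want, seed=fam_seed)
            except FamilyCapacityError:
                if not allow_short:
                    raise
                recs = enumerate_family(fam, 0, seed=fam_seed)  # no-op, keep determinism
            for r in recs:
                families.setdefault(r.canonical_smiles, fam.family_id)
            out.extend(recs)
        return out

    finetune_1 = build_corpus(draw(ft_fams, finetune1_n))
    if len(finetune_1) < finetune1_n:
        raise ValueError("fine-tuning families yielded fewer distinct molecules than requested")

    # template set: stratified subset of set I over all fine-tune families
    by_family: dict[str, list[MoleculeRecord]] = {}
    for rec in finetune_1:
        by_family.setdefault(families[rec.canonical_smiles], []).append(rec)
    finetune_2: list[MoleculeRecord] = []
    fam_cycle = itertools.cycle(sorted(by_family))
    picked: dict[str, int] = {f: 0 for f in by_family}
    while len(finetune_2) < finetune2_n:
        f = next(fam_cycle)
        pool = by_family[f]
        if picked[f] < len(pool):
            finetune_2.append(pool[picked[f]])
            picked[f] += 1

    pretrain = draw(pre_fams, pretrain_n, allow_short=True)
    ft2_smiles = {r.canonical_smiles for r in finetune_2}
    pretrain = [r for r in pretrain if r.canonical_smiles not in ft2_smiles]
    pretrain = build_corpus(pretrain)
    if len(pretrain) < pretrain_n:
        # top up from the first families that still have capacity
        deficit = pretrain_n - len(pretrain)
        have = {r.canonical_smiles for r in pretrain}
        for fam in pre_fams:
            if deficit <= 0:
                break
            extra = enumerate_family(fam, min(fam.capacity, 400), seed=seed + 1)
            for r in extra:
                if deficit <= 0:
                    break
                if r.canonical_smiles not in have and r.canonical_smiles not in ft2_smiles:
                    have.add(r.canonical_smiles)
                    families.setdefault(r.canonical_smiles, fam.family_id)
                    pretrain.append(r)
                    deficit -= 1
        if deficit > 0:
            raise ValueError(f"pretraining families cannot yield {pretrain_n} distinct molecules")

    return SyntheticStudy(pretrain, finetune_1, finetune_2, families, seed)
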