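"""SMILES standardization, corpus construction, and fingerprint similarity.

Molecules are standardized the way chemical-language-model corpora are
conventionally prepared: isotopes cleared, stereochemistry stripped, the
largest organic fragment kept (salt/counter-ion removal), and the result
emitted as RDKit canonical SMILES. Corpora are deduplicated on the canonical
form and capped at 140 characters, the longest string the downstream sequence
model will decode.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: maximum canonical-SMILES length admitted to any corpus
MAX_SMILES_LEN = 140

FP_RADIUS = 2
FP_NBITS = 2048

_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_NBITS)


class EmptyCorpusError(ValueError):
    """Raised when filtering/deduplication leaves no molecules."""


class StandardizationError(ValueError):
    """Raised in single-molecule mode for unparseable SMILES."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule with provenance.

    ``canonical_smiles`` is empty when ``is_valid`` is False.
    """

    raw_smiles: str
    canonical_smiles: str
    source_id: str = ""
    is_valid: bool = True


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with most heavy atoms; prefer carbon-containing
    fragments; ties broken by lexicographically smallest canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]

    def key(f: Chem.Mol):
        has_c = any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        smi = Chem.MolToSmiles(f)
        return (has_c, f.GetNumHeavyAtoms(), [-ord(c) for c in smi])

    return max(frags, key=key)


def standardize(raw_smiles: str, source_id: str = "", strict: bool = True) -> MoleculeRecord:
    """Standardize one SMILES string into a :class:`MoleculeRecord`.

    Removes isotopic labels and stereochemistry, keeps the largest organic
    fragment, and canonicalizes. With ``strict=True`` an unparseable input
    raises :class:`StandardizationError`; bulk loaders pass ``strict=False``
    and receive a record flagged invalid instead.
    """
    if not raw_smiles or not raw_smiles.strip():
        if strict:
            raise StandardizationError("empty SMILES string")
        return MoleculeRecord(raw_smiles, "", source_id, is_valid=False)
    mol = Chem.MolFromSmiles(raw_smiles.strip())
    if mol is None:
        if strict:
            raise StandardizationError(f"unparseable SMILES: {raw_smiles!r}")
        return MoleculeRecord(raw_smiles, "", source_id, is_valid=False)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    Chem.RemoveStereochemistry(mol)
    mol = _largest_organic_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        if strict:
            raise StandardizationError(f"fragment of {raw_smiles!r} failed sanitization")
        return MoleculeRecord(raw_smiles, "", source_id, is_valid=False)
    return MoleculeRecord(raw_smiles, Chem.MolToSmiles(mol), source_id, is_valid=True)


def standardize_all(smiles: Iterable[str], ids: Iterable[str] | None = None) -> list[MoleculeRecord]:
    """Bulk standardization: invalid inputs are logged and flagged, never raised."""
    smiles = list(smiles)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(smiles))]
    records = [standardize(s, i, strict=False) for s, i in zip(smiles, ids)]
    n_bad = sum(not r.is_valid for r in records)
    if n_bad:
        logger.warning("standardize_all: %d of %d SMILES invalid, skipped", n_bad, len(records))
    return records


def build_corpus(records: Sequence[MoleculeRecord], max_len: int = MAX_SMILES_LEN) -> list[MoleculeRecord]:
    """Deduplicate standardized records on canonical SMILES and apply the
    length cap. Keeps the first occurrence of each canonical form, in input
    order. Raises :class:`EmptyCorpusError` when nothing survives."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if not rec.is_valid or not rec.canonical_smiles:
            continue
        if len(rec.canonical_smiles) > max_len:
            continue
        if rec.canonical_smiles in seen:
            continue
        seen.add(rec.canonical_smiles)
        out.append(rec)
    if not out:
        raise EmptyCorpusError("no valid molecules remain after filtering")
    return out


@dataclass(frozen=True)
class Fingerprint:
    """Morgan (ECFP-like) binary fingerprint, radius 2 hashed to 2048 bits."""

    bits: np.ndarray  # uint8 0/1 vector, length 2048
    radius: int = FP_RADIUS

    def __post_init__(self):
        if self.bits.shape != (FP_NBITS,):
            raise ValueError(f"fingerprint must have exactly {FP_NBITS} bits")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def morgan_fp(mol: MoleculeRecord | str) -> Fingerprint:
    """Morgan fingerprint (radius 2, 2048-bit) of a valid molecule."""
    smi = mol.canonical_smiles if isinstance(mol, MoleculeRecord) else mol
    if isinstance(mol, MoleculeRecord) and not mol.is_valid:
        raise ValueError("cannot fingerprint an invalid molecule")
    m = Chem.MolFromSmiles(smi)
    if m is None:
        raise ValueError(f"cannot fingerprint unparseable SMILES: {smi!r}")
    arr = np.zeros(FP_NBITS, dtype=np.uint8)
    on = _fpgen.GetFingerprint(m).GetOnBits()
    arr[list(on)] = 1
    return Fingerprint(arr)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a∧b| / |a∨b| of two fingerprints.

    Undefined (raises) when both fingerprints are all-zero.
    """
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        raise ValueError("Tanimoto similarity undefined for two empty fingerprints")
    return inter / union


def fingerprint_matrix(smiles: Sequence[str]) -> np.ndarray:
    """Stack Morgan fingerprints of many molecules into an (n, 2048) uint8 array."""
    return np.stack([morgan_fp(s).bits for s in smiles])


def bulk_tanimoto(query_fp: np.ndarray, ref_matrix: np.ndarray) -> np.ndarray:
    """Tanimoto of one fingerprint row against every row of a matrix."""
    inter = (ref_matrix & query_fp).sum(axis=1).astype(np.float64)
    union = (ref_matrix | query_fp).sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore"):
        sims = np.where(union > 0, inter / union, np.nan)
    return sims


def nearest_neighbor_sim(
    query: MoleculeRecord | str, reference_set: Sequence[MoleculeRecord | str]
) -> tuple[float, str]:
    """Maximum Tanimoto of ``query`` over a reference corpus.

    Returns ``(similarity, reference_identifier)`` where the identifier is the
    matched molecule's source_id (or its SMILES for plain strings). Ties are
    broken by first occurrence.
    """
    if len(reference_set) == 0:
        raise ValueError("reference set must be non-empty")
    qfp = morgan_fp(query)
    best_sim, best_id = -1.0, ""
    for ref in reference_set:
        sim = tanimoto(qfp, morgan_fp(ref))
        if sim > best_sim:
            best_sim = sim
            if isinstance(ref, MoleculeRecord):
                best_id = ref.source_id or ref.canonical_smiles
            else:
                best_id = ref
    return best_sim, best_id


def nearest_neighbor_sims(queries: Sequence[str], reference: Sequence[str]) -> np.ndarray:
    """Vectorized nearest-neighbor Tanimoto of each query to a reference corpus."""
    if len(reference) == 0:
        raise ValueError("reference set must be non-empty")
    ref = fingerprint_matrix(reference)
    out = np.empty(len(queries))
    for i, q in enumerate(queries):
        out[i] = np.nanmax(bulk_tanimoto(morgan_fp(q).bits, ref))
    return out


# ---------------------------------------------------------------------------
# File IO: .smi (one SMILES per line, optional whitespace-separated id) and
# CSV with a named SMILES column.

def read_smi(path: str | Path) -> list[MoleculeRecord]:
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smi = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"line{i + 1}"
        records.append(standardize(smi, mol_id, strict=False))
    return records


def read_csv_smiles(path: str | Path, smiles_column: str = "smiles", id_column: str | None = None) -> list[MoleculeRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or smiles_column not in reader.fieldnames:
            raise ValueError(f"CSV has no column named {smiles_column!r}")
        for i, row in enumerate(reader):
            mol_id = row[id_column] if id_column else f"row{i + 1}"
            records.append(standardize(row[smiles_column], mol_id, strict=False))
    return records


def write_smi(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.is_valid:
                fh.write(f"{rec.canonical_smiles}\t{rec.source_id}\n")
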