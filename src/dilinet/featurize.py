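"""SMILES curation and Morgan-fingerprint featurization.

Input tables carry one molecule per row (``smiles``, binary ``label``,
optional ``id``). Molecules are canonicalized, deduplicated on canonical
SMILES (records whose duplicates disagree on the label are dropped
entirely), and featurized as 2,048-bit radius-2 Morgan fingerprints. The
network consumes a 128-dimensional binary input obtained by OR-folding the
fingerprint modulo 128; baselines consume the raw 2,048 bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

N_BITS = 2048
RADIUS = 2
FOLDED_DIM = 128

__all__ = [
    "Compound",
    "FeaturizationError",
    "canonicalize_smiles",
    "morgan_fingerprint",
    "fold_to_input",
    "deduplicate",
    "load_dataset",
    "featurize_compounds",
    "N_BITS",
    "RADIUS",
    "FOLDED_DIM",
]


class FeaturizationError(ValueError):
    """Raised when a record cannot be parsed or featurized."""


@dataclass(frozen=True)
class Compound:
    """One molecule: opaque identifier, SMILES, binary DILI label (1 = positive)."""

    id: str
    smiles: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise FeaturizationError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")


def _mol_from_smiles(smiles: str, record_id: str | None = None) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise FeaturizationError(f"record {record_id!r}: empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f"record {record_id!r}: " if record_id is not None else ""
        raise FeaturizationError(f"{where}unparseable SMILES {smiles!r}")
    return mol


def canonicalize_smiles(smiles: str, record_id: str | None = None) -> str:
    """Canonical SMILES; any two spellings of one molecular graph map to the same string."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles, record_id))


_FP_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS, fpSize=N_BITS)


def morgan_fingerprint(smiles: str, radius: int = RADIUS, n_bits: int = N_BITS,
                       record_id: str | None = None) -> np.ndarray:
    """Binary circular (Morgan/ECFP-style) fingerprint of the molecule.

    Deterministic and spelling-invariant: any SMILES of the same molecule
    yields a bitwise-identical vector.
    """
    mol = _mol_from_smiles(smiles, record_id)
    if radius == RADIUS and n_bits == N_BITS:
        gen = _FP_GENERATOR
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def fold_to_input(fp: np.ndarray) -> np.ndarray:
    """OR-fold a 2,048-bit fingerprint to the 128-dim network input.

    Position ``j`` of the output is the OR of fingerprint bits
    ``j, j+128, ..., j+1920``. Returned as float 0.0/1.0, the form the
    network consumes.
    """
    fp = np.asarray(fp)
    if fp.shape[-1] != N_BITS:
        raise FeaturizationError(f"expected {N_BITS} fingerprint bits, got {fp.shape[-1]}")
    folded = fp.reshape(*fp.shape[:-1], N_BITS // FOLDED_DIM, FOLDED_DIM).any(axis=-2)
    return folded.astype(np.float64)


def deduplicate(compounds: list[Compound]) -> list[Compound]:
    """One record per canonical SMILES, first occurrence kept.

    Duplicate groups whose labels conflict are removed entirely: without
    provenance there is no principled way to pick a side.
    """
    order: list[str] = []
    first: dict[str, Compound] = {}
    labels: dict[str, set[int]] = {}
    for comp in compounds:
        key = canonicalize_smiles(comp.smiles, comp.id)
        if key not in first:
            order.append(key)
            first[key] = comp
        labels.setdefault(key, set()).add(comp.label)
    kept = [first[key] for key in order if len(labels[key]) == 1]
    n_conflicts = sum(1 for key in order if len(labels[key]) > 1)
    logger.info("deduplicate: %d records -> %d unique (%d conflicting molecules dropped)",
                len(compounds), len(kept), n_conflicts)
    return kept


def load_dataset(path) -> list[Compound]:
    """Read a ``smiles,label`` CSV (optional ``id``) into validated compounds."""
    try:
        frame = pd.read_csv(path, dtype={"smiles": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FeaturizationError(f"cannot read dataset {path}: {exc}") from exc
    missing = {"smiles", "label"} - set(frame.columns)
    if missing:
        raise FeaturizationError(f"dataset {path} lacks required column(s): {sorted(missing)}")
    if "id" not in frame.columns:
        frame = frame.assign(id=[str(i) for i in range(len(frame))])
    compounds: list[Compound] = []
    for row in frame.itertuples(index=False):
        label = row.label
        if not (isinstance(label, (int, np.integer)) or float(label).is_integer()) or int(label) not in (0, 1):
            raise FeaturizationError(f"record {row.id!r}: non-binary label {label!r}")
        _mol_from_smiles(row.smiles, str(row.id))
        compounds.append(Compound(id=str(row.id), smiles=row.smiles, label=int(label)))
    n_pos = sum(c.label for c in compounds)
    logger.info("loaded %d compounds from %s: %d positive, %d negative",
                len(compounds), path, n_pos, len(compounds) - n_pos)
    return compounds


def featurize_compounds(compounds: list[Compound], mode: str = "fold"):
    """Featurize a compound list into ``(X, y)``.

    mode "fold": X is (n, 128) float OR-folded bits (network input);
    mode "raw": X is (n, 2048) uint8 fingerprint bits (baseline input).
    """
    if mode not in ("fold", "raw"):
        raise ValueError("mode must be 'fold' or 'raw'")
    fps = np.stack([morgan_fingerprint(c.smiles, record_id=c.id) for c in compounds])
    y = np.array([c.label for c in compounds], dtype=int)
    if mode == "raw":
        return fps, y
    return fold_to_input(fps), y
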