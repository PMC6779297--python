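"""Circular Morgan fingerprints and Tanimoto similarity.

Chemical structures are encoded as hashed, folded circular Morgan
fingerprints (the RDKit equivalent of ECFP; ECFP diameter = 2 x radius, so
radius 2 corresponds to ECFP4 and radius 8 to ECFP16).  Similarity between
two compounds is the Tanimoto coefficient over the fingerprint bit sets,

    Tc(A, B) = |A & B| / |A | B|,

and the associated distance is 1 - Tc.  This structure space underlies both
the similarity-based predictor and the clustering used for class balancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import DimensionError, InvalidStructureError

__all__ = [
    "Fingerprint",
    "morgan_fingerprint",
    "tanimoto",
    "tanimoto_matrix",
    "tanimoto_distance_matrix",
    "bulk_tanimoto",
    "read_smiles",
    "write_smiles",
]

DEFAULT_RADIUS = 8
DEFAULT_N_BITS = 1024


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary substructure vector for one compound.

    Parameters
    ----------
    bits
        uint8 vector of 0/1 of length ``n_bits``.
    radius
        Morgan radius the fingerprint was computed at.
    n_bits
        Folded length of the bit vector.
    """

    bits: np.ndarray = field(repr=False)
    radius: int
    n_bits: int

    def __post_init__(self) -> None:
        if self.bits.shape != (self.n_bits,):
            raise DimensionError(
                f"bit vector has shape {self.bits.shape}, expected ({self.n_bits},)"
            )

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"unparseable SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    """Hashed-folded circular Morgan fingerprint of a molecule.

    Deterministic: the same (SMILES, radius, n_bits) always yields the same
    bits, and any SMILES spelling of the same molecule gives identical bits
    because hashing operates on the molecular graph.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if n_bits < 1 or n_bits & (n_bits - 1):
        raise ValueError(f"n_bits must be a power of two, got {n_bits}")
    mol = _parse(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = gen.GetFingerprintAsNumPy(mol).astype(np.uint8)
    return Fingerprint(bits=bits, radius=radius, n_bits=n_bits)


def _check_compatible(a: Fingerprint, b: Fingerprint) -> None:
    if a.n_bits != b.n_bits:
        raise DimensionError(f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient in [0, 1]; 0 by convention when both are empty."""
    _check_compatible(a, b)
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = a.popcount + b.popcount - inter
    if union == 0:
        return 0.0
    return inter / union


def _stack(fps: list[Fingerprint]) -> np.ndarray:
    n_bits = fps[0].n_bits
    for fp in fps[1:]:
        if fp.n_bits != n_bits:
            raise DimensionError("fingerprints have mixed lengths")
    return np.stack([fp.bits for fp in fps]).astype(np.int64)


def bulk_tanimoto(query: Fingerprint, refs: list[Fingerprint]) -> np.ndarray:
    """Tanimoto of one query against a list of references (vectorized)."""
    if not refs:
        return np.empty(0)
    mat = _stack(refs)
    _check_compatible(query, refs[0])
    q = query.bits.astype(np.int64)
    inter = mat @ q
    union = mat.sum(axis=1) + q.sum() - inter
    out = np.zeros(len(refs))
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def tanimoto_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """All-pairs Tanimoto similarity matrix (symmetric, unit diagonal)."""
    mat = _stack(fps)
    inter = mat @ mat.T
    pop = mat.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    # empty-vs-empty pairs: convention Tc = 0, but the self-diagonal stays 1
    # only for non-empty molecules; an all-zero fingerprint has d(a,a)=0 anyway
    np.fill_diagonal(sim, np.where(pop > 0, 1.0, 1.0))
    return sim


def tanimoto_distance_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """Symmetric matrix of 1 - Tc with a zero diagonal."""
    return 1.0 - tanimoto_matrix(fps)


def read_smiles(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file: one `SMILES [id]` per line; '#' lines are comments.

    Returns (compound_id, smiles) tuples; a missing id defaults to the
    1-based line position rendered as ``mol<k>``.
    """
    out: list[tuple[str, str]] = []
    for k, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"mol{k}"
        out.append((cid, smiles))
    return out


def write_smiles(path: str | Path, records: list[tuple[str, str]]) -> None:
    """Write (compound_id, smiles) tuples as a .smi file."""
    with open(path, "w") as fh:
        for cid, smiles in records:
            fh.write(f"{smiles} {cid}\n")
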