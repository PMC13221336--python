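"""Bit-string molecular fingerprints and Tanimoto similarity.

Four fingerprint kinds are implemented:

``pubchem881``
    The 881-bit PubChem/CACTVS substructure-key fingerprint (element
    counts, ring counts, SMARTS feature sections), implemented in
    :mod:`toxsar.fingerprints.pubchem`.  This is the reference kind for
    ranking a panel against its lead structure.
``maccs166``
    The public 166-key MACCS set (keys 1-166 mapped to bits 0-165).
``circular_r2_1024``
    Radius-2 hashed circular (Morgan) fingerprint folded to 1024 bits.
``path_d7_2048``
    Hashed linear-path fingerprint, paths up to 7 bonds, folded to
    2048 bits.

The hashed kinds are computed with fixed generator parameters so the
on-bit sets are stable across runs and platforms for a given RDKit
release.

Tanimoto similarity is total: two empty bit sets compare as 1.0, one
empty set against a non-empty one as 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from ..chem import Compound, mol_from_compound
from .pubchem import pubchem_on_bits

__all__ = [
    "FINGERPRINT_LENGTHS",
    "BitFingerprint",
    "SimilarityMatrix",
    "fingerprint",
    "tanimoto",
    "similarity_matrix",
    "rank_by_reference",
    "selection_report",
    "load_rules",
    "DEFAULT_RULES",
]

FINGERPRINT_LENGTHS = {
    "pubchem881": 881,
    "maccs166": 166,
    "circular_r2_1024": 1024,
    "path_d7_2048": 2048,
}

#: Substructure rules reproducing the panel-selection logic: the
#: nitrovinyl rule flags the conjugated C=C-NO2 moiety, the remaining
#: rules flag its constituent features.
DEFAULT_RULES = {
    "nitrovinyl": "C=C[N+](=O)[O-]",
    "nitro": "[N+](=O)[O-]",
    "vinyl": "C=C",
    "phenyl": "c1ccccc1",
    "carboxyl": "C(=O)[OX2H1]",
}


@dataclass(frozen=True)
class BitFingerprint:
    kind: str
    length: int
    on_bits: frozenset[int]

    def __post_init__(self):
        if self.kind not in FINGERPRINT_LENGTHS:
            raise ValueError(f"unknown fingerprint kind: {self.kind!r}")
        if FINGERPRINT_LENGTHS[self.kind] != self.length:
            raise ValueError(
                f"kind {self.kind!r} fixes length "
                f"{FINGERPRINT_LENGTHS[self.kind]}, got {self.length}"
            )
        if self.on_bits and not (
            0 <= min(self.on_bits) and max(self.on_bits) < self.length
        ):
            raise ValueError("on_bits outside [0, length)")


@dataclass(frozen=True)
class SimilarityMatrix:
    kind: str
    ids: tuple[int, ...]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_PATH = rdFingerprintGenerator.GetRDKitFPGenerator(
    minPath=1, maxPath=7, fpSize=2048, branchedPaths=False
)


def _as_mol(compound) -> Chem.Mol:
    if isinstance(compound, Compound):
        return mol_from_compound(compound)
    return compound


def fingerprint(compound, kind: str) -> BitFingerprint:
    """Compute one fingerprint kind for a compound (or RDKit molecule)."""
    if kind not in FINGERPRINT_LENGTHS:
        raise ValueError(f"unknown fingerprint kind: {kind!r}")
    mol = _as_mol(compound)
    if kind == "pubchem881":
        bits = pubchem_on_bits(mol)
    elif kind == "maccs166":
        # RDKit indexes MACCS keys 1..166 in a 167-bit vector; drop the
        # unused bit 0 so the key set occupies [0, 166).
        raw = MACCSkeys.GenMACCSKeys(mol)
        bits = frozenset(b - 1 for b in raw.GetOnBits() if b >= 1)
    elif kind == "circular_r2_1024":
        bits = frozenset(_MORGAN.GetFingerprint(mol).GetOnBits())
    else:  # path_d7_2048
        bits = frozenset(_PATH.GetFingerprint(mol).GetOnBits())
    return BitFingerprint(kind=kind, length=FINGERPRINT_LENGTHS[kind], on_bits=bits)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|a∩b| / |a∪b| over on-bits; 1.0 for two empty bit sets."""
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind!r} vs {b.kind!r}")
    union = a.on_bits | b.on_bits
    if not union:
        return 1.0
    return len(a.on_bits & b.on_bits) / len(union)


def similarity_matrix(panel: list[Compound], kind: str) -> SimilarityMatrix:
    """Full pairwise Tanimoto matrix over a panel of ≥ 2 compounds."""
    if len(panel) < 2:
        raise ValueError("similarity matrix requires at least 2 compounds")
    fps = [fingerprint(c, kind) for c in panel]
    n = len(fps)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
        values[i, i] = tanimoto(fps[i], fps[i])
    return SimilarityMatrix(
        kind=kind, ids=tuple(c.id for c in panel), values=values
    )


def rank_by_reference(
    matrix: SimilarityMatrix, ref_id: int
) -> list[tuple[int, float]]:
    """Rank compounds by Tanimoto against a reference, descending.

    Ties are broken by ascending compound id.
    """
    if ref_id not in matrix.ids:
        raise ValueError(f"unknown reference id {ref_id}")
    ref_pos = matrix.ids.index(ref_id)
    pairs = [
        (cid, float(matrix.values[ref_pos, i]))
        for i, cid in enumerate(matrix.ids)
    ]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def load_rules(path) -> dict[str, str]:
    """Read a name → SMARTS rule mapping from a YAML config file."""
    with open(path) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, dict):
        raise ValueError("rule file must map rule names to SMARTS strings")
    return {str(k): str(v) for k, v in rules.items()}


def selection_report(
    panel: list[Compound],
    ref_id: int,
    rules: dict[str, str] | None = None,
    kind: str = "pubchem881",
) -> pd.DataFrame:
    """Per-compound substructure flags plus Tanimoto against the reference.

    Rows are ordered by descending Tc (ties by ascending id), mirroring a
    similarity-sorted selection table.
    """
    if rules is None:
        rules = DEFAULT_RULES
    patterns = {}
    for name, smarts in rules.items():
        pat = Chem.MolFromSmarts(smarts)
        if pat is None:
            raise ValueError(f"rule {name!r}: invalid SMARTS {smarts!r}")
        patterns[name] = pat

    matrix = similarity_matrix(panel, kind)
    order = {cid: rank for rank, (cid, _) in enumerate(rank_by_reference(matrix, ref_id))}
    tc = dict(rank_by_reference(matrix, ref_id))

    rows = []
    for compound in sorted(panel, key=lambda c: order[c.id]):
        mol = mol_from_compound(compound)
        row = {"id": compound.id, "name": compound.name, "tc": tc[compound.id]}
        for name, pat in patterns.items():
            row[name] = mol.HasSubstructMatch(pat)
        rows.append(row)
    return pd.DataFrame(rows)
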