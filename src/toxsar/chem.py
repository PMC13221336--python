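"""Compound-table parsing and drug-likeness descriptor profiles.

The compound panel arrives as a delimited text table with columns
``id,name,cas,smiles`` (any column order).  Descriptors follow the
classical definitions: Crippen atom-contribution LogP, Ertl
fragment-contribution TPSA (N/O scheme), Lipinski hydrogen-bond
donor/acceptor counts (OH+NH / N+O) and the four rule-of-five checks.

SMILES are taken as written; in particular the charged nitro form
``[N+](=O)[O-]`` is not normalized, because both the Crippen atom
classes and the TPSA fragment contributions differ between the charged
and the neutral representation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "Compound",
    "DescriptorProfile",
    "CompoundTableError",
    "parse_compound_table",
    "load_panel",
    "mol_from_compound",
    "heavy_atom_count",
    "crippen_logp",
    "ertl_tpsa",
    "descriptor_profile",
    "descriptor_table",
]

#: Ghose drug-likeness window for the heavy-atom count.
GHOSE_ATOM_RANGE = (20, 70)

_REQUIRED_COLUMNS = ("id", "name", "cas", "smiles")


class CompoundTableError(ValueError):
    """Raised for malformed compound tables (bad SMILES, duplicate ids...)."""


@dataclass(frozen=True)
class Compound:
    """One panel member, identified by its canonical SMILES."""

    id: int
    name: str
    cas: str
    smiles: str


@dataclass(frozen=True)
class DescriptorProfile:
    mw: float
    heavy_atoms: int
    hbd: int
    hba: int
    logp: float
    tpsa: float
    ro5_violations: int
    ghose_atoms_ok: bool


def mol_from_compound(compound: Compound) -> Chem.Mol:
    """Parse and validate the SMILES of a compound.

    The molecule must parse, be a single connected fragment and contain
    at least one heavy atom.
    """
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise CompoundTableError(
            f"compound {compound.id}: SMILES does not parse: {compound.smiles!r}"
        )
    if mol.GetNumHeavyAtoms() < 1:
        raise CompoundTableError(f"compound {compound.id}: no heavy atoms")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise CompoundTableError(
            f"compound {compound.id}: SMILES is not a connected molecule"
        )
    return mol


def parse_compound_table(source) -> list[Compound]:
    """Read a compound table from a path, file object or CSV string.

    The header row must name the columns ``id``, ``name``, ``cas`` and
    ``smiles`` in any order.  Every SMILES is validated by parsing and a
    row-level error names the offending compound id.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CompoundTableError(f"missing columns: {', '.join(missing)}")

    compounds = []
    seen: set[int] = set()
    for _, row in df.iterrows():
        try:
            cid = int(row["id"])
        except (TypeError, ValueError):
            raise CompoundTableError(f"non-integer id: {row['id']!r}") from None
        if cid in seen:
            raise CompoundTableError(f"duplicate compound id {cid}")
        seen.add(cid)
        compound = Compound(
            id=cid,
            name="" if pd.isna(row["name"]) else str(row["name"]).strip(),
            cas="" if pd.isna(row["cas"]) else str(row["cas"]).strip(),
            smiles=str(row["smiles"]).strip(),
        )
        mol_from_compound(compound)  # validates; raises with the row id
        compounds.append(compound)
    return compounds


def load_panel() -> list[Compound]:
    """Load the packaged nine-member nitrostyrene compound panel."""
    ref = resources.files("toxsar.data").joinpath("panel.csv")
    with resources.as_file(ref) as path:
        return parse_compound_table(Path(path))


def heavy_atom_count(compound: Compound) -> int:
    """Number of non-hydrogen atoms."""
    return mol_from_compound(compound).GetNumHeavyAtoms()


def crippen_logp(compound: Compound) -> float:
    """Crippen atom-contribution LogP (implicit hydrogens included)."""
    return Crippen.MolLogP(mol_from_compound(compound))


def ertl_tpsa(compound: Compound) -> float:
    """Ertl fragment-contribution TPSA in Å² (N/O contributions only)."""
    return rdMolDescriptors.CalcTPSA(mol_from_compound(compound))


def descriptor_profile(compound: Compound) -> DescriptorProfile:
    """Full descriptor profile with rule-of-five and Ghose atom checks."""
    mol = mol_from_compound(compound)
    mw = Descriptors.MolWt(mol)
    heavy = mol.GetNumHeavyAtoms()
    hbd = rdMolDescriptors.CalcNumLipinskiHBD(mol)
    hba = rdMolDescriptors.CalcNumLipinskiHBA(mol)
    logp = Crippen.MolLogP(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    violations = sum([mw > 500, logp > 5, hbd > 5, hba > 10])
    lo, hi = GHOSE_ATOM_RANGE
    return DescriptorProfile(
        mw=mw,
        heavy_atoms=heavy,
        hbd=hbd,
        hba=hba,
        logp=logp,
        tpsa=tpsa,
        ro5_violations=violations,
        ghose_atoms_ok=lo <= heavy <= hi,
    )


def descriptor_table(compounds: list[Compound]) -> pd.DataFrame:
    """Descriptor report, one row per compound, fixed column order."""
    rows = []
    for compound in compounds:
        profile = descriptor_profile(compound)
        rows.append(
            {
                "id": compound.id,
                "mw": profile.mw,
                "heavy_atoms": profile.heavy_atoms,
                "hbd": profile.hbd,
                "hba": profile.hba,
                "logp": profile.logp,
                "tpsa": profile.tpsa,
                "ro5_violations": profile.ro5_violations,
                "ghose_atoms_ok": profile.ghose_atoms_ok,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "mw",
            "heavy_atoms",
            "hbd",
            "hba",
            "logp",
            "tpsa",
            "ro5_violations",
            "ghose_atoms_ok",
        ],
    )
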