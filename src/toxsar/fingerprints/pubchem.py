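"""881-bit PubChem/CACTVS substructure-key fingerprint.

The key set has three sections:

* bits 0-114    hierarchic element counts (implicit hydrogens included),
* bits 115-262  ring counts by size and ring class over the SSSR ring set,
* bits 263-880  substructure presence tests expressed as SMARTS.

A ring is *saturated-or-aromatic* when every ring bond is a single or an
aromatic bond, *unsaturated* otherwise, and *aromatic* when every ring
bond is aromatic.  Ring-composition classes look at heavy atoms only:
carbon-only, nitrogen-containing and heteroatom-containing.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

from ._pubchem_bits import ELEMENT_BITS, RING_BITS, SMARTS_BITS

N_BITS = 881


@lru_cache(maxsize=None)
def _compiled_smarts():
    pats = []
    for bit, smarts in SMARTS_BITS:
        pat = Chem.MolFromSmarts(smarts)
        if pat is None:  # pragma: no cover - table is static
            raise ValueError(f"bit {bit}: SMARTS does not compile: {smarts!r}")
        pats.append((bit, pat))
    return pats


def _element_bits(mol):
    counts = {}
    n_h = 0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        counts[z] = counts.get(z, 0) + 1
        n_h += atom.GetTotalNumHs(includeNeighbors=False)
    # explicit hydrogens are counted as atoms, implicit ones via the H count
    counts[1] = counts.get(1, 0) + n_h
    for bit, z, min_count in ELEMENT_BITS:
        if counts.get(z, 0) >= min_count:
            yield bit


def _ring_profiles(mol):
    """Classify each SSSR ring as (size, saturated, aromatic, has_n, has_het)."""
    ri = mol.GetRingInfo()
    profiles = []
    for atom_ids, bond_ids in zip(ri.AtomRings(), ri.BondRings()):
        aromatic = all(
            mol.GetBondWithIdx(b).GetIsAromatic() for b in bond_ids
        )
        saturated = all(
            mol.GetBondWithIdx(b).GetBondType() == Chem.BondType.SINGLE
            or mol.GetBondWithIdx(b).GetIsAromatic()
            for b in bond_ids
        )
        atomic_nums = [mol.GetAtomWithIdx(a).GetAtomicNum() for a in atom_ids]
        has_n = 7 in atomic_nums
        has_het = any(z not in (1, 6) for z in atomic_nums)
        profiles.append((len(atom_ids), saturated, aromatic, has_n, has_het))
    return profiles


_RING_PREDICATES = {
    "any": lambda s, a, n, h: True,
    "sat_carbon": lambda s, a, n, h: (s or a) and not h,
    "sat_nitrogen": lambda s, a, n, h: (s or a) and n,
    "sat_hetero": lambda s, a, n, h: (s or a) and h,
    "unsat_carbon": lambda s, a, n, h: not s and not a and not h,
    "unsat_nitrogen": lambda s, a, n, h: not s and not a and n,
    "unsat_hetero": lambda s, a, n, h: not s and not a and h,
    "aromatic": lambda s, a, n, h: a,
    "hetero_aromatic": lambda s, a, n, h: a and h,
}


def _ring_bits(mol):
    profiles = _ring_profiles(mol)
    for bit, ring_class, ring_size, min_count in RING_BITS:
        pred = _RING_PREDICATES[ring_class]
        count = sum(
            1
            for size, sat, arom, has_n, has_het in profiles
            if (ring_size == 0 or size == ring_size)
            and pred(sat, arom, has_n, has_het)
        )
        if count >= min_count:
            yield bit


def _smarts_bits(mol):
    for bit, pat in _compiled_smarts():
        if mol.HasSubstructMatch(pat):
            yield bit


def pubchem_on_bits(mol) -> frozenset[int]:
    """Compute the on-bit set of the 881-bit substructure fingerprint.

    ``mol`` must be a sanitized RDKit molecule (aromaticity perceived,
    implicit hydrogen counts assigned).
    """
    bits = set(_element_bits(mol))
    bits.update(_ring_bits(mol))
    bits.update(_smarts_bits(mol))
    return frozenset(bits)
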