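import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from toxsar.chem import Compound
from toxsar.fingerprints import (
    DEFAULT_RULES,
    FINGERPRINT_LENGTHS,
    BitFingerprint,
    fingerprint,
    rank_by_reference,
    selection_report,
    similarity_matrix,
    tanimoto,
)
from toxsar.fingerprints.pubchem import pubchem_on_bits

# On-bit set of the lead compound's 881-bit substructure fingerprint,
# frozen from an independent reference implementation of the public key
# definitions (computed once during development, not at test time).
LEAD_PUBCHEM_BITS = frozenset(
    {0, 9, 10, 11, 14, 18, 19, 178, 179, 255, 283, 284, 285, 301, 332, 333,
     344, 345, 351, 355, 356, 365, 370, 371, 384, 395, 401, 416, 423, 430,
     434, 441, 445, 446, 449, 454, 455, 470, 490, 502, 516, 520, 524, 552,
     556, 564, 570, 578, 582, 584, 595, 599, 603, 608, 618, 634, 640, 660,
     664, 668, 677, 678, 679, 688, 708, 709, 710}
)

# Tanimoto of compounds 2..9 against the lead, printed at 2 d.p. in the
# similarity-sorted panel table.
PANEL_TC_2DP = [0.88, 0.77, 0.75, 0.74, 0.67, 0.64, 0.59, 0.58]


def _fp(kind, on_bits):
    return BitFingerprint(kind=kind, length=FINGERPRINT_LENGTHS[kind], on_bits=frozenset(on_bits))


class TestPubchemFingerprint:
    def test_lead_compound_frozen_bits(self, panel_by_id):
        fp = fingerprint(panel_by_id[1], "pubchem881")
        assert fp.on_bits == LEAD_PUBCHEM_BITS

    def test_lead_compound_semantic_bits(self, panel_by_id):
        bits = fingerprint(panel_by_id[1], "pubchem881").on_bits
        assert 11 in bits  # >= 8 carbons
        assert 14 in bits  # >= 1 nitrogen
        assert 255 in bits  # >= 1 aromatic ring
        assert 301 in bits  # N~O bonded pair
        assert 256 not in bits  # no hetero-aromatic ring

    def test_benzene_ring_bits(self):
        bits = pubchem_on_bits(Chem.MolFromSmiles("c1ccccc1"))
        assert 255 in bits  # aromatic ring
        assert 256 not in bits  # not hetero-aromatic
        assert 14 not in bits and 18 not in bits  # no N, no O

    def test_pyridine_heteroaromatic(self):
        bits = pubchem_on_bits(Chem.MolFromSmiles("c1ccncc1"))
        assert 255 in bits and 256 in bits

    def test_methane_minimal(self):
        bits = pubchem_on_bits(Chem.MolFromSmiles("C"))
        assert 0 in bits  # >= 4 H
        assert 255 not in bits

    def test_determinism(self, panel_by_id):
        a = fingerprint(panel_by_id[3], "pubchem881")
        b = fingerprint(panel_by_id[3], "pubchem881")
        assert a.on_bits == b.on_bits


class TestFingerprintKinds:
    @pytest.mark.parametrize("kind", sorted(FINGERPRINT_LENGTHS))
    def test_lengths_and_bounds(self, panel_by_id, kind):
        fp = fingerprint(panel_by_id[1], kind)
        assert fp.length == FINGERPRINT_LENGTHS[kind]
        assert all(0 <= b < fp.length for b in fp.on_bits)
        assert fp.on_bits  # a real molecule sets at least one bit

    def test_unknown_kind(self, panel_by_id):
        with pytest.raises(ValueError, match="unknown"):
            fingerprint(panel_by_id[1], "daylight")

    def test_maccs_benzene_keys(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        bits = fingerprint(mol, "maccs166").on_bits
        # MACCS key 163 (6-membered ring) and 162 (aromatic) are 1-indexed;
        # shifted down by one in the 166-bit layout.
        assert 161 in bits and 162 in bits
        assert max(bits) < 166

    @pytest.mark.parametrize("kind", ["circular_r2_1024", "path_d7_2048"])
    def test_hashed_kinds_atom_order_invariant(self, kind):
        a = fingerprint(Chem.MolFromSmiles("OCC1=CC=CC=C1N"), kind)
        b = fingerprint(Chem.MolFromSmiles("NC1=CC=CC=C1CO"), kind)
        assert a.on_bits == b.on_bits

    def test_pubchem_atom_order_invariant(self):
        a = pubchem_on_bits(Chem.MolFromSmiles("OCC1=CC=CC=C1N"))
        b = pubchem_on_bits(Chem.MolFromSmiles("NC1=CC=CC=C1CO"))
        assert a == b


class TestTanimoto:
    def test_identity(self):
        fp = _fp("maccs166", {1, 5, 9})
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        assert tanimoto(_fp("maccs166", {1, 2}), _fp("maccs166", {3, 4})) == 0.0

    def test_both_empty_convention(self):
        assert tanimoto(_fp("maccs166", set()), _fp("maccs166", set())) == 1.0

    def test_one_empty(self):
        assert tanimoto(_fp("maccs166", {1}), _fp("maccs166", set())) == 0.0

    def test_kind_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(_fp("maccs166", {1}), _fp("pubchem881", {1}))

    def test_compound_2_vs_lead(self, panel_by_id):
        a = fingerprint(panel_by_id[1], "pubchem881")
        b = fingerprint(panel_by_id[2], "pubchem881")
        assert round(tanimoto(a, b), 2) == 0.88

    @given(
        a=st.sets(st.integers(0, 165)),
        b=st.sets(st.integers(0, 165)),
    )
    @settings(max_examples=200)
    def test_matches_set_arithmetic_oracle(self, a, b):
        expected = 1.0 if not (a | b) else len(a & b) / len(a | b)
        assert tanimoto(_fp("maccs166", a), _fp("maccs166", b)) == expected

    @given(
        a=st.sets(st.integers(0, 165)),
        b=st.sets(st.integers(0, 165)),
    )
    @settings(max_examples=100)
    def test_bounds(self, a, b):
        value = tanimoto(_fp("maccs166", a), _fp("maccs166", b))
        assert 0.0 <= value <= 1.0


class TestSimilarityMatrix:
    def test_identical_pair(self):
        c = Compound(id=1, name="", cas="", smiles="c1ccccc1")
        d = Compound(id=2, name="", cas="", smiles="C1=CC=CC=C1")
        m = similarity_matrix([c, d], "pubchem881")
        assert np.allclose(m.values, 1.0)

    def test_symmetry_and_diagonal(self, panel):
        m = similarity_matrix(panel, "pubchem881")
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert ((m.values >= 0) & (m.values <= 1)).all()

    def test_panel_range_vs_lead(self, panel):
        m = similarity_matrix(panel, "pubchem881")
        column = m.values[0][1:]
        assert round(min(column), 3) == 0.578
        assert round(max(column), 3) == 0.877

    def test_requires_two_compounds(self, panel):
        with pytest.raises(ValueError):
            similarity_matrix(panel[:1], "pubchem881")


class TestRankByReference:
    def test_panel_order(self, panel):
        m = similarity_matrix(panel, "pubchem881")
        ranked = rank_by_reference(m, 1)
        assert [cid for cid, _ in ranked] == [1, 2, 3, 4, 5, 6, 7, 8, 9]
        for (cid, tc), expected in zip(ranked[1:], PANEL_TC_2DP):
            assert abs(tc - expected) < 0.005

    def test_reference_ranks_first(self, panel):
        m = similarity_matrix(panel, "pubchem881")
        top_id, top_tc = rank_by_reference(m, 1)[0]
        assert top_id == 1 and top_tc == 1.0

    def test_tie_broken_by_id(self):
        ref = Compound(id=5, name="", cas="", smiles="c1ccccc1")
        dup_a = Compound(id=9, name="", cas="", smiles="C1=CC=CC=C1")
        dup_b = Compound(id=2, name="", cas="", smiles="c1ccccc1")
        m = similarity_matrix([ref, dup_a, dup_b], "pubchem881")
        assert [cid for cid, _ in rank_by_reference(m, 5)] == [2, 5, 9]

    def test_unknown_reference(self, panel):
        m = similarity_matrix(panel, "pubchem881")
        with pytest.raises(ValueError, match="unknown"):
            rank_by_reference(m, 42)


class TestSelectionReport:
    def test_nitrovinyl_partition(self, panel):
        report = selection_report(panel, 1).set_index("id")
        assert set(report.index[report["nitrovinyl"]]) == {1, 3, 8, 9}
        assert set(report.index[~report["nitrovinyl"]]) == {2, 4, 5, 6, 7}

    def test_compound_flags(self, panel):
        report = selection_report(panel, 1).set_index("id")
        assert not report.loc[2, "nitrovinyl"] and report.loc[2, "nitro"]
        assert not report.loc[4, "nitro"]
        assert not report.loc[6, "vinyl"]
        assert report.loc[7, "carboxyl"]

    def test_all_panel_members_have_phenyl(self, panel):
        report = selection_report(panel, 1)
        assert report["phenyl"].all()

    def test_invalid_smarts_names_rule(self, panel):
        with pytest.raises(ValueError, match="broken"):
            selection_report(panel, 1, rules={"broken": "C(("})

    def test_default_rules_complete(self):
        assert set(DEFAULT_RULES) == {"nitrovinyl", "nitro", "vinyl", "phenyl", "carboxyl"}
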