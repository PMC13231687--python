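"""Fragmentation, series assembly, and activity-cliff enumeration."""

import itertools

import pytest
from rdkit import Chem

from acprofiles.chem import (MMS, MoleculeRecord, ac_compounds_per_assay,
                             build_mms, extract_acs, fragment_molecule,
                             read_smiles_file)
from acprofiles.chem import _ratio_ok
from acprofiles.errors import InputError
from conftest import random_matrix

import numpy as np


def record(smiles, cid="x"):
    return MoleculeRecord.from_smiles(cid, smiles)


class TestFragmentMolecule:
    def test_toluene_single_cut(self):
        frags = fragment_molecule(record("Cc1ccccc1"))
        assert len(frags) == 1
        f = frags[0]
        assert f.n_sub == 1 and f.n_att == 1
        assert Chem.MolToSmiles(Chem.MolFromSmiles(f.substituent)) == "*C"

    def test_oversized_molecule_returns_nothing(self):
        big = record("C" * 61)  # 61 heavy atoms
        assert big.n_heavy == 61
        assert fragment_molecule(big) == []
        assert fragment_molecule(record("C" * 60, "ok"), max_heavy=60) != []

    def test_ratio_boundary_inclusive(self):
        # (7-1)/30 = 0.2 kept; (8-1)/30 ~ 0.233 discarded
        assert _ratio_ok(7, 1, 30, 0.2)
        assert not _ratio_ok(8, 1, 30, 0.2)
        # a real boundary molecule: heptyl chain (7) on a C23 ring = 30 heavy
        mol = record("CCCCCCCC1CCCCCCCCCCCCCCCCCCCCCC1")
        assert mol.n_heavy == 30
        sizes = {f.n_sub for f in fragment_molecule(mol)}
        assert max(sizes) == 7  # ratio (7-1)/30 = 0.2, boundary kept
        tighter = {f.n_sub for f in fragment_molecule(mol, ratio_threshold=0.19)}
        assert max(tighter) == 6  # just below the bound drops the heptyl cut

    def test_unparsable_and_disconnected_raise(self):
        with pytest.raises(InputError, match="bad1"):
            MoleculeRecord.from_smiles("bad1", "not-a-smiles")
        with pytest.raises(InputError, match="bad2"):
            MoleculeRecord.from_smiles("bad2", "CC.CC")

    def test_ratio_filter_monotone(self):
        mol = record("CCCCc1ccc(CCN(C)C)cc1")
        counts = [len(fragment_molecule(mol, ratio_threshold=t))
                  for t in (0.05, 0.1, 0.2, 0.4)]
        assert counts == sorted(counts)

    def test_core_canonicalization_across_parents(self):
        f1 = fragment_molecule(record("Cc1ccncc1", "m1"))
        f2 = fragment_molecule(record("CCc1ccncc1", "m2"))
        cores1 = {f.core_key for f in f1}
        cores2 = {f.core_key for f in f2}
        shared = cores1 & cores2  # the bare pyridine core reached twice
        assert shared, (cores1, cores2)

    def test_double_cut_option(self):
        frags1 = fragment_molecule(record("Cc1ccc(CC)nc1"), max_cuts=1)
        frags2 = fragment_molecule(record("Cc1ccc(CC)nc1"), max_cuts=2)
        assert {f.n_att for f in frags1} == {1}
        assert 2 in {f.n_att for f in frags2}
        assert set(frags1) <= set(frags2)

    def test_single_cut_roundtrip_reassembly(self):
        smiles = "CCOc1ccc(CN2CCCC2)cc1"
        parent = Chem.CanonSmiles(smiles)
        for f in fragment_molecule(record(smiles)):
            core = Chem.MolFromSmiles(f.core_key)
            sub = Chem.MolFromSmiles(f.substituent)
            for m in (core, sub):
                for a in m.GetAtoms():
                    if a.GetAtomicNum() == 0:
                        a.SetAtomMapNum(1)
            joined = Chem.molzip(Chem.CombineMols(core, sub))
            assert Chem.MolToSmiles(joined) == parent


class TestBuildMMS:
    def frags_of(self, pairs):
        out = []
        for cid, smi in pairs:
            out.extend(fragment_molecule(record(smi, cid)))
        return out

    def test_two_compounds_shared_core(self):
        mms = build_mms(self.frags_of([("c1", "Cc1ccccc1"), ("c2", "CCc1ccccc1")]))
        assert len(mms) == 1
        assert mms[0].member_ids == {"c1", "c2"}

    def test_singleton_core_emits_nothing(self):
        assert build_mms(self.frags_of([("c1", "Cc1ccccc1")])) == []

    def test_overlapping_series_allowed(self):
        # brute-force grouping of cores over a hand-built triple
        frags = self.frags_of([
            ("c1", "Cc1ccc(F)cc1"), ("c2", "CCc1ccc(F)cc1"), ("c3", "Cc1ccc(Cl)cc1"),
        ])
        by_core = {}
        for f in frags:
            by_core.setdefault(f.core_key, set()).add(f.parent_id)
        expected = {frozenset(v) for v in by_core.values() if len(v) >= 2}
        got = {s.member_ids for s in build_mms(frags)}
        assert got == expected
        assert any("c1" in m and "c2" in m for m in got)
        assert any("c1" in m and "c3" in m for m in got)

    def test_series_ids_deterministic(self):
        frags = self.frags_of([("c1", "Cc1ccccc1"), ("c2", "CCc1ccccc1"),
                               ("c3", "Cc1ccncc1"), ("c4", "CCc1ccncc1")])
        a = build_mms(frags)
        b = build_mms(list(reversed(frags)))
        assert a == b
        assert [s.series_id for s in a] == sorted(s.series_id for s in a)


class TestExtractACs:
    series = MMS(series_id="S1", core_key="*c1ccccc1",
                 members=(("a1", "*C"), ("a2", "*CC"), ("i1", "*O"),
                          ("i2", "*N"), ("i3", "*F")))

    def test_count_is_product(self):
        labels = {"a1": 1, "a2": 1, "i1": 0, "i2": 0, "i3": 0}
        acs = extract_acs(self.series, labels, "assayX")
        assert len(acs) == 2 * 3
        assert {(ac.active_id, ac.inactive_id) for ac in acs} == set(
            itertools.product(["a1", "a2"], ["i1", "i2", "i3"]))

    def test_homogeneous_series_has_no_cliffs(self):
        labels = dict.fromkeys(["a1", "a2", "i1", "i2", "i3"], 1)
        assert extract_acs(self.series, labels, "assayX") == []

    def test_brute_force_pairs(self):
        labels = {"a1": 1, "a2": 1, "i1": 0, "i2": 1, "i3": 1}
        acs = extract_acs(self.series, labels, "assayX")
        brute = {(a, b) for a in labels for b in labels
                 if labels[a] == 1 and labels[b] == 0}
        assert {(ac.active_id, ac.inactive_id) for ac in acs} == brute

    def test_missing_label_raises(self):
        with pytest.raises(InputError, match="i3"):
            extract_acs(self.series, {"a1": 1, "a2": 1, "i1": 0, "i2": 0}, "assayX")


class TestACCompoundsPerAssay:
    def test_union_counts(self, tiny_matrix):
        s1 = MMS("S1", "k1", (("c1", "*C"), ("c2", "*F"), ("c3", "*O")))
        out = ac_compounds_per_assay([s1], tiny_matrix)
        # a1 column over c1..c3 = [1,0,0] -> mixed -> all members participate
        assert out["a1"] == {"c1", "c2", "c3"}
        # a3 column over c1..c3 = [1,1,1] -> homogeneous -> none
        assert out["a3"] == set()

    def test_shared_compound_counted_once(self, tiny_matrix):
        s1 = MMS("S1", "k1", (("c1", "*C"), ("c2", "*F")))
        s2 = MMS("S2", "k2", (("c1", "*N"), ("c3", "*O")))
        out = ac_compounds_per_assay([s1, s2], tiny_matrix)
        # brute-force union over mixed series in a1: both series mixed
        assert out["a1"] == {"c1", "c2", "c3"}


def test_ac_count_invariant_on_random_series():
    """AC count equals n_active x n_inactive for random label patterns."""
    rng = np.random.default_rng(5)
    members = tuple((f"m{i}", f"*C{i}") for i in range(8))
    series = MMS("S", "core", members)
    for _ in range(100):
        labels = {cid: int(rng.integers(0, 2)) for cid, _ in members}
        acs = extract_acs(series, labels, "a")
        n_act = sum(labels.values())
        assert len(acs) == n_act * (8 - n_act)


def test_smiles_io_roundtrip(tmp_path):
    path = tmp_path / "lib.smi"
    path.write_text("Cc1ccccc1\tm1\nCCO\tm2\n")
    records = read_smiles_file(path)
    assert [r.compound_id for r in records] == ["m1", "m2"]
    assert records[0].n_heavy == 7
    path.write_text("Cc1ccccc1\tm1\nCCO\tm1\n")
    with pytest.raises(InputError, match="duplicate"):
        read_smiles_file(path)
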