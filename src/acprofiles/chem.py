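"""Matched molecular series (MMS) extraction and activity-cliff enumeration.

Structural analogs are identified by systematic fragmentation of acyclic
single bonds: each eligible cut splits a molecule into a *core* (the larger
fragment, carrying an attachment point) and a *substituent* (the smaller
fragment).  Compounds sharing a canonical core form a matching molecular
series — the matched-molecular-pair idea extended from pairs to series.
Within a series tested in a binary assay, every (active, inactive) compound
pair is an activity cliff: close structural analogs with opposite outcomes.

Eligibility of a cut is controlled by a fragment-to-size ratio
``(n_sub - n_att) / n_mol <= ratio_threshold`` where ``n_mol`` is the
heavy-atom count of the parent, ``n_sub`` the heavy-atom count of the
substituent fragment(s) and ``n_att`` the number of attachment points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import InputError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "Fragmentation",
    "MMS",
    "ActivityCliff",
    "fragment_molecule",
    "build_mms",
    "extract_acs",
    "ac_compounds_per_assay",
    "read_smiles_file",
    "write_mms_table",
    "write_ac_table",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """A library compound: identifier, structure, heavy-atom count."""

    compound_id: str
    smiles: str
    n_heavy: int

    @classmethod
    def from_smiles(cls, compound_id: str, smiles: str) -> "MoleculeRecord":
        mol = _parse_single_molecule(compound_id, smiles)
        return cls(compound_id=compound_id, smiles=Chem.MolToSmiles(mol),
                   n_heavy=mol.GetNumHeavyAtoms())


@dataclass(frozen=True)
class Fragmentation:
    """One eligible cut of a parent molecule into core + substituent."""

    parent_id: str
    core_key: str
    substituent: str
    n_sub: int
    n_att: int


@dataclass(frozen=True)
class MMS:
    """A matching molecular series: >=2 compounds sharing a canonical core."""

    series_id: str
    core_key: str
    members: tuple  # of (compound_id, substituent), sorted

    @property
    def member_ids(self) -> frozenset:
        return frozenset(cid for cid, _ in self.members)


@dataclass(frozen=True)
class ActivityCliff:
    """An (active, inactive) analog pair from one series in one assay."""

    assay_id: str
    active_id: str
    inactive_id: str
    series_id: str


def _parse_single_molecule(compound_id: str, smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES for compound {compound_id!r}: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise InputError(f"disconnected structure for compound {compound_id!r}: {smiles!r}")
    return mol


def _heavy_and_att(frag: Chem.Mol) -> tuple[int, int]:
    heavy = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 0)
    att = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() == 0)
    return heavy, att


def _canonical(frag: Chem.Mol) -> str:
    # Unlabeled attachment dummies: RDKit canonicalization makes symmetric
    # cores from different parents compare byte-identical.
    return Chem.MolToSmiles(frag)


def _ratio_ok(n_sub: int, n_att: int, n_mol: int, threshold: float) -> bool:
    return (n_sub - n_att) / n_mol <= threshold


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]


def fragment_molecule(
    mol: MoleculeRecord,
    max_heavy: int = 60,
    ratio_threshold: float = 0.2,
    max_cuts: int = 1,
) -> list[Fragmentation]:
    """Enumerate eligible core/substituent fragmentations of one molecule.

    Every acyclic single bond between heavy atoms is a candidate cut.  For a
    single cut the smaller fragment is the substituent (on an exact size tie
    both orientations are emitted when both pass the ratio filter).  With
    ``max_cuts=2`` pairs of cuts are additionally enumerated; the middle
    fragment (two attachment points) is the core and the two flanking
    fragments together form the substituent.

    Molecules with more than ``max_heavy`` heavy atoms return an empty list.
    Results are deduplicated on (core_key, substituent) and sorted.
    """
    if not 0.0 < ratio_threshold < 1.0:
        raise InputError("ratio_threshold must lie in (0, 1)")
    if max_cuts not in (1, 2):
        raise InputError("max_cuts must be 1 or 2")
    rdmol = _parse_single_molecule(mol.compound_id, mol.smiles)
    n_mol = rdmol.GetNumHeavyAtoms()
    if n_mol > max_heavy:
        return []
    bonds = _cuttable_bonds(rdmol)
    out: set[tuple[str, str, int, int]] = set()

    for bidx in bonds:
        frag = Chem.FragmentOnBonds(rdmol, [bidx], addDummies=True,
                                    dummyLabels=[(0, 0)])
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        if len(pieces) != 2:  # pragma: no cover - acyclic cut always yields 2
            continue
        sizes = [_heavy_and_att(p)[0] for p in pieces]
        for i, j in ((0, 1), (1, 0)):
            n_sub = sizes[i]
            if n_sub > sizes[j]:
                continue  # the substituent is never the strictly larger side
            if not _ratio_ok(n_sub, 1, n_mol, ratio_threshold):
                continue
            out.add((_canonical(pieces[j]), _canonical(pieces[i]), n_sub, 1))

    if max_cuts == 2:
        for b1, b2 in itertools.combinations(bonds, 2):
            frag = Chem.FragmentOnBonds(rdmol, [b1, b2], addDummies=True,
                                        dummyLabels=[(0, 0), (0, 0)])
            pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
            if len(pieces) != 3:
                continue
            core = [p for p in pieces if _heavy_and_att(p)[1] == 2]
            subs = [p for p in pieces if _heavy_and_att(p)[1] == 1]
            if len(core) != 1 or len(subs) != 2:
                continue
            n_sub = sum(_heavy_and_att(p)[0] for p in subs)
            if not _ratio_ok(n_sub, 2, n_mol, ratio_threshold):
                continue
            sub_key = ".".join(sorted(_canonical(p) for p in subs))
            out.add((_canonical(core[0]), sub_key, n_sub, 2))

    return [
        Fragmentation(parent_id=mol.compound_id, core_key=ck, substituent=sub,
                      n_sub=ns, n_att=na)
        for ck, sub, ns, na in sorted(out)
    ]


def build_mms(frags: Iterable[Fragmentation]) -> list[MMS]:
    """Assemble matching molecular series from pooled fragmentations.

    One series per canonical core with at least two distinct member
    compounds; series identifiers are assigned by lexicographic core rank,
    so the output is deterministic for a given fragment pool.
    """
    by_core: dict[str, set[tuple[str, str]]] = {}
    for f in frags:
        by_core.setdefault(f.core_key, set()).add((f.parent_id, f.substituent))
    eligible = {
        core: members
        for core, members in by_core.items()
        if len({cid for cid, _ in members}) >= 2
    }
    width = max(5, len(str(len(eligible))))
    return [
        MMS(series_id=f"S{rank:0{width}d}", core_key=core,
            members=tuple(sorted(members)))
        for rank, core in enumerate(sorted(eligible))
        for members in [eligible[core]]
    ]


def extract_acs(
    series: MMS,
    assay_labels: Mapping[str, int],
    assay_id: str,
) -> list[ActivityCliff]:
    """All (active, inactive) pairs of one series in one assay.

    The count is exactly n_active * n_inactive; every member must carry a
    label (the profiling matrix is complete by construction).
    """
    actives, inactives = [], []
    for cid in sorted(series.member_ids):
        if cid not in assay_labels:
            raise InputError(
                f"compound {cid!r} of series {series.series_id} has no label "
                f"in assay {assay_id!r}"
            )
        (actives if assay_labels[cid] == 1 else inactives).append(cid)
    return [
        ActivityCliff(assay_id=assay_id, active_id=a, inactive_id=i,
                      series_id=series.series_id)
        for a in actives
        for i in inactives
    ]


def ac_compounds_per_assay(mms_list: Sequence[MMS], matrix) -> dict[str, set]:
    """Per assay, the set of compounds participating in at least one AC.

    Every member of a label-mixed series participates (an inactive member
    forms cliffs with all active members and vice versa), so the result per
    assay is the union of members of mixed series.
    """
    out: dict[str, set] = {a: set() for a in matrix.assay_ids}
    for series in mms_list:
        ids = sorted(series.member_ids)
        for assay_id in matrix.assay_ids:
            labels = matrix.labels(assay_id, ids)
            if 0 < sum(labels.values()) < len(labels):
                out[assay_id].update(ids)
    return out


def read_smiles_file(path) -> list[MoleculeRecord]:
    """Read a SMILES library, one ``SMILES<TAB>compound_id`` record per line."""
    records = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 'SMILES<TAB>compound_id'")
            smiles, cid = parts
            if cid in seen:
                raise InputError(f"{path}:{lineno}: duplicate compound_id {cid!r}")
            seen.add(cid)
            records.append(MoleculeRecord.from_smiles(cid, smiles))
    return records


def write_mms_table(mms_list: Sequence[MMS], path) -> None:
    with open(path, "w") as fh:
        fh.write("series_id\tcore_key\tcompound_id\tsubstituent\n")
        for s in mms_list:
            for cid, sub in s.members:
                fh.write(f"{s.series_id}\t{s.core_key}\t{cid}\t{sub}\n")


def write_ac_table(acs: Sequence[ActivityCliff], path) -> None:
    with open(path, "w") as fh:
        fh.write("assay_id\tseries_id\tactive_id\tinactive_id\n")
        for ac in acs:
            fh.write(f"{ac.assay_id}\t{ac.series_id}\t{ac.active_id}\t{ac.inactive_id}\n")
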