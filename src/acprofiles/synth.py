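"""Synthetic analog-series libraries and profiling matrices with planted
statistical structure.

The generator emulates the data regime the pipeline is built for:

* analog series — a ring-system core (scaffold x decoration combination,
  unique per series) carrying distinct small substituents at one variable
  site, emitted as valid SMILES well under 60 heavy atoms;
* a complete binary profiling matrix whose background cells are i.i.d.
  Bernoulli at ~1% activity (the sparsity regime of real primary-screening
  matrices);
* designated test assays in which disjoint blocks of series get mixed
  active/inactive labels (guaranteeing activity cliffs), the blocks being
  disjoint so that test assays are statistically independent of each other
  — mirroring the near-zero pairwise similarity of real assay panels;
* planted nearest-neighbor profile assays: copies of a test assay's column
  with each label flipped independently with probability epsilon, giving a
  controlled, measurable test<->profile similarity.

Everything is a pure function of (config, seed): the same configuration
reproduces the library and matrix byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import MoleculeRecord
from .errors import InputError
from .matrix import ProfilingMatrix

__all__ = ["SyntheticConfig", "generate_library", "generate_matrix", "generate"]

# Ring-system scaffolds with a variable substitution site ([*:1]) and a
# decoration site ([*:2]); the (scaffold, decoration) pair is unique per
# series, so cores never collide across series.
# Each scaffold is a distinct ring system (no scaffold is another scaffold
# with extra atoms at the variable site, so cores can never merge across
# series), with <= 6 ring atoms so that decoration cuts always fail the
# fragment-to-size filter.  Both attachment sites sit directly on the ring.
SCAFFOLDS = (
    "c1cc([*:2])ccc1[*:1]",      # benzene (para)
    "c1cc([*:2])cnc1[*:1]",      # pyridine
    "c1nc([*:2])ncc1[*:1]",      # pyrimidine
    "c1nc([*:2])cnc1[*:1]",      # pyrazine
    "C1CC([*:2])CCC1[*:1]",      # cyclohexane
    "C1CN([*:2])CCC1[*:1]",      # piperidine, N-decorated
    "C1CC([*:2])CC1[*:1]",       # cyclopentane
    "C1CC([*:2])OCC1[*:1]",      # tetrahydropyran
    "c1sc([*:2])cc1[*:1]",       # thiophene
    "c1oc([*:2])cc1[*:1]",       # furan
    "Cn1c([*:2])ccc1[*:1]",      # N-methylpyrrole
    "c1sc([*:2])nc1[*:1]",       # thiazole
    "c1oc([*:2])nc1[*:1]",       # oxazole
    "c1cc([*:2])nnc1[*:1]",      # pyridazine
    "Cn1c([*:2])ncc1[*:1]",      # N-methylimidazole
)

# Decorations: >= 4 heavy atoms each, so the decoration cut fails the 0.2
# fragment-to-size filter for every generated molecule.
DECORATIONS = (
    "[*:2]c1ccccc1", "[*:2]c1ccncc1", "[*:2]C1CCCCC1", "[*:2]c1ccco1",
    "[*:2]c1cccs1", "[*:2]N1CCOCC1", "[*:2]S(C)(=O)=O", "[*:2]C(=O)OC",
    "[*:2]C(=O)NC", "[*:2]OCC(F)F", "[*:2]c1ccc(C(F)(F)F)cc1",
    "[*:2]c1ccc(S(C)(=O)=O)cc1", "[*:2]c1ccc(C#CC)cc1",
    "[*:2]C(=O)N1CCCC1", "[*:2]Oc1ccccc1",
)

# Substituents: 1-3 heavy atoms (the fragment-to-size filter then passes at
# every realizable molecule size).
SUBSTITUENTS = (
    "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]C(C)C", "[*:1]Cl", "[*:1]F",
    "[*:1]Br", "[*:1]I", "[*:1]OC", "[*:1]O", "[*:1]N", "[*:1]C#N",
    "[*:1]CO", "[*:1]OCC", "[*:1]NC", "[*:1]C=C", "[*:1]SC", "[*:1]CCl",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic data set.

    ``planted_nn`` maps test-assay index -> flip rate epsilon; by default
    two thirds of the test assays (rounded) receive a planted
    nearest-neighbor profile assay at epsilon = 0.1 and the rest none.
    ``ac_fraction`` of all series are made AC-forming, divided into
    disjoint equal blocks across test assays.  AC-series compounds draw
    their background cells at ``ac_background_rate`` (screening actives are
    frequent hitters; an all-zero profile would drop the series from the
    experiment), everything else at ``base_active_rate``.
    """

    n_series: int = 180
    analogs_per_series: tuple = (5, 9)  # inclusive range
    n_assays: int = 133
    n_test_assays: int = 12
    base_active_rate: float = 0.01
    ac_background_rate: float = 0.05
    planted_nn: Optional[dict] = None  # test index -> epsilon
    ac_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.base_active_rate < 1:
            raise InputError("base_active_rate must lie in (0, 1)")
        if not 0 < self.ac_background_rate < 1:
            raise InputError("ac_background_rate must lie in (0, 1)")
        if self.n_test_assays >= self.n_assays:
            raise InputError("n_test_assays must be < n_assays")
        if not 0 < self.ac_fraction <= 1:
            raise InputError("ac_fraction must lie in (0, 1]")
        if self.analogs_per_series[0] < 2:
            raise InputError("series need at least 2 analogs")
        if self.planted_nn is not None:
            for idx, eps in self.planted_nn.items():
                if not 0 <= eps <= 0.5:
                    raise InputError("flip rate epsilon must lie in [0, 0.5]")
                if not 0 <= idx < self.n_test_assays:
                    raise InputError(f"planted test index {idx} out of range")

    @property
    def effective_planted(self) -> dict:
        if self.planted_nn is not None:
            return dict(self.planted_nn)
        n_planted = round(self.n_test_assays * 2 / 3)
        return {i: 0.1 for i in range(n_planted)}


def _zip_smiles(*parts: str) -> str:
    mols = [Chem.MolFromSmiles(p) for p in parts]
    combo = mols[0]
    for m in mols[1:]:
        combo = Chem.CombineMols(combo, m)
    out = Chem.molzip(combo)
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def generate_library(cfg: SyntheticConfig):
    """Build the analog-series compound library.

    Returns ``(records, truth_series)`` where ``truth_series`` maps a
    ground-truth series id to its member compound ids.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    lo, hi = cfg.analogs_per_series
    if hi > len(SUBSTITUENTS):
        raise InputError("substituent pool smaller than max analogs per series")
    combos = [(s, d) for s in SCAFFOLDS for d in DECORATIONS]
    if cfg.n_series > len(combos):
        raise InputError(
            f"core pool exhausted: {cfg.n_series} series > {len(combos)} cores"
        )
    order = rng.permutation(len(combos))[: cfg.n_series]

    records: list[MoleculeRecord] = []
    truth: dict[str, list] = {}
    counter = 0
    for series_idx, combo_idx in enumerate(order):
        scaffold, decoration = combos[combo_idx]
        n_analogs = int(rng.integers(lo, hi + 1))
        subs = rng.choice(len(SUBSTITUENTS), size=n_analogs, replace=False)
        gt_id = f"G{series_idx:03d}"
        truth[gt_id] = []
        for sub_idx in subs:
            smiles = _zip_smiles(scaffold, decoration, SUBSTITUENTS[sub_idx])
            cid = f"C{counter:05d}"
            counter += 1
            records.append(MoleculeRecord.from_smiles(cid, smiles))
            truth[gt_id].append(cid)
    seen: dict[str, str] = {}
    for r in records:
        if r.smiles in seen:  # distinct cores should never collide
            raise InputError(
                f"structure collision: {r.compound_id} duplicates {seen[r.smiles]}"
            )
        seen[r.smiles] = r.compound_id
    return records, truth


def generate_matrix(cfg: SyntheticConfig, records, truth_series):
    """Build the complete binary profiling matrix with planted structure.

    Returns ``(matrix, ground_truth)``; the ground truth records the test
    assays, profile assays, planted (test -> profile, epsilon) pairs and
    the disjoint AC-series block of each test assay.
    """
    rng = np.random.default_rng([cfg.seed, 202])
    compound_ids = [r.compound_id for r in records]
    n_compounds = len(compound_ids)
    assay_ids = [f"A{j:03d}" for j in range(cfg.n_assays)]

    assay_order = rng.permutation(cfg.n_assays)
    test_assays = sorted(assay_ids[j] for j in assay_order[: cfg.n_test_assays])
    profile_assays = sorted(set(assay_ids) - set(test_assays))
    col = {a: assay_ids.index(a) for a in assay_ids}
    row = {c: i for i, c in enumerate(compound_ids)}

    # Disjoint AC-series blocks per test assay.
    series_ids = sorted(truth_series)
    n_ac = int(round(cfg.ac_fraction * len(series_ids)))
    if n_ac < cfg.n_test_assays:
        raise InputError("fewer AC-forming series than test assays")
    ac_pool = [series_ids[i] for i in rng.permutation(len(series_ids))[:n_ac]]

    # Background: AC-series compounds are screening actives and hence more
    # promiscuous than the rest of the library; their background cells use
    # ac_background_rate, everything else base_active_rate.
    ac_members = {cid for sid in ac_pool for cid in truth_series[sid]}
    rates = np.full(n_compounds, cfg.base_active_rate)
    rates[[row[c] for c in ac_members]] = cfg.ac_background_rate
    values = (rng.random((n_compounds, cfg.n_assays))
              < rates[:, None]).astype(np.uint8)
    blocks: dict[str, list] = {t: [] for t in test_assays}
    for i, sid in enumerate(ac_pool):
        blocks[test_assays[i % cfg.n_test_assays]].append(sid)

    for t, sids in blocks.items():
        for sid in sids:
            members = truth_series[sid]
            if len(members) < 2:
                raise InputError(f"series {sid} too small for mixed labels")
            k_active = int(rng.integers(1, len(members)))
            actives = rng.choice(len(members), size=k_active, replace=False)
            labels = np.zeros(len(members), dtype=np.uint8)
            labels[actives] = 1
            for cid, lab in zip(members, labels):
                values[row[cid], col[t]] = lab

    planted: dict[str, tuple] = {}
    free_profile = [a for a in profile_assays]
    pick = rng.permutation(len(free_profile))
    for slot, (test_idx, eps) in enumerate(sorted(cfg.effective_planted.items())):
        t = test_assays[test_idx]
        p = free_profile[pick[slot]]
        flips = rng.random(n_compounds) < eps
        values[:, col[p]] = values[:, col[t]] ^ flips.astype(np.uint8)
        planted[t] = (p, eps)

    frame = pd.DataFrame(values, index=pd.Index(compound_ids, name="compound_id"),
                         columns=assay_ids)
    ground_truth = {
        "test_assays": test_assays,
        "profile_assays": profile_assays,
        "planted": planted,
        "ac_series": {t: sorted(b) for t, b in blocks.items()},
    }
    return ProfilingMatrix(frame), ground_truth


def generate(cfg: SyntheticConfig):
    """Library + matrix in one call: (records, truth_series, matrix, truth)."""
    records, truth_series = generate_library(cfg)
    matrix, ground_truth = generate_matrix(cfg, records, truth_series)
    return records, truth_series, matrix, ground_truth
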