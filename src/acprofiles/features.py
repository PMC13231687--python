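"""Compound representations: bioactivity profiles, ECFP4, and combinations.

A compound's bioactivity profile is its row of binary outcomes over the
profile assays (the test assay is never a feature).  Reduced profiles keep
only the k assays most similar to the test assay (computed on training
compounds) or a random size-matched control.  The structural representation
is the standard folded Morgan/circular fingerprint with radius 2 ("ECFP4")
hashed to 2048 bits; the combined representation concatenates profile
features first, fingerprint bits second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import InputError, LeakageError
from .matrix import AssaySimilarityRanking, ProfilingMatrix

__all__ = [
    "ECFP4_BITS",
    "Representation",
    "profile_vector",
    "ecfp4_vector",
    "combined_vector",
    "reduce_profile",
    "feature_matrix",
]

ECFP4_BITS = 2048

PROFILE_KINDS = ("profile_all", "profile_top50", "profile_top10",
                 "profile_rand50", "profile_rand10")
KINDS = PROFILE_KINDS + ("ecfp4", "combined")

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=ECFP4_BITS)


@dataclass(frozen=True)
class Representation:
    """A named feature layout: ordered feature ids and total length."""

    kind: str
    feature_ids: tuple
    vector_length: int

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InputError(f"unknown representation kind {self.kind!r}")
        if len(self.feature_ids) != self.vector_length:
            raise InputError("feature_ids length does not match vector_length")


def profile_vector(
    m: ProfilingMatrix,
    compound_id: str,
    profile_assays: Sequence,
    test_assay: Optional[str] = None,
) -> np.ndarray:
    """The compound's binary profile over ``profile_assays``, in order."""
    if test_assay is not None and test_assay in profile_assays:
        raise LeakageError(
            f"test assay {test_assay!r} must not be a profile feature"
        )
    return np.array(
        [m._read_cells([compound_id], a)[0] for a in profile_assays],
        dtype=np.uint8,
    )


def ecfp4_vector(smiles: str) -> np.ndarray:
    """Folded circular fingerprint, radius 2, 2048 bits."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    return np.asarray(_morgan.GetFingerprint(mol), dtype=np.uint8)


def combined_vector(profile: np.ndarray, fp: np.ndarray,
                    representation: Optional[Representation] = None) -> np.ndarray:
    """Concatenate profile features first, fingerprint bits second."""
    out = np.concatenate([np.asarray(profile, dtype=np.uint8),
                          np.asarray(fp, dtype=np.uint8)])
    if representation is not None and len(out) != representation.vector_length:
        raise InputError(
            f"combined length {len(out)} != declared {representation.vector_length}"
        )
    return out


def reduce_profile(
    ranking: AssaySimilarityRanking,
    mode: str,
    k: int,
    seed: Optional[int] = None,
) -> tuple:
    """Select k profile assays: the top-k most similar, or a random control.

    ``top_k`` takes the first k ranking entries (so top-10 is nested in
    top-50% is nested in the full profile).  ``random_k`` samples k assays
    without replacement from all ranked profile assays under ``seed``; the
    selection is returned in ascending assay_id order.
    """
    if k > len(ranking.entries):
        raise InputError(f"k={k} exceeds {len(ranking.entries)} profile assays")
    if mode == "top_k":
        return ranking.top(k)
    if mode == "random_k":
        rng = np.random.default_rng(seed)
        pool = sorted(ranking.assay_ids)
        picked = rng.choice(len(pool), size=k, replace=False)
        return tuple(pool[i] for i in sorted(picked))
    raise InputError(f"unknown reduction mode {mode!r}")


def feature_matrix(
    kind: str,
    compounds: Sequence[str],
    m: Optional[ProfilingMatrix] = None,
    profile_assays: Optional[Sequence] = None,
    smiles_by_id: Optional[dict] = None,
    test_assay: Optional[str] = None,
) -> tuple[np.ndarray, Representation]:
    """Stack one representation for a list of compounds into an X matrix."""
    needs_profile = kind in PROFILE_KINDS or kind == "combined"
    needs_fp = kind in ("ecfp4", "combined")
    if needs_profile and (m is None or profile_assays is None):
        raise InputError(f"{kind} requires a matrix and profile assays")
    if needs_fp and smiles_by_id is None:
        raise InputError(f"{kind} requires compound structures")

    blocks = []
    feature_ids: tuple = ()
    if needs_profile:
        blocks.append(np.stack([
            profile_vector(m, c, profile_assays, test_assay=test_assay)
            for c in compounds
        ]))
        feature_ids += tuple(profile_assays)
    if needs_fp:
        blocks.append(np.stack([ecfp4_vector(smiles_by_id[c]) for c in compounds]))
        feature_ids += tuple(f"bit_{i}" for i in range(ECFP4_BITS))
    X = np.concatenate(blocks, axis=1) if len(blocks) > 1 else blocks[0]
    rep = Representation(kind=kind, feature_ids=feature_ids,
                         vector_length=X.shape[1])
    return X, rep
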