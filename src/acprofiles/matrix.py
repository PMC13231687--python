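"""The complete binary compound-profiling matrix and assay similarity.

Rows are compounds ("bioactivity profiles"), columns are assays ("activity
vectors"), cells are binary active/inactive outcomes with no missing values.
Assay-assay similarity is the Tanimoto coefficient of active-compound sets,
optionally restricted to a compound subset — in leakage-controlled
experiments that restriction is the training compounds of the current test
assay, so similarity rankings never look at test compounds.

All cell reads funnel through :meth:`ProfilingMatrix._read_cells`, which
lets tests substitute an access-instrumented subclass to audit that no code
path touches cells it must not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "ProfilingMatrix",
    "AssaySimilarityRanking",
    "SparsitySummary",
    "load_matrix",
    "drop_all_inactive_compounds",
    "active_set",
    "assay_tanimoto",
    "rank_profile_assays",
    "summarize_sparsity",
]


@dataclass(frozen=True)
class AssaySimilarityRanking:
    """Profile assays ranked by Tanimoto similarity to one test assay."""

    test_assay: str
    entries: tuple  # of (profile_assay_id, tanimoto), descending similarity
    restriction: frozenset

    @property
    def assay_ids(self) -> tuple:
        return tuple(a for a, _ in self.entries)

    def top(self, k: int) -> tuple:
        if k > len(self.entries):
            raise InputError(
                f"requested top {k} of only {len(self.entries)} ranked assays"
            )
        return tuple(a for a, _ in self.entries[:k])


@dataclass(frozen=True)
class SparsitySummary:
    """Per-assay active-fraction statistics, in percent."""

    median_pct: float
    mean_pct: float
    sd_pct: float


class ProfilingMatrix:
    """Complete compounds x assays binary table."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise InputError(f"duplicate compound_id {dup!r}")
        if frame.columns.has_duplicates:
            dup = frame.columns[frame.columns.duplicated()][0]
            raise InputError(f"duplicate assay_id {dup!r}")
        if frame.isna().any().any():
            rows = frame.index[frame.isna().any(axis=1)]
            cols = frame.columns[frame.isna().any(axis=0)]
            raise InputError(
                f"missing cell(s), e.g. compound {rows[0]!r} / assay {cols[0]!r}"
            )
        values = frame.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise InputError(
                f"non-binary cell {values[r, c]!r} at compound "
                f"{frame.index[r]!r} / assay {frame.columns[c]!r}"
            )
        self._frame = frame.astype(np.uint8)
        self._values = self._frame.to_numpy()
        self._row_pos = {cid: i for i, cid in enumerate(frame.index)}
        self._col_pos = {aid: j for j, aid in enumerate(frame.columns)}

    # ---- basic introspection -------------------------------------------
    @property
    def compound_ids(self) -> tuple:
        return tuple(self._frame.index)

    @property
    def assay_ids(self) -> tuple:
        return tuple(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    # ---- the single cell accessor --------------------------------------
    def _read_cells(self, compound_ids: Sequence, assay_id) -> np.ndarray:
        """Return the binary values of one assay column for given compounds.

        Every read in the package goes through here; instrumented subclasses
        override it to record accesses for leakage audits.
        """
        if assay_id not in self._col_pos:
            raise InputError(f"unknown assay {assay_id!r}")
        try:
            rows = [self._row_pos[c] for c in compound_ids]
        except KeyError as exc:
            raise InputError(f"unknown compound {exc.args[0]!r}") from None
        return self._values[rows, self._col_pos[assay_id]]

    def labels(self, assay_id, compound_ids: Sequence) -> dict:
        vals = self._read_cells(compound_ids, assay_id)
        return {c: int(v) for c, v in zip(compound_ids, vals)}

    # ---- operations -----------------------------------------------------
    def drop_all_inactive(self) -> "ProfilingMatrix":
        """Remove compounds inactive in every assay (idempotent)."""
        keep = self._values.any(axis=1)
        out = ProfilingMatrix.__new__(ProfilingMatrix)
        frame = self._frame.loc[keep]
        out._frame = frame
        out._values = frame.to_numpy()
        out._row_pos = {cid: i for i, cid in enumerate(frame.index)}
        out._col_pos = dict(self._col_pos)
        return out

    def active_set(self, assay_id, restriction: Optional[Iterable] = None) -> frozenset:
        """Compounds active in one assay, within an optional restriction."""
        ids = self.compound_ids if restriction is None else sorted(restriction)
        vals = self._read_cells(ids, assay_id)
        return frozenset(c for c, v in zip(ids, vals) if v == 1)

    def assay_tanimoto(self, a, b, restriction: Optional[Iterable] = None) -> float:
        """Tanimoto similarity |A n B| / |A u B| of two assays' active sets.

        Both all-empty active sets give 0 (no shared evidence), keeping
        rankings total.
        """
        sa = self.active_set(a, restriction)
        sb = self.active_set(b, restriction)
        union = len(sa | sb)
        return len(sa & sb) / union if union else 0.0

    def rank_profile_assays(
        self,
        test_assay,
        profile_assays: Sequence,
        train_compounds: Iterable,
    ) -> AssaySimilarityRanking:
        """Rank all profile assays by similarity to the test assay.

        Similarity is computed on training compounds only; ties break by
        ascending assay_id so rankings are reproducible.
        """
        profile_assays = list(profile_assays)
        if test_assay in profile_assays:
            raise InputError("test assay must not appear among profile assays")
        train = sorted(set(train_compounds))
        if not train:
            raise InputError("train_compounds must be non-empty")
        test_active = self.active_set(test_assay, train)
        sims = []
        for assay in profile_assays:
            s = self.active_set(assay, train)
            union = len(test_active | s)
            sims.append((assay, len(test_active & s) / union if union else 0.0))
        sims.sort(key=lambda t: (-t[1], t[0]))
        return AssaySimilarityRanking(
            test_assay=test_assay, entries=tuple(sims), restriction=frozenset(train)
        )

    def summarize_sparsity(self) -> SparsitySummary:
        """Median / mean / sample-SD of per-assay active fractions (percent)."""
        fractions = self._frame.to_numpy().mean(axis=0) * 100.0
        sd = float(np.std(fractions, ddof=1)) if len(fractions) > 1 else 0.0
        return SparsitySummary(
            median_pct=float(np.median(fractions)),
            mean_pct=float(np.mean(fractions)),
            sd_pct=sd,
        )

    # ---- I/O -------------------------------------------------------------
    @classmethod
    def load(cls, path) -> "ProfilingMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if frame.index.isna().any() or frame.isna().any().any():
            raise InputError(f"{path}: missing cell or compound_id")
        try:
            frame = frame.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path}: non-numeric cell ({exc})") from None
        return cls(frame)

    def save(self, path) -> None:
        self._frame.to_csv(path, sep="\t", index_label="compound_id")


# Function-style aliases for the object methods above.

def load_matrix(path) -> ProfilingMatrix:
    return ProfilingMatrix.load(path)


def drop_all_inactive_compounds(m: ProfilingMatrix) -> ProfilingMatrix:
    return m.drop_all_inactive()


def active_set(m: ProfilingMatrix, assay_id, restriction=None) -> frozenset:
    return m.active_set(assay_id, restriction)


def assay_tanimoto(m: ProfilingMatrix, a, b, restriction=None) -> float:
    return m.assay_tanimoto(a, b, restriction)


def rank_profile_assays(m, test_assay, profile_assays, train_compounds):
    return m.rank_profile_assays(test_assay, profile_assays, train_compounds)


def summarize_sparsity(m: ProfilingMatrix) -> SparsitySummary:
    return m.summarize_sparsity()


def write_ranking(ranking: AssaySimilarityRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("test_assay\trank\tprofile_assay\ttanimoto\n")
        for rank, (assay, sim) in enumerate(ranking.entries, 1):
            fh.write(f"{ranking.test_assay}\t{rank}\t{assay}\t{sim:.6f}\n")
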