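"""Leakage-controlled train/test partitioning over matching molecular series.

Two schemes, both operating only on series that form activity cliffs in the
test assay (i.e. contain both labels):

* intra-series: per series, a coin flip sends all actives to one partition
  and all inactives to the other.  Training never sees analogs of one series
  with different labels, but the test set contains analogs of training
  compounds with the *opposite* label — the hard scenario.
* series-unit: each whole series goes to exactly one partition, targeting an
  80:20 train:test compound ratio.  No structural analog of any test
  compound is seen during training.

A compound can belong to several series.  Series are processed in a seeded
random order; a compound keeps its first assignment, and any later series
whose invariant would be violated by a pinned compound is dropped (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chem import MMS
from .errors import InputError

__all__ = [
    "SplitAssignment",
    "intra_series_split",
    "series_unit_split",
    "class_weights",
    "exclude_silent_series",
    "write_split",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitAssignment:
    """A train/test partition of AC-series members for one test assay."""

    test_assay: str
    scheme: str  # "intra_series" | "series_unit"
    train: dict  # compound_id -> label
    test: dict  # compound_id -> label
    series_map: dict  # compound_id -> tuple of series_ids
    seed: int
    n_excluded_series: int = 0  # series without both labels
    dropped_series: tuple = ()  # series dropped by pinned-compound conflicts

    @property
    def train_ids(self) -> tuple:
        return tuple(sorted(self.train))

    @property
    def test_ids(self) -> tuple:
        return tuple(sorted(self.test))


def _mixed_series(mms_list: Sequence[MMS], assay_labels: Mapping[str, int]):
    """Split series into AC-forming (both labels) and label-homogeneous."""
    mixed, pure = [], []
    for s in mms_list:
        labels = {cid: assay_labels[cid] for cid in s.member_ids}
        if 0 < sum(labels.values()) < len(labels):
            mixed.append((s, labels))
        else:
            pure.append(s)
    return mixed, pure


def _series_map(assigned_series) -> dict:
    out: dict[str, list] = {}
    for s in assigned_series:
        for cid in s.member_ids:
            out.setdefault(cid, []).append(s.series_id)
    return {cid: tuple(sorted(v)) for cid, v in out.items()}


def intra_series_split(
    mms_list: Sequence[MMS],
    assay_labels: Mapping[str, int],
    seed: int,
    test_assay: str = "",
) -> SplitAssignment:
    """Per-series orientation split: actives one side, inactives the other.

    The orientation (actives->train or actives->test) is drawn with
    probability 0.5 per series under ``seed``.  Series lacking either label
    are excluded (counted); series that cannot honor an already-pinned
    compound are dropped.
    """
    rng = np.random.default_rng(seed)
    mixed, pure = _mixed_series(mms_list, assay_labels)
    if pure:
        logger.info("intra_series_split: excluded %d series without both labels",
                    len(pure))
    order = rng.permutation(len(mixed))
    orientations = rng.random(len(mixed)) < 0.5  # True: actives -> train

    assignment: dict[str, str] = {}  # compound_id -> "train" | "test"
    train: dict[str, int] = {}
    test: dict[str, int] = {}
    kept, dropped = [], []
    for pos in order:
        series, labels = mixed[pos]
        actives_to_train = bool(orientations[pos])
        wanted = {
            cid: ("train" if (lab == 1) == actives_to_train else "test")
            for cid, lab in labels.items()
        }
        if any(assignment.get(cid, part) != part for cid, part in wanted.items()):
            dropped.append(series.series_id)
            continue
        for cid, part in wanted.items():
            assignment[cid] = part
            (train if part == "train" else test)[cid] = labels[cid]
        kept.append(series)
    if dropped:
        logger.info("intra_series_split: dropped %d conflicting series", len(dropped))
    return SplitAssignment(
        test_assay=test_assay, scheme="intra_series", train=train, test=test,
        series_map=_series_map(kept), seed=seed,
        n_excluded_series=len(pure), dropped_series=tuple(sorted(dropped)),
    )


def _closest_subset_sum(sizes: np.ndarray, target: float, rng) -> np.ndarray:
    """Pick a proper, non-empty subset of series whose total size is as
    close as possible to ``target``; random among optimal realisations.

    Boolean reachability over prefix items, then a backtrack that chooses
    include/exclude at random wherever both can still realise the optimum.
    """
    total = int(sizes.sum())
    n = len(sizes)
    reach = np.zeros((n + 1, total + 1), dtype=bool)
    reach[0, 0] = True
    for i, size in enumerate(sizes):
        reach[i + 1] = reach[i]
        reach[i + 1, size:] |= reach[i, : total + 1 - size]
    candidates = np.flatnonzero(reach[n])
    candidates = candidates[(candidates > 0) & (candidates < total)]
    if len(candidates) == 0:
        raise InputError("cannot form two non-empty partitions")
    best = candidates[np.argmin(np.abs(candidates - target))]
    # ties between equally close sums: argmin picks the smaller; acceptable.
    chosen = np.zeros(n, dtype=bool)
    remaining = int(best)
    for i in range(n - 1, -1, -1):
        size = int(sizes[i])
        can_skip = reach[i, remaining]
        can_take = remaining >= size and reach[i, remaining - size]
        take = can_take if not can_skip else (can_take and rng.random() < 0.5)
        if take:
            chosen[i] = True
            remaining -= size
    assert remaining == 0
    return chosen


def series_unit_split(
    mms_list: Sequence[MMS],
    assay_labels: Mapping[str, int],
    ratio: float = 0.8,
    seed: int = 0,
    test_assay: str = "",
) -> SplitAssignment:
    """Whole-series split targeting a ``ratio`` train fraction of compounds.

    Series are shuffled under ``seed``; overlap conflicts resolve by
    first-assignment pinning (a later series all of whose pinned members
    already sit in one partition follows them; mixed pins drop the series).
    The train compound count is the closest achievable to ``ratio`` x total.
    """
    rng = np.random.default_rng(seed)
    mixed, pure = _mixed_series(mms_list, assay_labels)
    if len(mixed) < 2:
        raise InputError("series_unit_split needs at least 2 AC-forming series")
    if pure:
        logger.info("series_unit_split: excluded %d series without both labels",
                    len(pure))
    order = rng.permutation(len(mixed))

    # Resolve compound overlap first: pin compounds in shuffled series order,
    # dropping series whose pinned members would straddle partitions later.
    shuffled = [mixed[i] for i in order]
    sizes = np.array([len(s.member_ids) for s, _ in shuffled])
    target = ratio * sizes.sum()
    chosen = _closest_subset_sum(sizes, target, rng)

    assignment: dict[str, str] = {}
    train: dict[str, int] = {}
    test: dict[str, int] = {}
    kept, dropped = [], []
    for (series, labels), to_train in zip(shuffled, chosen):
        part = "train" if to_train else "test"
        pinned = {assignment[cid] for cid in labels if cid in assignment}
        if pinned == {("test" if part == "train" else "train")}:
            part = pinned.pop()  # follow unanimous pins to keep series whole
        if any(assignment.get(cid, part) != part for cid in labels):
            dropped.append(series.series_id)
            continue
        for cid, lab in labels.items():
            assignment[cid] = part
            (train if part == "train" else test)[cid] = lab
        kept.append(series)
    if dropped:
        logger.info("series_unit_split: dropped %d conflicting series", len(dropped))
    if not train or not test:
        raise InputError("series_unit_split produced an empty partition")
    return SplitAssignment(
        test_assay=test_assay, scheme="series_unit", train=train, test=test,
        series_map=_series_map(kept), seed=seed,
        n_excluded_series=len(pure), dropped_series=tuple(sorted(dropped)),
    )


def class_weights(labels: Sequence[int]) -> dict:
    """Inverse-frequency class weights, n_total / (2 * n_label)."""
    labels = list(labels)
    n_pos = sum(1 for x in labels if x == 1)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InputError("class_weights requires both labels present")
    n = len(labels)
    return {1: n / (2 * n_pos), 0: n / (2 * n_neg)}


def exclude_silent_series(
    mms_list: Sequence[MMS],
    matrix,
    profile_assays: Sequence,
    drop_whole_series: bool = True,
) -> list[MMS]:
    """Remove series containing compounds with all-inactive profiles.

    A compound whose bioactivity profile (over ``profile_assays``) is all
    zero carries no profile information.  By default the whole series is
    removed when any member is silent; ``drop_whole_series=False`` instead
    removes only the silent members (the series survives if >=2 remain).
    """
    profile_assays = list(profile_assays)
    if not profile_assays:
        raise InputError("profile_assays must be non-empty")

    silent_cache: dict[str, bool] = {}

    def is_silent(cid) -> bool:
        if cid not in silent_cache:
            silent_cache[cid] = all(
                matrix._read_cells([cid], a)[0] == 0 for a in profile_assays
            )
        return silent_cache[cid]

    out = []
    n_removed = 0
    for s in mms_list:
        silent = {cid for cid in s.member_ids if is_silent(cid)}
        if not silent:
            out.append(s)
        elif drop_whole_series:
            n_removed += 1
        else:
            members = tuple(m for m in s.members if m[0] not in silent)
            if len({cid for cid, _ in members}) >= 2:
                out.append(MMS(series_id=s.series_id, core_key=s.core_key,
                               members=members))
            else:
                n_removed += 1
    if n_removed:
        logger.info("exclude_silent_series: removed %d of %d series",
                    n_removed, len(mms_list))
    return out


def write_split(split: SplitAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("test_assay\tscheme\tseed\tcompound_id\tseries_id\tpartition\tlabel\n")
        for part, members in (("train", split.train), ("test", split.test)):
            for cid in sorted(members):
                series = ";".join(split.series_map.get(cid, ()))
                fh.write(f"{split.test_assay}\t{split.scheme}\t{split.seed}\t"
                         f"{cid}\t{series}\t{part}\t{members[cid]}\n")
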