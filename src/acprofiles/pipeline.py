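"""End-to-end experiment orchestration.

A run takes a compound library and a complete profiling matrix (real or
synthetic), extracts matching molecular series and activity cliffs, selects
hold-out test assays, and then sweeps every (test assay x scheme x
representation x algorithm) cell: leakage-controlled split, feature
construction, training, prediction, metrics — plus the 1-NN assay-transfer
control per test assay, MDI importances for forests, MCC-quartile grouping
and paired significance statistics.  All outputs are TSV files plus a
manifest with checksums and the seeds used.

Per-cell seeds derive from the master seed by stable hashing so cells are
independent yet the whole run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import (MMS, ac_compounds_per_assay, build_mms, fragment_molecule,
                   read_smiles_file)
from .errors import InputError
from .matrix import ProfilingMatrix
from .metrics import AssayResult, group_by_mcc, paired_wilcoxon_holm
from .modeling import AssayPredictionModel, one_nn_transfer
from .metrics import ConfusionCounts, balanced_accuracy
from .splits import exclude_silent_series, intra_series_split
from . import synth

__all__ = ["ExperimentConfig", "select_test_assays", "run_experiment",
           "derive_seed", "extract_series", "planted_nn_benchmark"]

logger = logging.getLogger(__name__)


def derive_seed(master: int, *parts) -> int:
    """Stable per-cell seed below 2**31 from the master seed and cell id."""
    key = "|".join([str(master), *map(str, parts)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class ExperimentConfig:
    """Configuration of one full experiment run."""

    matrix_path: Optional[str] = None
    smiles_path: Optional[str] = None
    synthetic: Optional[dict] = None  # SyntheticConfig fields
    n_test_assays: int = 50
    min_ac_compounds: int = 500
    schemes: tuple = ("intra_series", "series_unit")
    representations: tuple = ("profile_all", "ecfp4", "combined")
    algos: tuple = ("RF", "XGB", "SVM")
    seed: int = 0
    grid: Optional[dict] = None  # per-algo grid overrides
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for key in ("schemes", "representations", "algos"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def select_test_assays(
    matrix: ProfilingMatrix,
    mms_list: Sequence[MMS],
    min_ac_compounds: int,
    n: int,
    seed: int,
) -> tuple[list, list]:
    """Sample n eligible hold-out assays; the rest form the profile."""
    ac_compounds = ac_compounds_per_assay(mms_list, matrix)
    eligible = sorted(a for a, c in ac_compounds.items()
                      if len(c) >= min_ac_compounds)
    if len(eligible) < n:
        counts = {a: len(c) for a, c in sorted(ac_compounds.items())}
        raise InputError(
            f"only {len(eligible)} assays have >= {min_ac_compounds} unique "
            f"AC compounds (need {n}); AC-compound counts: {counts}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n, replace=False)
    test_assays = sorted(eligible[i] for i in picked)
    profile_assays = sorted(set(matrix.assay_ids) - set(test_assays))
    return test_assays, profile_assays


def extract_series(records, max_heavy: int = 60, ratio_threshold: float = 0.2,
                   max_cuts: int = 1) -> list[MMS]:
    """Fragment a library and assemble its matching molecular series."""
    frags = []
    for rec in records:
        frags.extend(fragment_molecule(rec, max_heavy=max_heavy,
                                       ratio_threshold=ratio_threshold,
                                       max_cuts=max_cuts))
    return build_mms(frags)


def _one_nn_result(matrix, mms_list, test_assay, profile_assays, seed):
    """1-NN label transfer under the intra-series split for one assay."""
    members = sorted({c for s in mms_list for c in s.member_ids})
    labels = matrix.labels(test_assay, members)
    split = intra_series_split(mms_list, labels, seed, test_assay=test_assay)
    predicted = one_nn_transfer(matrix, test_assay, profile_assays,
                                split.train_ids, split.test_ids)
    y_true = [split.test[c] for c in sorted(split.test)]
    y_pred = [predicted[c] for c in sorted(split.test)]
    from .metrics import mcc as _mcc, roc_auc as _auc
    c = ConfusionCounts.from_predictions(y_true, y_pred)
    return AssayResult(
        test_assay=test_assay, scheme="intra_series", representation="1nn",
        algo="1NN", ba=balanced_accuracy(c),
        roc_auc=_auc([float(p) for p in y_pred], y_true), mcc=_mcc(c),
    )


def _ac_series_for_assay(matrix, mms_list, assay_id) -> list[MMS]:
    out = []
    for s in mms_list:
        labels = matrix.labels(assay_id, sorted(s.member_ids))
        if 0 < sum(labels.values()) < len(labels):
            out.append(s)
    return out


def run_experiment(cfg: ExperimentConfig):
    """Execute the full sweep and write results + manifest to output_dir.

    Returns a dict with the results DataFrame, 1-NN results, groupings and
    statistics.  Failed cells are logged and reported with NaN metrics.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.synthetic is not None:
        scfg = synth.SyntheticConfig(**{**cfg.synthetic, "seed": cfg.seed})
        records, truth_series, matrix, ground_truth = synth.generate(scfg)
    else:
        if cfg.matrix_path is None or cfg.smiles_path is None:
            raise InputError("need matrix_path and smiles_path, or synthetic config")
        matrix = ProfilingMatrix.load(cfg.matrix_path)
        records = read_smiles_file(cfg.smiles_path)
        ground_truth = None
    matrix = matrix.drop_all_inactive()
    records = [r for r in records if r.compound_id in set(matrix.compound_ids)]
    smiles_by_id = {r.compound_id: r.smiles for r in records}

    mms_list = extract_series(records)
    test_assays, profile_assays = select_test_assays(
        matrix, mms_list, cfg.min_ac_compounds, cfg.n_test_assays, cfg.seed
    )
    mms_list = exclude_silent_series(mms_list, matrix, profile_assays)

    rows, onenn_rows = [], []
    importance_rows = []
    for assay in test_assays:
        assay_series = _ac_series_for_assay(matrix, mms_list, assay)
        seed_nn = derive_seed(cfg.seed, assay, "intra_series", "1nn")
        try:
            onenn_rows.append(_one_nn_result(matrix, assay_series, assay,
                                             profile_assays, seed_nn))
        except Exception as exc:
            logger.warning("1-NN failed for assay %s: %s", assay, exc)
        for scheme in cfg.schemes:
            for representation in cfg.representations:
                for algo in cfg.algos:
                    cell_seed = derive_seed(cfg.seed, assay, scheme,
                                            representation, algo)
                    grid = (cfg.grid or {}).get(algo)
                    try:
                        model = AssayPredictionModel(
                            matrix, assay_series, assay, profile_assays,
                            scheme, representation, algo,
                            smiles_by_id=smiles_by_id, grid=grid,
                        )
                        res = model.fit(cell_seed)
                        rows.append(AssayResult(
                            test_assay=assay, scheme=scheme,
                            representation=representation, algo=algo,
                            ba=res.ba, roc_auc=res.roc_auc, mcc=res.mcc,
                        ))
                        if res.importances is not None:
                            top = res.importances.as_series().nlargest(30)
                            for fid, v in top.items():
                                importance_rows.append({
                                    "test_assay": assay, "scheme": scheme,
                                    "representation": representation,
                                    "feature_id": fid, "mdi": v,
                                })
                    except Exception as exc:
                        logger.warning("cell failed (%s/%s/%s/%s): %s", assay,
                                       scheme, representation, algo, exc)
                        rows.append(AssayResult(
                            test_assay=assay, scheme=scheme,
                            representation=representation, algo=algo,
                            ba=float("nan"), roc_auc=float("nan"),
                            mcc=float("nan"),
                        ))

    grouped = group_by_mcc([r for r in rows if not np.isnan(r.mcc)])
    results = pd.DataFrame([vars(r) for r in grouped] +
                           [vars(r) for r in rows if np.isnan(r.mcc)])
    onenn = pd.DataFrame([vars(r) for r in onenn_rows])

    stats_frames = []
    for (scheme, algo), sub in results.groupby(["scheme", "algo"]):
        pivot = sub.pivot_table(index="test_assay", columns="representation",
                                values="ba")
        complete = pivot.dropna()
        if len(complete) >= 5 and pivot.shape[1] >= 2:
            by_kind = {k: complete[k] for k in complete.columns}
            stats = paired_wilcoxon_holm(by_kind)
            stats.insert(0, "algo", algo)
            stats.insert(0, "scheme", scheme)
            stats_frames.append(stats)
    statistics = (pd.concat(stats_frames, ignore_index=True)
                  if stats_frames else pd.DataFrame())

    importances = pd.DataFrame(importance_rows)
    files = {
        "results.tsv": results,
        "one_nn.tsv": onenn,
        "statistics.tsv": statistics,
        "importances.tsv": importances,
    }
    for name, frame in files.items():
        frame.to_csv(outdir / name, sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in vars(cfg).items()},
        "test_assays": list(test_assays),
        "n_profile_assays": len(profile_assays),
        "files": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return {
        "results": results, "one_nn": onenn, "statistics": statistics,
        "importances": importances, "test_assays": test_assays,
        "profile_assays": profile_assays, "ground_truth": ground_truth,
        "matrix": matrix, "mms_list": mms_list, "smiles_by_id": smiles_by_id,
    }


# ---------------------------------------------------------------------------
# Planted nearest-neighbor benchmark
# ---------------------------------------------------------------------------

BENCH_GRID = {  # single-candidate grids keep the sweep cheap
    "RF": {"n_estimators": [200], "max_depth": [None]},
    "XGB": {"n_estimators": [100], "max_depth": [6], "learning_rate": [0.3]},
    "SVM": {"C": [10.0], "gamma": ["scale"]},
}


def planted_nn_benchmark(
    seed: int,
    representations=("profile_all", "profile_top10", "profile_rand10", "ecfp4"),
    algo: str = "RF",
    include_series_unit: bool = True,
    synthetic_overrides: Optional[dict] = None,
):
    """Run the assay-similarity benchmark on planted synthetic data.

    Generates the default synthetic study (test assays with and without a
    planted nearest-neighbor profile assay at flip rate 0.1), then for every
    test assay runs 1-NN label transfer and one classifier per
    representation under the intra-series split (optionally also the
    series-unit split on the full profile).  The same per-assay split seed
    is used for all representations so differences reflect the features
    alone, mirroring how representations are compared on fixed partitions.

    Returns a dict with the per-assay results table, the pooled 1-NN
    transfer counts on planted assays, and the generator ground truth.
    """
    scfg = synth.SyntheticConfig(**{**(synthetic_overrides or {}),
                                    "seed": derive_seed(seed, "synth")})
    records, truth_series, matrix, gt = synth.generate(scfg)
    smiles_by_id = {r.compound_id: r.smiles for r in records}
    mms_list = extract_series(records)
    test_assays = gt["test_assays"]
    profile_assays = gt["profile_assays"]
    mms_list = exclude_silent_series(mms_list, matrix, profile_assays)

    rows = []
    nn_correct = nn_total = 0
    for assay in test_assays:
        assay_series = _ac_series_for_assay(matrix, mms_list, assay)
        members = sorted({c for s in assay_series for c in s.member_ids})
        labels = matrix.labels(assay, members)
        split_seed = derive_seed(seed, assay, "intra")
        split = intra_series_split(assay_series, labels, split_seed,
                                   test_assay=assay)

        predicted = one_nn_transfer(matrix, assay, profile_assays,
                                    split.train_ids, split.test_ids)
        y_true = [split.test[c] for c in sorted(split.test)]
        y_pred = [predicted[c] for c in sorted(split.test)]
        if assay in gt["planted"]:
            nn_correct += sum(a == b for a, b in zip(y_true, y_pred))
            nn_total += len(y_true)
        c = ConfusionCounts.from_predictions(y_true, y_pred)
        from .metrics import mcc as _mcc
        rows.append({"test_assay": assay, "scheme": "intra_series",
                     "representation": "1nn", "algo": "1NN",
                     "ba": balanced_accuracy(c), "mcc": _mcc(c),
                     "planted": assay in gt["planted"]})

        for representation in representations:
            model = AssayPredictionModel(
                matrix, assay_series, assay, profile_assays, "intra_series",
                representation, algo, smiles_by_id=smiles_by_id,
                grid=BENCH_GRID[algo],
            )
            res = model.fit(split_seed)
            rows.append({"test_assay": assay, "scheme": "intra_series",
                         "representation": representation, "algo": algo,
                         "ba": res.ba, "mcc": res.mcc,
                         "planted": assay in gt["planted"]})
        if include_series_unit:
            model = AssayPredictionModel(
                matrix, assay_series, assay, profile_assays, "series_unit",
                "profile_all", algo, smiles_by_id=smiles_by_id,
                grid=BENCH_GRID[algo],
            )
            res = model.fit(derive_seed(seed, assay, "unit"))
            rows.append({"test_assay": assay, "scheme": "series_unit",
                         "representation": "profile_all", "algo": algo,
                         "ba": res.ba, "mcc": res.mcc,
                         "planted": assay in gt["planted"]})

    results = pd.DataFrame(rows)
    return {
        "results": results,
        "nn_correct": nn_correct,
        "nn_total": nn_total,
        "ground_truth": gt,
        "config": scfg,
    }
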