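"""Classifiers, the 1-NN assay-transfer baseline, and MDI feature importance.

Three model families are supported — random forest (RF), extreme gradient
boosting (XGB) and an RBF-kernel support vector machine (SVM) — each tuned
by grid search under stratified five-fold cross-validation with balanced
accuracy as the selection metric, refit on the full training partition with
inverse-frequency class weights.

The 1-NN control bypasses learning entirely: it finds the profile assay
most similar (active-set Tanimoto on training compounds) to the test assay
and copies that assay's labels onto the test compounds.

Feature importance for forests is the mean decrease in impurity (MDI):
for feature X_m, sum p(t) * [i(t) - p_L i(t_L) - p_R i(t_R)] over all nodes
t splitting on X_m, average over trees, normalize to sum 1.

:class:`AssayPredictionModel` bundles one experiment cell (test assay x
split scheme x representation x algorithm) statsmodels-style: construct it
from the data, call :meth:`fit`, read metrics off the returned
:class:`AssayPredictionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import features as feat
from . import splits as sp
from .errors import InputError
from .matrix import ProfilingMatrix
from .metrics import ConfusionCounts, balanced_accuracy, mcc, roc_auc

__all__ = [
    "DEFAULT_GRIDS",
    "ModelSpec",
    "TrainedModel",
    "FeatureImportance",
    "train",
    "predict_scores",
    "predict_labels",
    "one_nn_transfer",
    "mdi_importance",
    "AssayPredictionModel",
    "AssayPredictionResults",
]

DEFAULT_GRIDS = {
    "RF": {"n_estimators": [100, 500], "max_depth": [None, 10]},
    "XGB": {"n_estimators": [100, 500], "max_depth": [6, 10],
            "learning_rate": [0.1, 0.3]},
    "SVM": {"C": [0.1, 1, 10], "gamma": ["scale", 0.01]},
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice plus its hyperparameter search space."""

    algo: str  # "RF" | "XGB" | "SVM"
    grid: Optional[dict] = None
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.algo not in DEFAULT_GRIDS:
            raise InputError(f"unknown algorithm {self.algo!r}")
        if self.cv_folds < 2:
            raise InputError("cv_folds must be >= 2")
        if self.grid is not None and not self.grid:
            raise InputError("grid must be non-empty")

    @property
    def effective_grid(self) -> dict:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.algo]


@dataclass(frozen=True)
class TrainedModel:
    spec: ModelSpec
    estimator: object  # fitted sklearn-compatible classifier
    chosen_params: dict
    n_features: int

    @property
    def threshold(self) -> float:
        return 0.0 if self.spec.algo == "SVM" else 0.5


@dataclass(frozen=True)
class FeatureImportance:
    values: dict  # feature_id (or index) -> importance
    normalized: bool

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def _build_estimator(spec: ModelSpec, weights: Optional[Mapping[int, float]]):
    if spec.algo == "RF":
        return RandomForestClassifier(
            random_state=spec.seed, n_jobs=1,
            class_weight=dict(weights) if weights else None,
        )
    if spec.algo == "SVM":
        return SVC(
            kernel="rbf", random_state=spec.seed,
            class_weight=dict(weights) if weights else None,
        )
    return XGBClassifier(random_state=spec.seed, n_jobs=1, eval_metric="logloss")


def train(
    spec: ModelSpec,
    X: np.ndarray,
    y: Sequence[int],
    weights: Optional[Mapping[int, float]] = None,
) -> TrainedModel:
    """Grid search (stratified CV, balanced accuracy), refit on all data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise InputError("feature matrix contains NaN")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("training labels contain a single class")
    folds = min(spec.cv_folds, int(counts.min()))
    estimator = _build_estimator(spec, weights)
    fit_params = {}
    if spec.algo == "XGB" and weights:
        fit_params["sample_weight"] = np.array([weights[int(t)] for t in y])
    grid = spec.effective_grid
    if folds >= 2 and sum(len(v) for v in grid.values()) > len(grid):
        search = GridSearchCV(
            estimator, grid, scoring="balanced_accuracy",
            cv=StratifiedKFold(folds, shuffle=True, random_state=spec.seed),
            n_jobs=1, refit=True,
        )
        search.fit(X, y, **fit_params)
        fitted, params = search.best_estimator_, dict(search.best_params_)
    else:
        # single-candidate grid or too few samples per class to fold
        params = {k: v[0] for k, v in grid.items()}
        estimator.set_params(**params)
        estimator.fit(X, y, **fit_params)
        fitted = estimator
    return TrainedModel(spec=spec, estimator=fitted, chosen_params=params,
                        n_features=X.shape[1])


def predict_scores(model: TrainedModel, X_test: np.ndarray) -> np.ndarray:
    """One finite score per row; higher means more likely active."""
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[1] != model.n_features:
        raise InputError(
            f"feature count {X_test.shape[1]} != training {model.n_features}"
        )
    if model.spec.algo == "SVM":
        scores = model.estimator.decision_function(X_test)
    else:
        pos = list(model.estimator.classes_).index(1)
        scores = model.estimator.predict_proba(X_test)[:, pos]
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise InputError("non-finite prediction scores")
    return scores


def predict_labels(model: TrainedModel, X_test: np.ndarray) -> np.ndarray:
    return (predict_scores(model, X_test) >= model.threshold).astype(int)


def one_nn_transfer(
    m: ProfilingMatrix,
    test_assay: str,
    profile_assays: Sequence,
    train_compounds: Sequence,
    test_compounds: Sequence,
) -> dict:
    """Copy each test compound's label from the most similar profile assay.

    The nearest assay j_NN maximizes active-set Tanimoto to the test assay
    over training compounds (ties break by ascending assay_id); predictions
    read test-compound cells of j_NN only — never of the test assay.
    """
    if not profile_assays:
        raise InputError("profile assay set must be non-empty")
    train_set, test_set = set(train_compounds), set(test_compounds)
    if train_set & test_set:
        raise InputError("train and test compounds overlap")
    ranking = m.rank_profile_assays(test_assay, profile_assays, train_set)
    j_nn = ranking.entries[0][0]
    test_sorted = sorted(test_set)
    values = m._read_cells(test_sorted, j_nn)
    return {c: int(v) for c, v in zip(test_sorted, values)}


def _forest_of(model) -> RandomForestClassifier:
    if isinstance(model, RandomForestClassifier):
        return model
    if isinstance(model, TrainedModel) and model.spec.algo == "RF":
        return model.estimator
    raise InputError("MDI importance requires a random forest model")


def mdi_importance(
    model,
    feature_ids: Optional[Sequence] = None,
    per_tree_normalize: bool = False,
) -> FeatureImportance:
    """Mean-decrease-in-impurity importance by explicit node traversal.

    The default accumulates each tree's raw weighted impurity decreases,
    averages over trees, and normalizes the average to sum 1.  With
    ``per_tree_normalize=True`` each tree's vector is normalized before
    averaging, which reproduces sklearn's ``feature_importances_`` exactly.
    """
    forest = _forest_of(model)
    n_features = forest.n_features_in_
    acc = np.zeros(n_features)
    for est in forest.estimators_:
        t = est.tree_
        imp = np.zeros(n_features)
        w_root = t.weighted_n_node_samples[0]
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            w_t = t.weighted_n_node_samples[node]
            p_t = w_t / w_root
            p_l = t.weighted_n_node_samples[left] / w_t
            p_r = t.weighted_n_node_samples[right] / w_t
            delta = (t.impurity[node]
                     - p_l * t.impurity[left]
                     - p_r * t.impurity[right])
            imp[t.feature[node]] += p_t * delta
        if per_tree_normalize and imp.sum() > 0:
            imp = imp / imp.sum()
        acc += imp
    acc /= len(forest.estimators_)
    total = acc.sum()
    if total > 0:
        acc = acc / total
    ids = list(feature_ids) if feature_ids is not None else list(range(n_features))
    if len(ids) != n_features:
        raise InputError("feature_ids length does not match the forest")
    return FeatureImportance(values=dict(zip(ids, acc.tolist())), normalized=True)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class AssayPredictionModel:
    """One AC-compound prediction experiment cell, statsmodels-style.

    Parameters
    ----------
    matrix : ProfilingMatrix
        The complete binary profiling matrix.
    mms_list : sequence of MMS
        Matching molecular series (silent series already excluded).
    test_assay : str
        The held-out assay whose AC compounds are predicted.
    profile_assays : sequence
        Feature assays; must not contain ``test_assay``.
    scheme : {"intra_series", "series_unit"}
    representation : one of the representation kinds
        ``profile_all``, ``profile_top50``, ``profile_top10``,
        ``profile_rand50``, ``profile_rand10``, ``ecfp4``, ``combined``.
    algo : {"RF", "XGB", "SVM"}
    smiles_by_id : dict, optional
        Needed for structural representations.
    grid : dict, optional
        Hyperparameter grid override (defaults per algorithm).
    """

    _REDUCTIONS = {"profile_top50": ("top_k", 0.5), "profile_top10": ("top_k", 10),
                   "profile_rand50": ("random_k", 0.5), "profile_rand10": ("random_k", 10)}

    def __init__(self, matrix, mms_list, test_assay, profile_assays, scheme,
                 representation, algo, smiles_by_id=None, grid=None,
                 series_unit_ratio=0.8):
        if test_assay in profile_assays:
            raise InputError("test assay cannot be a profile assay")
        if scheme not in ("intra_series", "series_unit"):
            raise InputError(f"unknown scheme {scheme!r}")
        self.matrix = matrix
        self.mms_list = list(mms_list)
        self.test_assay = test_assay
        self.profile_assays = tuple(profile_assays)
        self.scheme = scheme
        self.representation = representation
        self.algo = algo
        self.smiles_by_id = smiles_by_id
        self.grid = grid
        self.series_unit_ratio = series_unit_ratio

    def _split(self, seed: int) -> sp.SplitAssignment:
        members = sorted({c for s in self.mms_list for c in s.member_ids})
        labels = self.matrix.labels(self.test_assay, members)
        if self.scheme == "intra_series":
            return sp.intra_series_split(self.mms_list, labels, seed,
                                         test_assay=self.test_assay)
        return sp.series_unit_split(self.mms_list, labels,
                                    ratio=self.series_unit_ratio, seed=seed,
                                    test_assay=self.test_assay)

    def _feature_assays(self, split: sp.SplitAssignment, seed: int) -> tuple:
        if self.representation == "ecfp4":
            return ()
        if self.representation in ("profile_all", "combined"):
            return self.profile_assays
        mode, k = self._REDUCTIONS[self.representation]
        if isinstance(k, float):
            k = int(len(self.profile_assays) * k)
        ranking = self.matrix.rank_profile_assays(
            self.test_assay, self.profile_assays, split.train_ids
        )
        return tuple(feat.reduce_profile(ranking, mode, k, seed=seed))

    def fit(self, seed: int = 0) -> "AssayPredictionResults":
        """Split, featurize, train, predict, and score this cell."""
        split = self._split(seed)
        assays = self._feature_assays(split, seed)
        kind = "ecfp4" if self.representation == "ecfp4" else (
            "combined" if self.representation == "combined" else "profile_all")
        X_train, rep = feat.feature_matrix(
            kind, split.train_ids, m=self.matrix,
            profile_assays=assays or None, smiles_by_id=self.smiles_by_id,
            test_assay=self.test_assay,
        )
        X_test, _ = feat.feature_matrix(
            kind, split.test_ids, m=self.matrix,
            profile_assays=assays or None, smiles_by_id=self.smiles_by_id,
            test_assay=self.test_assay,
        )
        rep = feat.Representation(kind=self.representation,
                                  feature_ids=rep.feature_ids,
                                  vector_length=rep.vector_length)
        y_train = np.array([split.train[c] for c in split.train_ids])
        y_test = np.array([split.test[c] for c in split.test_ids])
        weights = sp.class_weights(y_train)
        spec = ModelSpec(algo=self.algo, grid=self.grid, seed=seed)
        model = train(spec, X_train, y_train, weights)
        scores = predict_scores(model, X_test)
        y_pred = (scores >= model.threshold).astype(int)
        importances = None
        if self.algo == "RF":
            importances = mdi_importance(model, feature_ids=rep.feature_ids)
        return AssayPredictionResults(
            model=self, split=split, representation=rep, trained=model,
            y_true=y_test, scores=scores, y_pred=y_pred,
            importances=importances, seed=seed,
        )


@dataclass(frozen=True)
class AssayPredictionResults:
    """Fitted-cell results: predictions, metrics, and MDI importances."""

    model: AssayPredictionModel
    split: sp.SplitAssignment
    representation: feat.Representation
    trained: TrainedModel
    y_true: np.ndarray
    scores: np.ndarray
    y_pred: np.ndarray
    importances: Optional[FeatureImportance]
    seed: int

    @property
    def confusion(self) -> ConfusionCounts:
        return ConfusionCounts.from_predictions(self.y_true, self.y_pred)

    @property
    def ba(self) -> float:
        return balanced_accuracy(self.confusion)

    @property
    def mcc(self) -> float:
        return mcc(self.confusion)

    @property
    def roc_auc(self) -> float:
        return roc_auc(self.scores, self.y_true)

    def predictions_frame(self) -> pd.DataFrame:
        m = self.model
        return pd.DataFrame({
            "test_assay": m.test_assay, "scheme": m.scheme,
            "representation": m.representation, "algo": m.algo,
            "compound_id": self.split.test_ids,
            "true_label": self.y_true, "score": self.scores,
            "predicted_label": self.y_pred,
        })

    def summary(self) -> str:
        m = self.model
        c = self.confusion
        lines = [
            "AC compound prediction results",
            "=" * 46,
            f"test assay        {m.test_assay}",
            f"scheme            {m.scheme}",
            f"representation    {m.representation} ({self.representation.vector_length} features)",
            f"algorithm         {m.algo}  params {self.trained.chosen_params}",
            f"train/test size   {len(self.split.train)}/{len(self.split.test)}",
            f"confusion         TP={c.tp} FN={c.fn} TN={c.tn} FP={c.fp}",
            f"balanced accuracy {self.ba:.3f}",
            f"ROC-AUC           {self.roc_auc:.3f}",
            f"MCC               {self.mcc:.3f}",
        ]
        if self.importances is not None:
            top = self.importances.as_series().sort_values(ascending=False)[:5]
            lines.append("top MDI features  "
                         + ", ".join(f"{k}={v:.3f}" for k, v in top.items()))
        return "\n".join(lines)
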