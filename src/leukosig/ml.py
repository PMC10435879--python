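"""Tree-ensemble classification, feature ranking and repeated-holdout evaluation.

Two engines are exposed behind one training contract: a gradient-boosted
decision-tree classifier (GBT; 100 trees for prediction, 500 for ranking,
depth 6, learning rate 0.3, L2 lambda 3, subsample 1) and a random forest
(depth 4, 5 features considered per node, nodes below 5 samples not split).
Evaluation uses repeated random holdout: 100 repeats of an unstratified
66/34 train/test split, predictions pooled into one confusion matrix, and
AUC / classification accuracy / precision / recall / F1 recorded per
repeat.  Feature importances become dense ranks, a learning curve removes
the lowest-ranked features first, and the final signature unions the top
GBT-ranked features with the top cumulative-score features.  Classical
(Torgerson) multidimensional scaling summarises group separability of a
feature subset in two dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.preprocessing import LabelEncoder
from xgboost import XGBClassifier

from .errors import ConfigError

METRICS = ("AUC", "CA", "precision", "recall", "F1")


@dataclass
class ModelParams:
    """Hyperparameters of the tree-ensemble engines.

    ``model_kind`` selects "gbt" or "rf".  ``max_depth=None`` resolves to the
    per-engine default (6 for GBT, 4 for RF).  ``n_trees_predict`` is used
    for classification, ``n_trees_rank`` for feature-importance ranking.
    """

    model_kind: str = "gbt"
    n_trees_predict: int = 100
    n_trees_rank: int = 500
    max_depth: int | None = None
    learning_rate: float = 0.3
    l2_lambda: float = 3.0
    subsample: float = 1.0
    rf_max_features_per_node: int = 5
    rf_min_split: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("gbt", "rf"):
            raise ConfigError(f"model_kind must be 'gbt' or 'rf', got {self.model_kind!r}")
        if self.n_trees_predict < 1 or self.n_trees_rank < 1:
            raise ConfigError("tree counts must be positive")
        if not 0 < self.subsample <= 1:
            raise ConfigError("subsample must be in (0, 1]")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")

    @property
    def depth(self) -> int:
        if self.max_depth is not None:
            return self.max_depth
        return 6 if self.model_kind == "gbt" else 4


class FittedModel:
    """A fitted classifier with string-label predict / predict_proba."""

    def __init__(self, estimator, encoder: LabelEncoder):
        self.estimator = estimator
        self.encoder = encoder
        self.classes_ = encoder.classes_

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # ties resolve to the lowest class label in sort order (argmax picks
        # the first maximum)
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def feature_importances_(self) -> np.ndarray:
        return self.estimator.feature_importances_


def _make_estimator(params: ModelParams, n_trees: int, n_features: int, seed: int):
    if params.model_kind == "gbt":
        return XGBClassifier(
            n_estimators=n_trees,
            max_depth=params.depth,
            learning_rate=params.learning_rate,
            reg_lambda=params.l2_lambda,
            subsample=params.subsample,
            tree_method="exact",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=params.depth,
        max_features=min(params.rf_max_features_per_node, n_features),
        min_samples_split=params.rf_min_split,
        random_state=seed,
        n_jobs=1,
    )


def train_model(X, y, params: ModelParams, n_trees: int | None = None) -> FittedModel:
    """Fit a GBT or RF classifier; deterministic given ``params.seed``."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    if np.isnan(Xa).any():
        raise ValueError("feature matrix contains missing values")
    enc = LabelEncoder().fit(ya)
    if len(enc.classes_) < 2:
        raise ValueError("training requires at least 2 classes")
    est = _make_estimator(
        params, n_trees or params.n_trees_predict, Xa.shape[1], params.seed
    )
    est.fit(Xa, enc.transform(ya))
    return FittedModel(est, enc)


def feature_ranks(X: pd.DataFrame, y, params: ModelParams) -> pd.Series:
    """Dense importance ranks 1..n_features (1 = most important).

    Trains with ``n_trees_rank`` trees and ranks the model-internal
    importances; ties break by feature-name lexicographic order, so the
    result is always a permutation of 1..n.
    """
    model = train_model(X, y, params, n_trees=params.n_trees_rank)
    imp = pd.Series(model.feature_importances_, index=list(X.columns))
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order, name="rank")
    return ranks.reindex(imp.index)


@dataclass
class EvaluationResult:
    """Pooled confusion matrix and per-repeat metrics of repeated holdout."""

    confusion: pd.DataFrame           # rows = actual, columns = predicted
    per_repeat: pd.DataFrame          # one row per repeat, METRICS columns
    repeats: int
    train_fraction: float
    redraws: int = 0                  # splits redrawn for a missing class

    @property
    def summary(self) -> pd.DataFrame:
        return self.per_repeat.agg(["mean", "std"]).T

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "train_fraction": self.train_fraction,
            "redraws": self.redraws,
            "confusion": {
                a: {p: int(v) for p, v in row.items()}
                for a, row in self.confusion.iterrows()
            },
            "metrics_mean": {m: float(self.per_repeat[m].mean()) for m in METRICS},
            "metrics_std": {m: float(self.per_repeat[m].std()) for m in METRICS},
        }


def _macro_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    """Macro one-vs-rest AUC over classes with both outcomes in the test set."""
    aucs = []
    for i, c in enumerate(classes):
        pos = y_true == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, proba[:, i]))
    return float(np.mean(aucs)) if aucs else np.nan


def repeated_holdout(
    X: pd.DataFrame,
    y,
    params: ModelParams,
    repeats: int = 100,
    train_fraction: float = 0.66,
    average: str = "macro",
) -> EvaluationResult:
    """Repeated random unstratified holdout evaluation.

    Each repeat draws a fresh train/test split without replacement (test
    size ceil((1 - train_fraction) * n)), trains a fresh model with
    ``n_trees_predict`` trees, and accumulates test predictions into one
    pooled confusion matrix.  A repeat whose training part misses a class
    is redrawn and counted in ``redraws``.  Splits are drawn from a
    canonically sorted sample index, so the result is invariant to input
    row order.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    ya = pd.Series(np.asarray(y), index=X.index)
    order = np.argsort(X.index.astype(str), kind="stable")
    X = X.iloc[order]
    ya = ya.iloc[order]
    classes = np.array(sorted(pd.unique(ya)))
    if min((ya == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 samples")
    n = len(ya)
    n_test = int(np.ceil((1.0 - train_fraction) * n))
    rng = np.random.default_rng(params.seed)

    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    records = []
    redraws = 0
    for rep in range(repeats):
        while True:
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if set(pd.unique(ya.iloc[train_idx])) == set(classes):
                break
            redraws += 1
        rep_params = replace(params, seed=int(rng.integers(0, 2**31 - 1)))
        model = train_model(X.iloc[train_idx], ya.iloc[train_idx], rep_params)
        proba_model = model.predict_proba(X.iloc[test_idx])
        # align probability columns to the full class list
        proba = np.zeros((n_test, len(classes)))
        for j, c in enumerate(model.classes_):
            proba[:, list(classes).index(c)] = proba_model[:, j]
        pred = classes[np.argmax(proba, axis=1)]
        truth = ya.iloc[test_idx].to_numpy()
        for t, p in zip(truth, pred):
            confusion.loc[t, p] += 1
        present = np.array(sorted(pd.unique(truth)))
        prec, rec, f1, _ = precision_recall_fscore_support(
            truth, pred, labels=present, average=average, zero_division=0
        )
        records.append(
            {
                "repeat": rep,
                "AUC": _macro_auc(truth, proba, classes),
                "CA": float((truth == pred).mean()),
                "precision": float(prec),
                "recall": float(rec),
                "F1": float(f1),
            }
        )
    per_repeat = pd.DataFrame(records).set_index("repeat")
    return EvaluationResult(
        confusion=confusion,
        per_repeat=per_repeat,
        repeats=repeats,
        train_fraction=train_fraction,
        redraws=redraws,
    )


def learning_curve(
    X: pd.DataFrame,
    y,
    ranks: pd.Series,
    params: ModelParams,
    repeats: int = 100,
    train_fraction: float = 0.66,
) -> pd.DataFrame:
    """Repeated-holdout metrics as features are removed worst-rank first.

    For k = n_features down to 1, the top-k ranked features are evaluated
    with :func:`repeated_holdout` under the same seed, so the k = n row
    reproduces the full-feature result exactly.  Returns mean metrics per k.
    """
    missing = [f for f in X.columns if f not in ranks.index]
    if missing:
        raise ValueError(f"ranks do not cover features {missing}")
    ordered = sorted(X.columns, key=lambda f: (ranks[f], f))
    rows = []
    for k in range(len(ordered), 0, -1):
        res = repeated_holdout(
            X[ordered[:k]], y, params, repeats=repeats, train_fraction=train_fraction
        )
        row = {"n_features": k}
        row.update({m: float(res.per_repeat[m].mean()) for m in METRICS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("n_features")


@dataclass
class FeatureSelection:
    """The 6 + 2 signature: top GBT-ranked plus top cumulative-score features."""

    gbt_top: list[str]
    extra: list[str]
    selected: list[str] = field(init=False)

    def __post_init__(self) -> None:
        sel = list(self.gbt_top)
        sel.extend(f for f in self.extra if f not in sel)
        self.selected = sel


def select_features(
    gbt_ranks: pd.Series,
    cumulative_scores: pd.Series,
    n_top: int = 6,
    n_extra: int = 2,
) -> FeatureSelection:
    """Union the top-``n_top`` GBT-ranked with the top-``n_extra`` scored features.

    Order is preserved (GBT list first, then extras); duplicates collapse,
    so the selection has between ``n_top`` and ``n_top + n_extra`` members
    (8 at the defaults when the extras are disjoint).
    """
    if set(gbt_ranks.index) != set(cumulative_scores.index):
        raise ValueError("gbt_ranks and cumulative_scores must cover the same features")
    if n_top + n_extra > len(gbt_ranks):
        raise ValueError("n_top + n_extra exceeds the number of features")
    top = sorted(gbt_ranks.index, key=lambda f: (gbt_ranks[f], f))[:n_top]
    extra = sorted(
        cumulative_scores.index, key=lambda f: (-cumulative_scores[f], f)
    )[:n_extra]
    return FeatureSelection(gbt_top=list(top), extra=list(extra))


def classical_mds(X: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on z-scored feature columns.

    Euclidean distances of the standardized selected columns are
    double-centred and eigendecomposed; the first two principal coordinates
    are returned (columns ``mds1``, ``mds2`` indexed like ``X``).  Constant
    features are dropped with a warning before z-scoring.
    """
    cols = list(features) if features is not None else list(X.columns)
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    if len(X) < 3:
        raise ValueError("classical MDS needs at least 3 samples")
    M = X[cols].to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=0)
    if (sd == 0).any():
        dropped = [c for c, s in zip(cols, sd) if s == 0]
        warnings.warn(f"dropping constant features before MDS: {dropped}")
        keep = sd > 0
        M, sd = M[:, keep], sd[keep]
    Z = (M - M.mean(axis=0)) / sd
    D2 = squareform(pdist(Z, metric="euclidean")) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:2]
    coords = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    return pd.DataFrame(coords, index=X.index, columns=["mds1", "mds2"])
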