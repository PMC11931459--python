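"""Random-forest training with grid search and iterative GINI pruning.

Training regimen: per reference set, 75% of pairs go to training and 25% to
testing (seeded).  Hyperparameters are chosen by exhaustive grid search over

    n_estimators in {150, 200, 250}, max_depth in {3, 5, 7},
    min_samples_split in {2, 5}, bootstrap in {True, False},
    criterion in {gini, log_loss}

(72 combinations) with 3-fold stratified cross-validated ROC AUC as the
objective; every other hyperparameter stays at the scikit-learn default.
After each tuning round, features with GINI importance below 0.01 are
discarded and the whole search is re-run on the reduced set, until no
feature is dropped.  Ties in the grid are broken toward smaller
``n_estimators``, then shallower ``max_depth`` (prefer the simpler forest).

The module exposes both the flat operations (``split_by_refset``,
``tune_and_train``, ``prune_and_retrain``, ``score``, ``save_model`` /
``load_model``) and a Model/Results wrapper, :class:`InteractionClassifier`,
whose ``fit()`` returns an :class:`InteractionClassifierResults` carrying the
fitted forest, retained feature schema, importances, pruning history and a
``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence
import warnings

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold

from .errors import DegenerateModelError, ModelLoadError, ScoringError, TrainingError

__all__ = [
    "TrainingConfig",
    "TrainedClassifier",
    "split_by_refset",
    "tune_and_train",
    "prune_and_retrain",
    "score",
    "save_model",
    "load_model",
    "InteractionClassifier",
    "InteractionClassifierResults",
]

ARTIFACT_VERSION = "afmscreen-model-1"

DEFAULT_GRID = {
    "n_estimators": [150, 200, 250],
    "max_depth": [3, 5, 7],
    "min_samples_split": [2, 5],
    "bootstrap": [True, False],
    "criterion": ["gini", "log_loss"],
}


@dataclass
class TrainingConfig:
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    cv_folds: int = 3
    prune_threshold: float = 0.01
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class TrainedClassifier:
    """Fitted forest plus the schema and provenance needed to reuse it."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    gini_importances: dict
    hyperparameters: dict
    cv_auc: float
    seed: int
    config_digest: str
    pruning_history: list = field(default_factory=list)


def split_by_refset(
    dataset: pd.DataFrame,
    config: Optional[TrainingConfig] = None,
    refset_col: str = "refset",
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-refset random 75/25 split; disjoint and exhaustive."""
    config = config or TrainingConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for _, group in dataset.groupby(refset_col, sort=True):
        idx = np.array(group.index)
        if len(idx) < 4:
            warnings.warn(
                f"refset {group[refset_col].iloc[0]!r} has only {len(idx)} rows; "
                "all assigned to training"
            )
            train_idx.extend(idx)
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(config.train_fraction * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return dataset.loc[sorted(train_idx)], dataset.loc[sorted(test_idx)]


def _grid_order(grid: dict):
    """Deterministic grid enumeration, simplest models first for tie-breaks."""
    combos = list(ParameterGrid(grid))
    return sorted(
        combos,
        key=lambda p: (
            p.get("n_estimators", 0),
            p.get("max_depth") if p.get("max_depth") is not None else np.inf,
            str(sorted(p.items())),
        ),
    )


def _params_key(params: dict):
    return tuple(sorted(params.items()))


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties (== roc_auc_score, less
    input-validation overhead; it runs tens of thousands of times in a grid
    search)."""
    _, inv, counts = np.unique(scores, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    ranks = (cum - (counts - 1) / 2.0)[inv]
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _grid_cv_aucs(Xv, y, folds, grid: dict, seed: int) -> dict:
    """Mean CV AUC per grid combination.

    Forests that differ only in ``n_estimators`` share their earlier trees: a
    forest is grown once with ``warm_start`` and scored at each requested
    size, since the first-k-tree prefix of a forest is itself a random forest
    with ``n_estimators=k``.  This changes nothing about what is evaluated,
    only how many trees are built.
    """
    import sklearn

    sizes = sorted(grid.get("n_estimators", [100]))
    others = {k: v for k, v in grid.items() if k != "n_estimators"}
    Xv = np.ascontiguousarray(Xv, dtype=np.float32)
    auc_sums: dict[tuple, list] = {}
    with sklearn.config_context(assume_finite=True):
        for base in ParameterGrid(others) if others else [{}]:
            for tr, te in folds:
                Xtr, Xte, ytr, yte = Xv[tr], Xv[te], y[tr], y[te]
                clf = RandomForestClassifier(
                    random_state=seed, warm_start=True, n_estimators=sizes[0], **base
                )
                prev_probs = np.zeros(len(te))
                prev_n = 0
                for n in sizes:
                    clf.set_params(n_estimators=n)
                    clf.fit(Xtr, ytr)
                    # incremental scoring: only the newly grown trees predict
                    new = sum(
                        t.predict_proba(Xte, check_input=False)[:, 1]
                        for t in clf.estimators_[prev_n:n]
                    )
                    prev_probs = prev_probs + new
                    prev_n = n
                    key = _params_key({**base, "n_estimators": n})
                    auc_sums.setdefault(key, []).append(
                        _rank_auc(yte, prev_probs / n)
                    )
    return {k: float(np.mean(v)) for k, v in auc_sums.items()}


def tune_and_train(
    X: pd.DataFrame,
    y: np.ndarray,
    config: Optional[TrainingConfig] = None,
    seed: Optional[int] = None,
) -> TrainedClassifier:
    """Exhaustive grid search with K-fold CV AUC; refit winner on all rows."""
    config = config or TrainingConfig()
    seed = config.seed if seed is None else seed
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")
    if X.shape[1] == 0:
        raise DegenerateModelError("no features left to train on")
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    Xv = np.asarray(X, dtype=float)
    cv_aucs = _grid_cv_aucs(Xv, y, folds, config.grid, seed)
    best = None
    for params in _grid_order(config.grid):
        mean_auc = cv_aucs[_params_key(params)]
        if best is None or mean_auc > best[0]:  # strict: earlier (simpler) wins ties
            best = (mean_auc, params)
    cv_auc, params = best
    final = RandomForestClassifier(random_state=seed, **params)
    final.fit(Xv, y)
    return TrainedClassifier(
        estimator=final,
        feature_names=list(X.columns),
        gini_importances=dict(zip(X.columns, map(float, final.feature_importances_))),
        hyperparameters=dict(params),
        cv_auc=cv_auc,
        seed=seed,
        config_digest=config.digest(),
    )


def prune_and_retrain(
    X: pd.DataFrame,
    y: np.ndarray,
    config: Optional[TrainingConfig] = None,
    seed: Optional[int] = None,
) -> TrainedClassifier:
    """Alternate grid search and GINI pruning until no feature falls below
    the threshold.  The full search is re-run from scratch each round."""
    config = config or TrainingConfig()
    features = list(X.columns)
    history = []
    while True:
        clf = tune_and_train(X[features], y, config, seed)
        dropped = [
            f for f, g in clf.gini_importances.items() if g < config.prune_threshold
        ]
        history.append(
            {
                "n_features": len(features),
                "cv_auc": clf.cv_auc,
                "hyperparameters": clf.hyperparameters,
                "gini": dict(clf.gini_importances),
                "dropped": dropped,
            }
        )
        if not dropped:
            clf.pruning_history = history
            return clf
        features = [f for f in features if f not in dropped]
        if not features:
            raise DegenerateModelError("pruning removed every feature")


def score(classifier: TrainedClassifier, features) -> np.ndarray:
    """Fraction-of-trees probability in [0, 1] for one or many feature rows."""
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    if isinstance(features, pd.DataFrame):
        missing = [f for f in classifier.feature_names if f not in features.columns]
        if missing:
            raise ScoringError(f"input lacks retained features: {missing}")
        X = features[classifier.feature_names].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(classifier.feature_names):
            raise ScoringError(
                f"expected {len(classifier.feature_names)} features, got {X.shape[1]}"
            )
    return classifier.estimator.predict_proba(X)[:, 1]


def save_model(classifier: TrainedClassifier, path) -> None:
    """Persist the forest (joblib) with a JSON provenance sidecar."""
    path = Path(path)
    joblib.dump({"version": ARTIFACT_VERSION, "estimator": classifier.estimator}, path)
    sidecar = {
        "version": ARTIFACT_VERSION,
        "feature_names": classifier.feature_names,
        "gini_importances": classifier.gini_importances,
        "hyperparameters": classifier.hyperparameters,
        "cv_auc": classifier.cv_auc,
        "seed": classifier.seed,
        "config_digest": classifier.config_digest,
        "pruning_history": classifier.pruning_history,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> TrainedClassifier:
    path = Path(path)
    try:
        blob = joblib.load(path)
    except Exception as exc:
        raise ModelLoadError(f"cannot load model artifact {path}: {exc}") from exc
    if not isinstance(blob, dict) or blob.get("version") != ARTIFACT_VERSION:
        raise ModelLoadError(
            f"artifact {path} has version {blob.get('version') if isinstance(blob, dict) else '?'}, "
            f"expected {ARTIFACT_VERSION}"
        )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelLoadError(f"cannot read sidecar {sidecar_path}: {exc}") from exc
    return TrainedClassifier(
        estimator=blob["estimator"],
        feature_names=list(sidecar["feature_names"]),
        gini_importances=dict(sidecar["gini_importances"]),
        hyperparameters=dict(sidecar["hyperparameters"]),
        cv_auc=float(sidecar["cv_auc"]),
        seed=int(sidecar["seed"]),
        config_digest=sidecar["config_digest"],
        pruning_history=list(sidecar.get("pruning_history", [])),
    )


class InteractionClassifier:
    """Model object: a labeled feature table plus a training configuration.

    Parameters
    ----------
    data : DataFrame with one row per pair, feature columns, a binary label
        column (1/"positive" = true interaction) and a refset tag column.
    feature_names : columns to use as features; defaults to every numeric
        column that is not the label.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_names: Sequence[str],
        label_col: str = "label",
        refset_col: str = "refset",
        config: Optional[TrainingConfig] = None,
    ):
        self.data = data.reset_index(drop=True)
        self.feature_names = list(feature_names)
        self.label_col = label_col
        self.refset_col = refset_col
        self.config = config or TrainingConfig()

    @classmethod
    def from_dataframe(cls, data, label_col="label", refset_col="refset", config=None):
        drop = {label_col, refset_col, "pair_id"}
        feats = [
            c
            for c in data.columns
            if c not in drop and pd.api.types.is_numeric_dtype(data[c])
        ]
        return cls(data, feats, label_col, refset_col, config=config)

    def _labels(self, df) -> np.ndarray:
        raw = df[self.label_col]
        if raw.dtype == object:
            return (raw == "positive").astype(int).to_numpy()
        return raw.astype(int).to_numpy()

    def fit(self, seed: Optional[int] = None, prune: bool = True):
        seed = self.config.seed if seed is None else seed
        train, test = split_by_refset(self.data, self.config, self.refset_col, seed)
        fitfn = prune_and_retrain if prune else tune_and_train
        trained = fitfn(train[self.feature_names], self._labels(train), self.config, seed)
        return InteractionClassifierResults(self, trained, train, test)


class InteractionClassifierResults:
    """Fitted classifier with its split, diagnostics and persistence."""

    def __init__(self, model, trained: TrainedClassifier, train_df, test_df):
        self.model = model
        self.trained = trained
        self.train_df = train_df
        self.test_df = test_df

    @property
    def retained_features(self) -> list[str]:
        return list(self.trained.feature_names)

    @property
    def gini_importances(self) -> pd.Series:
        return pd.Series(self.trained.gini_importances).sort_values(ascending=False)

    @property
    def hyperparameters(self) -> dict:
        return dict(self.trained.hyperparameters)

    @property
    def pruning_history(self) -> list:
        return self.trained.pruning_history

    def predict(self, data) -> np.ndarray:
        return score(self.trained, data)

    def test_auc(self) -> float:
        if len(self.test_df) == 0:
            raise TrainingError("no held-out test rows")
        y = self.model._labels(self.test_df)
        return float(roc_auc_score(y, self.predict(self.test_df)))

    def summary(self) -> str:
        lines = [
            "Interaction classifier (random forest)",
            "=" * 46,
            f"training rows:      {len(self.train_df)}",
            f"test rows:          {len(self.test_df)}",
            f"cv AUC (best grid): {self.trained.cv_auc:.4f}",
            f"hyperparameters:    {self.trained.hyperparameters}",
            f"pruning rounds:     {len(self.trained.pruning_history)}",
            f"retained features:  {len(self.retained_features)}",
            "",
            "GINI importance (retained features)",
            "-" * 46,
        ]
        for name, g in self.gini_importances.items():
            lines.append(f"{name:<32s} {g:8.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        save_model(self.trained, path)
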