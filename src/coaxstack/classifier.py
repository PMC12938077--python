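"""Random-forest stacking classifier: training, tuning, threshold, importances.

A single binary random forest scores every pseudo two-way junction for
coaxial stacking.  Defaults reproduce the reference configuration: 703
trees, depth 43, minimum split 5, minimum leaf 1, feature-sampling ratio
0.23, positive class weight 4.8, and a decision threshold of 0.42 placed
at the crossing point of the kernel-density estimates of the predicted
probabilities of the two classes.

Hyperparameters can be re-tuned with a seeded Gaussian-process Bayesian
search over the six-dimensional space (five random initializations plus
ten guided iterations, 10-fold stratified cross-validation).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score

from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "ModelHyperparameters",
    "TrainedModel",
    "StackingPrediction",
    "train_forest",
    "bayes_optimize",
    "estimate_threshold",
    "predict_pairs",
    "feature_importances",
    "ablation_run",
    "save_model",
    "load_model",
]

DEFAULT_THRESHOLD = 0.42


@dataclass(frozen=True)
class ModelHyperparameters:
    """Forest hyperparameters; defaults are the tuned reference optimum."""

    n_trees: int = 703
    max_depth: int = 43
    min_split: int = 5
    min_leaf: int = 1
    feature_fraction: float = 0.23
    positive_class_weight: float = 4.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must be in (0, 1]")
        if self.positive_class_weight <= 0:
            raise ValueError("positive_class_weight must be > 0")

    def make_forest(self, criterion: str = "gini") -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            min_samples_split=self.min_split,
            min_samples_leaf=self.min_leaf,
            max_features=self.feature_fraction,
            class_weight={0: 1.0, 1: self.positive_class_weight},
            criterion=criterion,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to apply it reproducibly."""

    forest: RandomForestClassifier
    hyperparameters: ModelHyperparameters
    threshold: float
    feature_names: tuple[str, ...]
    training_metadata: dict = field(default_factory=dict)
    # retained to support criterion-specific importances and ablations
    train_X: Optional[np.ndarray] = None
    train_y: Optional[np.ndarray] = None
    _entropy_forest: Optional[RandomForestClassifier] = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if len(self.feature_names) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features")


@dataclass(frozen=True)
class StackingPrediction:
    """Per-pair output: probability of stacking and the thresholded label."""

    pair_id: str
    probability: float
    label: int
    stem_pair: Optional[tuple[int, int]] = None


def _validate_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if "label" not in table.columns:
        raise ValueError("feature table missing 'label' column")
    X = table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing feature values are not imputed; remove incomplete rows")
    y = table["label"].to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("training requires >= 2 samples per class")
    return X, y


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_forest(
    table: pd.DataFrame,
    hp: ModelHyperparameters = ModelHyperparameters(),
    threshold: Optional[float] = None,
    threshold_cv_folds: int = 5,
    parameter_version: str = "turner2004",
) -> TrainedModel:
    """Fit the stacking forest on a labeled feature table.

    Unless ``threshold`` pins the decision cutoff (e.g. to the shipped
    0.42), it is recomputed from this training set: class-wise KDE crossing
    of out-of-fold predicted probabilities (stratified, seeded folds).
    """
    X, y = _validate_table(table)
    forest = hp.make_forest()
    pinned = threshold is not None
    if threshold is None:
        cv = StratifiedKFold(n_splits=threshold_cv_folds, shuffle=True, random_state=hp.seed)
        oof = cross_val_predict(hp.make_forest(), X, y, cv=cv, method="predict_proba")[:, 1]
        threshold = estimate_threshold(oof[y == 1], oof[y == 0])
    forest.fit(X, y)
    meta = {
        "n_samples": int(len(y)),
        "n_positive": int(y.sum()),
        "seed": hp.seed,
        "parameter_version": parameter_version,
        "data_fingerprint": _fingerprint(X, y),
        "threshold_source": "pinned" if pinned else "kde",
    }
    return TrainedModel(
        forest=forest,
        hyperparameters=hp,
        threshold=float(threshold),
        feature_names=FEATURE_NAMES,
        training_metadata=meta,
        train_X=X,
        train_y=y,
    )


def _kde_density(samples: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE with Silverman's bandwidth (small floor for degenerate data)."""
    x = np.asarray(samples, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    bw = 0.9 * spread * n ** (-1 / 5) if spread > 0 else 0.01
    return norm.pdf((grid[:, None] - x[None, :]) / bw).mean(axis=1) / bw


def estimate_threshold(
    pos_probs: Sequence[float],
    neg_probs: Sequence[float],
    grid_size: int = 512,
) -> float:
    """Decision threshold at the KDE crossing of the two probability densities.

    Scans a fixed grid on [0, 1] upward for the first point where the
    positive-class density exceeds the negative-class density after having
    been at or below it; falls back to 0.5 (with a warning) when the
    densities never cross.
    """
    pos = np.asarray(pos_probs, dtype=float)
    neg = np.asarray(neg_probs, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both probability lists must be nonempty")
    grid = np.linspace(0.0, 1.0, grid_size)
    diff = _kde_density(pos, grid) - _kde_density(neg, grid)
    for i in range(1, grid_size):
        if diff[i - 1] <= 0 < diff[i]:
            # linear interpolation of the sign change
            t = grid[i - 1] + (grid[i] - grid[i - 1]) * (-diff[i - 1]) / (diff[i] - diff[i - 1])
            return float(min(max(t, 1e-6), 1 - 1e-6))
    warnings.warn("probability densities do not cross; falling back to threshold 0.5")
    return 0.5


def predict_pairs(
    model: TrainedModel,
    pairs,
    pair_ids: Optional[list[str]] = None,
    stem_pairs: Optional[list[tuple[int, int]]] = None,
) -> list[StackingPrediction]:
    """Score pseudo two-way pairs; label = probability > model.threshold.

    ``pairs`` may be a feature DataFrame, a list of :class:`FeatureVector`,
    or a raw (n, 12) array in canonical feature order.
    """
    if isinstance(pairs, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in pairs.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        X = pairs.loc[:, list(model.feature_names)].to_numpy(dtype=float)
        if pair_ids is None and "pair_id" in pairs.columns:
            pair_ids = pairs["pair_id"].tolist()
    else:
        rows = [
            p.as_array() if isinstance(p, FeatureVector) else np.asarray(p, dtype=float)
            for p in pairs
        ]
        if not rows:
            return []
        X = np.vstack(rows)
    if X.shape[0] == 0:
        return []
    if X.shape[1] != len(model.feature_names):
        raise ValueError(f"expected {len(model.feature_names)} features, got {X.shape[1]}")
    probs = model.forest.predict_proba(X)[:, 1]
    if pair_ids is None:
        pair_ids = [str(i) for i in range(len(probs))]
    return [
        StackingPrediction(
            pair_id=pair_ids[i],
            probability=float(probs[i]),
            label=int(probs[i] > model.threshold),
            stem_pair=None if stem_pairs is None else stem_pairs[i],
        )
        for i in range(len(probs))
    ]


def feature_importances(model: TrainedModel, criterion: str = "gini") -> list[tuple[str, float]]:
    """Split-based feature importances, ranked descending, summing to 1.

    ``"gini"`` reads the trained forest; ``"information_gain"`` fits a
    companion forest with the entropy criterion on the retained training
    data (cached on the model).
    """
    if criterion == "gini":
        forest = model.forest
    elif criterion == "information_gain":
        if model._entropy_forest is None:
            if model.train_X is None:
                raise ValueError("model lacks retained training data for entropy importances")
            ef = model.hyperparameters.make_forest(criterion="entropy")
            ef.fit(model.train_X, model.train_y)
            model._entropy_forest = ef
        forest = model._entropy_forest
    else:
        raise ValueError("criterion must be 'gini' or 'information_gain'")
    if not hasattr(forest, "feature_importances_"):
        raise ValueError("model is not fitted")
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    ranked = sorted(zip(model.feature_names, imp.tolist()), key=lambda t: (-t[1], t[0]))
    return ranked


def ablation_run(
    table: pd.DataFrame,
    dropped_features: Sequence[str],
    hp: ModelHyperparameters = ModelHyperparameters(),
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Mean and per-fold CV accuracy with the named feature columns removed.

    Fold assignment depends only on the labels and the seed, so ablated and
    unablated runs use identical folds and compare pairwise.
    """
    X, y = _validate_table(table)
    keep = [f for f in FEATURE_NAMES if f not in set(dropped_features)]
    unknown = set(dropped_features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features to drop: {sorted(unknown)}")
    if not keep:
        raise ValueError("cannot drop every feature")
    cols = [list(FEATURE_NAMES).index(f) for f in keep]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(hp.make_forest(), X[:, cols], y, cv=cv, scoring="accuracy")
    return float(scores.mean()), [float(s) for s in scores]


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search
# ---------------------------------------------------------------------------

#: dimension spec: name -> ("int", lo, hi) | ("float", lo, hi) | ("choice", [...])
DEFAULT_SEARCH_SPACE = {
    "n_trees": ("int", 100, 1000),
    "max_depth": ("int", 5, 60),
    "min_split": ("int", 2, 20),
    "min_leaf": ("int", 1, 10),
    "feature_fraction": ("float", 0.1, 1.0),
    "positive_class_weight": ("float", 0.5, 10.0),
}


def _space_points(space: dict) -> Optional[list[dict]]:
    """Exhaustive grid when every dimension is a small finite choice set."""
    names, option_lists = [], []
    total = 1
    for name, dim in space.items():
        if dim[0] != "choice":
            return None
        names.append(name)
        option_lists.append(list(dim[1]))
        total *= len(dim[1])
        if total > 64:
            return None
    points: list[dict] = [{}]
    for name, opts in zip(names, option_lists):
        points = [{**p, name: o} for p in points for o in opts]
    return points


def _decode(space: dict, unit: np.ndarray) -> dict:
    cfg = {}
    for u, (name, dim) in zip(unit, space.items()):
        kind = dim[0]
        if kind == "choice":
            opts = dim[1]
            cfg[name] = opts[min(int(u * len(opts)), len(opts) - 1)]
        elif kind == "int":
            lo, hi = dim[1], dim[2]
            cfg[name] = int(round(lo + u * (hi - lo)))
        else:
            lo, hi = dim[1], dim[2]
            cfg[name] = float(lo + u * (hi - lo))
    return cfg


def bayes_optimize(
    table: pd.DataFrame,
    space: dict = DEFAULT_SEARCH_SPACE,
    n_init: int = 5,
    n_iter: int = 10,
    folds: int = 10,
    seed: int = 0,
    scoring: str = "roc_auc",
) -> ModelHyperparameters:
    """Gaussian-process Bayesian search over the six tuned hyperparameters.

    Five random initializations followed by ten expected-improvement
    iterations (defaults), each configuration scored by seeded stratified
    k-fold cross-validation.  Fully deterministic for a fixed seed.  When
    the space is a small finite grid it is evaluated exhaustively instead.
    """
    X, y = _validate_table(table)
    for name, dim in space.items():
        if dim[0] in ("int", "float") and dim[1] > dim[2]:
            raise ValueError(f"degenerate range for {name}")
        if dim[0] == "choice" and len(dim[1]) == 0:
            raise ValueError(f"empty choice set for {name}")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    def evaluate(cfg: dict) -> float:
        hp = replace(ModelHyperparameters(seed=seed), **cfg)
        return float(cross_val_score(hp.make_forest(), X, y, cv=cv, scoring=scoring).mean())

    grid = _space_points(space)
    if grid is not None:
        scored = [(evaluate(cfg), -i, cfg) for i, cfg in enumerate(grid)]
        best = max(scored)[2]
        return replace(ModelHyperparameters(seed=seed), **best)

    rng = np.random.default_rng(seed)
    units = [rng.random(len(space)) for _ in range(n_init)]
    configs = [_decode(space, u) for u in units]
    scores = [evaluate(c) for c in configs]
    for _ in range(n_iter):
        U = np.vstack(units)
        s = np.asarray(scores)
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(len(space), 0.3)),
            alpha=1e-6,
            normalize_y=True,
            random_state=seed,
        )
        gp.fit(U, s)
        cand = rng.random((256, len(space)))
        mu, sigma = gp.predict(cand, return_std=True)
        best_s = s.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best_s) / sigma
            ei = np.where(sigma > 0, (mu - best_s) * norm.cdf(z) + sigma * norm.pdf(z), 0.0)
        pick = cand[int(np.argmax(ei))]
        units.append(pick)
        cfg = _decode(space, pick)
        configs.append(cfg)
        scores.append(evaluate(cfg))
    best = configs[int(np.argmax(scores))]
    return replace(ModelHyperparameters(seed=seed), **best)


def save_model(model: TrainedModel, path) -> None:
    """Single-file model artifact (forest, hyperparameters, threshold, metadata)."""
    joblib.dump(
        {
            "forest": model.forest,
            "hyperparameters": model.hyperparameters,
            "threshold": model.threshold,
            "feature_names": model.feature_names,
            "training_metadata": model.training_metadata,
            "train_X": model.train_X,
            "train_y": model.train_y,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    if tuple(blob["feature_names"]) != FEATURE_NAMES:
        raise ValueError(
            "model feature order is incompatible with this package version: "
            f"{blob['feature_names']}"
        )
    return TrainedModel(
        forest=blob["forest"],
        hyperparameters=blob["hyperparameters"],
        threshold=blob["threshold"],
        feature_names=tuple(blob["feature_names"]),
        training_metadata=blob["training_metadata"],
        train_X=blob.get("train_X"),
        train_y=blob.get("train_y"),
    )
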