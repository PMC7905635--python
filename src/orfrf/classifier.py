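"""Random-forest training, tuning, persistence and prediction.

Protocol: the mtry grid (features considered per split) is scored by
repeated stratified k-fold cross-validation (5 folds x 5 repeats by
default), the best mean accuracy wins (ties to the smaller mtry), and the
final forest is refit on all instances. Ensemble sizes follow the
canonical grid {100, 200, 500, 700}; 100 trees is the default — larger
ensembles buy little accuracy at several times the cost.

A prediction's score ``p_coding`` is the fraction of trees voting coding
(not averaged leaf probabilities); the default decision threshold is 0.5.

Model files embed the feature order, the ORF-extraction settings, the
genetic code id and the variance convention used in training, so a model
cannot silently be applied under different conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

from .errors import ModelError, ModelFormatError
from .features import FEATURE_NAMES
from .labeling import LabeledInstance
from .orfs import OrfConfig

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "1"
ALLOWED_TREE_COUNTS = (100, 200, 500, 700)
VARIANCE_CONVENTION = "kmer-frequency sample variance (ddof=1), stop codon included"


@dataclass(frozen=True)
class TrainingConfig:
    n_trees: int = 100
    mtry_grid: tuple[int, ...] = (2, 3, 6, 11)
    cv_folds: int = 5
    cv_repeats: int = 5
    seed: int = 0
    selection_metric: str = "accuracy"

    def __post_init__(self) -> None:
        if self.n_trees not in ALLOWED_TREE_COUNTS:
            raise ValueError(f"n_trees must be one of {ALLOWED_TREE_COUNTS}")
        if not self.mtry_grid or any(
            not 1 <= m <= len(FEATURE_NAMES) for m in self.mtry_grid
        ):
            raise ValueError(f"mtry values must lie in [1, {len(FEATURE_NAMES)}]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selection_metric != "accuracy":
            raise ValueError("only accuracy selection is supported")


@dataclass(frozen=True)
class CvResult:
    mtry: int
    mean_accuracy: float
    sd_accuracy: float


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    feature_order: tuple[str, ...]
    chosen_mtry: int
    n_trees: int
    orf_config: OrfConfig
    genetic_code_id: int
    variance_convention: str
    format_version: str
    seed: int
    permutation_importances: np.ndarray  # raw mean importance per feature
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if tuple(self.feature_order) != FEATURE_NAMES:
            raise ModelError(
                f"feature_order must be the canonical 11 names {FEATURE_NAMES}"
            )


@dataclass(frozen=True)
class Prediction:
    orf_ref: tuple[str, int, int, str]
    p_coding: float
    label: Literal["coding", "intergenic"]


def _to_xy(instances: Sequence[LabeledInstance]) -> tuple[np.ndarray, np.ndarray]:
    X = np.empty((len(instances), len(FEATURE_NAMES)))
    y = np.empty(len(instances), dtype=int)
    for i, inst in enumerate(instances):
        X[i] = inst.features.as_array()
        y[i] = 1 if inst.label == "coding" else 0
        if not np.isfinite(X[i]).all():
            raise ModelError(f"non-finite feature in instance {inst.orf_ref}")
    return X, y


def _forest(n_trees: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    )


def train(
    instances: Sequence[LabeledInstance],
    config: TrainingConfig = TrainingConfig(),
    orf_config: OrfConfig = OrfConfig(),
    genetic_code_id: int = 11,
) -> tuple[TrainedModel, list[CvResult]]:
    """Tune mtry by repeated stratified CV, refit on everything.

    Fully deterministic in (instances, config.seed).
    """
    X, y = _to_xy(instances)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelError("training requires both classes present")
    if counts.min() < 2:
        raise ModelError("training requires >= 2 instances per class")

    cv = RepeatedStratifiedKFold(
        n_splits=config.cv_folds,
        n_repeats=config.cv_repeats,
        random_state=config.seed,
    )
    results: list[CvResult] = []
    for mtry in config.mtry_grid:
        scores = cross_val_score(
            _forest(config.n_trees, mtry, config.seed), X, y, cv=cv, scoring="accuracy"
        )
        results.append(CvResult(mtry, float(scores.mean()), float(scores.std(ddof=1))))
        logger.info(
            "cv mtry=%d: accuracy %.4f +/- %.4f", mtry, scores.mean(), scores.std()
        )
    best = max(results, key=lambda r: (r.mean_accuracy, -r.mtry))
    forest = _forest(config.n_trees, best.mtry, config.seed).fit(X, y)
    perm = permutation_importance(
        forest, X, y, n_repeats=5, random_state=config.seed, n_jobs=1
    )
    model = TrainedModel(
        forest=forest,
        feature_order=FEATURE_NAMES,
        chosen_mtry=best.mtry,
        n_trees=config.n_trees,
        orf_config=orf_config,
        genetic_code_id=genetic_code_id,
        variance_convention=VARIANCE_CONVENTION,
        format_version=MODEL_FORMAT_VERSION,
        seed=config.seed,
        permutation_importances=np.asarray(perm.importances_mean),
    )
    return model, results


def _check_matrix(
    model: TrainedModel, feature_matrix: pd.DataFrame | np.ndarray
) -> np.ndarray:
    if isinstance(feature_matrix, pd.DataFrame):
        if tuple(feature_matrix.columns) != tuple(model.feature_order):
            raise ModelError(
                "feature columns do not match the model; expected order: "
                + ", ".join(model.feature_order)
            )
        X = feature_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(feature_matrix, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(model.feature_order):
            raise ModelError(
                f"feature matrix must have {len(model.feature_order)} columns "
                "in canonical order: " + ", ".join(model.feature_order)
            )
    if not np.isfinite(X).all():
        raise ModelError("non-finite values in feature matrix")
    return X


def vote_fraction(model: TrainedModel, feature_matrix) -> np.ndarray:
    """Fraction of trees voting 'coding' for each row."""
    X = _check_matrix(model, feature_matrix)
    votes = np.zeros(X.shape[0])
    for tree in model.forest.estimators_:
        votes += tree.predict(X) == 1
    return votes / len(model.forest.estimators_)


def predict(
    model: TrainedModel,
    feature_matrix: pd.DataFrame | np.ndarray,
    refs: Sequence[tuple[str, int, int, str]] | None = None,
    threshold: float = 0.5,
) -> list[Prediction]:
    """Deterministic per-row predictions; p_coding is the tree-vote fraction.

    ``label == 'coding'`` iff ``p_coding >= threshold``.
    """
    p = vote_fraction(model, feature_matrix)
    if refs is None:
        refs = [("row", i + 1, i + 1, "+") for i in range(len(p))]
    if len(refs) != len(p):
        raise ModelError("refs length does not match feature matrix rows")
    return [
        Prediction(
            tuple(r), float(pi), "coding" if pi >= threshold else "intergenic"
        )
        for r, pi in zip(refs, p)
    ]


def feature_importance(
    model: TrainedModel, kind: Literal["permutation", "gini"] = "permutation"
) -> list[tuple[str, float]]:
    """Ranked (feature, importance) with the top feature scaled to 100."""
    if kind == "permutation":
        raw = model.permutation_importances.astype(float)
    elif kind == "gini":
        raw = model.forest.feature_importances_.astype(float)
    else:
        raise ValueError(f"unknown importance kind {kind!r}")
    raw = np.clip(raw, 0.0, None)
    scale = raw.max()
    scaled = raw * (100.0 / scale) if scale > 0 else raw
    ranked = sorted(
        zip(model.feature_order, scaled), key=lambda t: t[1], reverse=True
    )
    return [(name, float(v)) for name, v in ranked]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist as one archive: metadata block + serialized forest."""
    payload = {
        "format_version": model.format_version,
        "metadata": {
            "feature_order": list(model.feature_order),
            "chosen_mtry": model.chosen_mtry,
            "n_trees": model.n_trees,
            "orf_config": model.orf_config.to_dict(),
            "genetic_code_id": model.genetic_code_id,
            "variance_convention": model.variance_convention,
            "seed": model.seed,
            "decision_threshold": model.decision_threshold,
            "permutation_importances": model.permutation_importances.tolist(),
        },
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model archive, refusing incompatible format versions."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted / not a joblib archive
        raise ModelFormatError(f"{path}: unreadable model file ({exc})") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path}: not a model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: format version {payload['format_version']!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    md = payload["metadata"]
    return TrainedModel(
        forest=payload["forest"],
        feature_order=tuple(md["feature_order"]),
        chosen_mtry=int(md["chosen_mtry"]),
        n_trees=int(md["n_trees"]),
        orf_config=OrfConfig.from_dict(md["orf_config"]),
        genetic_code_id=int(md["genetic_code_id"]),
        variance_convention=md["variance_convention"],
        format_version=payload["format_version"],
        seed=int(md["seed"]),
        permutation_importances=np.asarray(md["permutation_importances"]),
        decision_threshold=float(md["decision_threshold"]),
    )
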