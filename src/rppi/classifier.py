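"""Cascaded rescoring layer: a random forest over the original score + RP features.

The second-stage classifier is trained on the known positives plus an
equally sized random subsample of negatives, with stratified k-fold
cross-validation providing out-of-fold confidences.  The confidence of a
pair is the fraction of the forest's trees voting positive, so its
granularity is 1/t.  Feature-subset ablation conditions select columns by
feature type (Rank / Score / Fold), alone or combined with the original
score.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import features as ft
from .curves import KneeEstimate
from .matrix import GlobalThreshold, LabelSet, RPError, ScoreMatrix

MODEL_FORMAT_VERSION = 1

#: Ablation condition -> feature types included ("Original" is the raw score).
CONDITIONS: dict[str, tuple[str, ...]] = {
    "original": ("Original",),
    "rank": ("Rank",),
    "score": ("Score",),
    "fold": ("Fold",),
    "original+rank": ("Original", "Rank"),
    "original+score": ("Original", "Score"),
    "original+fold": ("Original", "Fold"),
    "rp-enhanced": ("Original", "Rank", "Score", "Fold"),
}


class DatasetError(RPError):
    """Invalid balanced-dataset construction (pool too small, tiny class...)."""


def condition_columns(condition: str, table_columns: Sequence[str]) -> list[str]:
    """Columns of ``table_columns`` belonging to the condition's feature types."""
    try:
        types = CONDITIONS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; choose from {sorted(CONDITIONS)}"
        ) from None
    cols = [
        c
        for c in table_columns
        if ft.FEATURE_TYPE_OF.get(c) in types
    ]
    if not cols:
        raise ft.SchemaError(f"no columns of types {types} in the feature table")
    return cols


@dataclass
class LabeledDataset:
    """A balanced, fold-assigned feature table ready for CV training."""

    table: pd.DataFrame
    labels: np.ndarray
    folds: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.folds = np.asarray(self.folds, dtype=int)
        if not (len(self.table) == len(self.labels) == len(self.folds)):
            raise DatasetError("table, labels and folds must have equal length")


@dataclass
class RescoringModel:
    """A trained rescoring ensemble with per-fold sub-models.

    ``final_model`` is trained on the full balanced dataset and is the one
    applied genome-wide; ``fold_models`` realize the out-of-fold protocol.
    """

    condition: str
    columns: list[str]
    t: int
    seed: int
    final_model: RandomForestClassifier
    fold_models: list[RandomForestClassifier] = field(default_factory=list)

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "condition": self.condition,
                "columns": list(self.columns),
                "t": self.t,
                "seed": self.seed,
                "final_model": self.final_model,
                "fold_models": self.fold_models,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "RescoringModel":
        blob = joblib.load(path)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ft.SchemaError("unsupported model archive version")
        return cls(
            condition=blob["condition"],
            columns=blob["columns"],
            t=blob["t"],
            seed=blob["seed"],
            final_model=blob["final_model"],
            fold_models=blob["fold_models"],
        )


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def all_candidate_pairs(matrix: ScoreMatrix, include_self: bool = False) -> list[tuple[str, str]]:
    """All scored unordered pairs of an intra-species matrix (canonical order)."""
    pairs = []
    for a, b, _ in matrix.iter_pairs():
        if a == b and not include_self:
            continue
        pairs.append(ft.canonical_pair(a, b))
    return pairs


def sample_balanced_negatives(
    matrix: ScoreMatrix,
    positives: LabelSet,
    seed: int,
    include_self: bool = False,
) -> list[tuple[str, str]]:
    """|positives| unique negative pairs, sampled without replacement.

    The candidate pool is every scored pair not in the positive set;
    self-pairs are excluded by default.  Deterministic under ``seed``.
    """
    pool = [p for p in all_candidate_pairs(matrix, include_self) if p not in positives]
    k = len(positives)
    if len(pool) < k:
        raise DatasetError(
            f"negative pool ({len(pool)} pairs) smaller than positive set ({k})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def assign_folds(labels: Sequence[int], k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold ids (0..k-1), class proportions within +-1 row per fold."""
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("need at least 2 folds")
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise DatasetError(f"class {cls} has fewer than {k} rows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = f
    return folds


def build_dataset(
    matrix: ScoreMatrix,
    positives: LabelSet,
    knees: Mapping[str, KneeEstimate],
    global_t: GlobalThreshold,
    seed: int,
    k: int = 5,
    symmetric_mode: bool = False,
    feature_table: pd.DataFrame | None = None,
) -> LabeledDataset:
    """Balanced labeled dataset: all positives + matched negatives, with folds.

    When a precomputed full-pair ``feature_table`` is supplied, rows are
    selected from it; otherwise features are computed for the sampled pairs.
    """
    pos = [ft.canonical_pair(*p) for p in positives]
    neg = sample_balanced_negatives(matrix, positives, seed=seed)
    pairs = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg))
    if feature_table is not None:
        table = feature_table.loc[pairs]
    else:
        table = ft.build_feature_table(
            pairs, matrix, knees, global_t, symmetric_mode=symmetric_mode
        )
    folds = assign_folds(labels, k=k, seed=seed)
    return LabeledDataset(table=table, labels=labels, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _make_forest(t: int, seed: int) -> RandomForestClassifier:
    # frozen hyperparameters: unbounded depth, sqrt(F) features per split
    return RandomForestClassifier(
        n_estimators=t,
        max_depth=None,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def _vote_fraction(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the positive class (granularity 1/t)."""
    votes = np.zeros(len(X))
    for tree in forest.estimators_:
        votes += tree.predict(X)
    return votes / len(forest.estimators_)


def train_and_score(
    dataset: LabeledDataset,
    condition: str = "rp-enhanced",
    t: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold confidences: each row scored by the model not trained on it."""
    cols = condition_columns(condition, dataset.table.columns)
    X = dataset.table[cols].to_numpy(dtype=float)
    y = dataset.labels
    conf = np.full(len(y), np.nan)
    for f in np.unique(dataset.folds):
        train = dataset.folds != f
        if len(np.unique(y[train])) < 2:
            raise DatasetError(f"training split for fold {f} is single-class")
        forest = _make_forest(t, seed=seed + int(f))
        forest.fit(X[train], y[train])
        conf[~train] = _vote_fraction(forest, X[~train])
    return conf


def fit_rescoring_model(
    dataset: LabeledDataset,
    condition: str = "rp-enhanced",
    t: int = 100,
    seed: int = 0,
) -> RescoringModel:
    """Fit per-fold sub-models plus a final model on the full balanced set."""
    cols = condition_columns(condition, dataset.table.columns)
    X = dataset.table[cols].to_numpy(dtype=float)
    y = dataset.labels
    fold_models = []
    for f in np.unique(dataset.folds):
        train = dataset.folds != f
        forest = _make_forest(t, seed=seed + int(f))
        forest.fit(X[train], y[train])
        fold_models.append(forest)
    final = _make_forest(t, seed=seed + len(fold_models))
    final.fit(X, y)
    return RescoringModel(
        condition=condition,
        columns=cols,
        t=t,
        seed=seed,
        final_model=final,
        fold_models=fold_models,
    )


def rescore_all(
    matrix: ScoreMatrix,
    knees: Mapping[str, KneeEstimate],
    global_t: GlobalThreshold,
    model: RescoringModel,
    symmetric_mode: bool = False,
) -> pd.DataFrame:
    """Apply a trained model to every pair of the matrix.

    Returns a frame (id_a, id_b, original_score, rp_confidence) sorted by
    descending confidence; confidences are multiples of 1/t.
    """
    table = ft.full_pair_table(matrix, knees, global_t, symmetric_mode=symmetric_mode)
    missing = [c for c in model.columns if c not in table.columns]
    if missing:
        raise ft.SchemaError(
            f"feature table is missing model columns: {missing}"
        )
    conf = _vote_fraction(model.final_model, table[model.columns].to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "id_a": table.index.get_level_values(0),
            "id_b": table.index.get_level_values(1),
            "original_score": table[ft.ORIGINAL_COLUMN].to_numpy(),
            "rp_confidence": conf,
        }
    )
    return out.sort_values(
        ["rp_confidence", "id_a", "id_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
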