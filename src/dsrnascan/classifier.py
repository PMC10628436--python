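"""Random-forest window classifier: training-set curation, cross-validation
and permutation-based feature contributions.

The positive class is the set of curated (editing-derived, structure
verified) dsRNA regions; controls are random genomic windows matched in
number and subject to the same read-support requirements — which, in
practice, makes them enriched for spliced loci, the confusable case the
features were designed to reject. The forest hyperparameters are fixed
defaults of the package (gini splits, bootstrapped, unlimited depth,
min_samples_split 2, min_samples_leaf 4, 20% of features per split, 100
trees); everything else follows the scikit-learn defaults recorded in the
model artifact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .alignment_io import AlignedRead, GenomicInterval, index_reads_by_window
from .eer_annotation import CuratedDsRNA
from .feature_extraction import (
    FEATURE_NAMES,
    chromosome_length,
    chromosome_names,
    extract_features,
    features_to_frame,
)

DEFAULT_WINDOW_SIZE = 2500
DEFAULT_MIN_READS = 6


@dataclass(frozen=True)
class ModelConfig:
    """Fixed random-forest hyperparameters (all overridable)."""

    split_criterion: str = "gini"
    bootstrap: bool = True
    max_depth: int | None = None
    min_samples_split: int = 2
    min_samples_leaf: int = 4
    max_features_fraction: float = 0.20
    n_trees: int = 100
    random_seed: int = 0

    def to_estimator(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            criterion=self.split_criterion,
            bootstrap=self.bootstrap,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features_fraction,
            n_estimators=self.n_trees,
            random_state=self.random_seed,
            n_jobs=1,
        )


@dataclass
class TrainingSet:
    """Balanced feature table with labels and per-row provenance intervals."""

    table: pd.DataFrame  # columns: chrom, start, end, 38 features, label

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.table.columns]
        if missing:
            raise ValueError(f"training table lacks feature columns {missing[:3]}...")
        if "label" not in self.table.columns:
            raise ValueError("training table lacks a label column")

    @property
    def X(self) -> pd.DataFrame:
        return self.table.loc[:, list(FEATURE_NAMES)]

    @property
    def y(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=int)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.X.to_numpy(dtype=float).tobytes())
        h.update(self.y.tobytes())
        return h.hexdigest()


@dataclass
class TrainedModel:
    """A fitted forest bound to its feature order and training provenance."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: ModelConfig
    training_fingerprint: str
    estimator_params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CVReport:
    fold_accuracies: tuple[float, ...]
    roc_auc: float
    auprc: float

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass(frozen=True)
class ImportanceReport:
    baseline_r2: float
    contributions: dict[str, float]  # baseline R^2 minus permuted R^2, mean over repeats
    repeats: int
    seed: int

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.contributions.items(), key=lambda kv: -kv[1])


def curate_training_set(
    positives: Sequence[CuratedDsRNA],
    reference,
    reads: Sequence[AlignedRead],
    seed: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_reads: int = DEFAULT_MIN_READS,
    max_attempts_factor: int = 100,
) -> TrainingSet:
    """Build a balanced table of positive and random-control windows.

    Positive rows are the curated regions (centred into ``window_size``-nt
    windows) that satisfy the read-support requirement of >= ``min_reads``
    overlapping reads with >= 1 internal skip. Controls are uniform random
    windows rejected on overlap with any positive or on failing the same
    read requirement, resampled until the class counts match.
    """
    if not positives:
        raise ValueError("cannot curate a training set without positive regions")
    rng = np.random.default_rng(seed)
    pos_intervals = [p.interval for p in positives]
    rows: list[tuple[GenomicInterval, object]] = []
    labels: list[int] = []
    kept_pos: list[GenomicInterval] = []
    for iv in pos_intervals:
        win = _centered_window(iv, window_size, chromosome_length(reference, iv.chrom))
        idx = index_reads_by_window(reads, win)
        if idx.total_reads < min_reads or idx.skipping_reads < 1:
            continue
        rows.append((win, extract_features(win, reads, reference)))
        labels.append(1)
        kept_pos.append(win)
    if not rows:
        raise ValueError("no positive region satisfies the read-support requirement")
    needed = len(kept_pos)
    chroms = chromosome_names(reference)
    weights = np.array([chromosome_length(reference, c) for c in chroms], dtype=float)
    weights /= weights.sum()
    controls: list[GenomicInterval] = []
    attempts = 0
    max_attempts = max_attempts_factor * needed
    while len(controls) < needed:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not sample enough control windows: "
                f"{len(controls)}/{needed} after {attempts} attempts"
            )
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        chrom_len = chromosome_length(reference, chrom)
        if chrom_len < window_size:
            continue
        start = int(rng.integers(0, chrom_len - window_size + 1))
        win = GenomicInterval(chrom, start, start + window_size)
        if any(win.overlaps(p) for p in pos_intervals):
            continue
        idx = index_reads_by_window(reads, win)
        if idx.total_reads < min_reads or idx.skipping_reads < 1:
            continue
        controls.append(win)
        rows.append((win, extract_features(win, reads, reference)))
        labels.append(0)
    return TrainingSet(features_to_frame(rows, labels))


def _centered_window(
    iv: GenomicInterval, window_size: int, chrom_len: int
) -> GenomicInterval:
    if iv.length >= window_size:
        return iv
    center = (iv.start + iv.end) // 2
    start = max(0, center - window_size // 2)
    end = min(chrom_len, start + window_size)
    start = max(0, end - window_size)
    return GenomicInterval(iv.chrom, start, end)


def train_model(ts: TrainingSet, config: ModelConfig | None = None) -> TrainedModel:
    config = config or ModelConfig()
    y = ts.y
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    forest = config.to_estimator()
    forest.fit(ts.X.to_numpy(dtype=float), y)
    return TrainedModel(
        forest=forest,
        feature_names=tuple(FEATURE_NAMES),
        config=config,
        training_fingerprint=ts.fingerprint(),
        estimator_params=forest.get_params(),
    )


def predict_proba(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Positive-class probability per row; columns are aligned by name."""
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise KeyError(f"feature column(s) missing: {missing}")
    X = features.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    return model.forest.predict_proba(X)[:, 1]


def cross_validate(
    ts: TrainingSet,
    k: int = 20,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV; pooled out-of-fold probabilities give one ROC
    AUC and one AUPRC."""
    config = config or ModelConfig(random_seed=seed)
    X = ts.X.to_numpy(dtype=float)
    y = ts.y
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available rows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accuracies: list[float] = []
    pooled_proba = np.zeros(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        forest = config.to_estimator()
        forest.fit(X[train_idx], y[train_idx])
        proba = forest.predict_proba(X[test_idx])[:, 1]
        pooled_proba[test_idx] = proba
        accuracies.append(accuracy_score(y[test_idx], (proba > 0.5).astype(int)))
    return CVReport(
        fold_accuracies=tuple(accuracies),
        roc_auc=float(roc_auc_score(y, pooled_proba)),
        auprc=float(average_precision_score(y, pooled_proba)),
    )


def permutation_importance(
    model: TrainedModel,
    heldout: TrainingSet,
    repeats: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation-based contribution scores on held-out data.

    The baseline is the coefficient of determination (R^2) between the 0/1
    label and the predicted positive-class probability; each feature's score
    is the mean drop in R^2 across ``repeats`` independent permutations of
    that column with all others fixed.
    """
    if len(heldout.table) == 0:
        raise ValueError("held-out set is empty")
    rng = np.random.default_rng(seed)
    X = heldout.X.to_numpy(dtype=float)
    y = heldout.y
    baseline = r2_score(y, model.forest.predict_proba(X)[:, 1])
    contributions: dict[str, float] = {}
    for col, name in enumerate(model.feature_names):
        drops = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, col] = Xp[rng.permutation(len(y)), col]
            permuted = r2_score(y, model.forest.predict_proba(Xp)[:, 1])
            drops.append(baseline - permuted)
        contributions[name] = float(np.mean(drops))
    return ImportanceReport(
        baseline_r2=float(baseline),
        contributions=contributions,
        repeats=repeats,
        seed=seed,
    )


def save_model(model: TrainedModel, path: str) -> None:
    joblib.dump(
        {
            "forest": model.forest,
            "feature_names": model.feature_names,
            "config": model.config,
            "training_fingerprint": model.training_fingerprint,
            "estimator_params": model.estimator_params,
        },
        path,
    )


def load_model(path: str) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(
        forest=payload["forest"],
        feature_names=tuple(payload["feature_names"]),
        config=payload["config"],
        training_fingerprint=payload["training_fingerprint"],
        estimator_params=payload.get("estimator_params", {}),
    )
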