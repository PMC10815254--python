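"""Seed scan and repeated stratified cross-validation.

Model assessment treats every frame as an individual sample: the labeled
latent frames are randomly permuted, stratified into four folds, and the
classifier is retrained on each training split (with SMOTE re-applied
inside the split only, so no synthetic point leaks into a test fold).
Five repeats of the four-fold split train 20 models in total.

The seed scan retrains the whole pipeline under a grid of pseudo seeds
(default 0, 100, ..., 10000) and keeps the seed that calls the fewest
unlabeled variants deleterious — a guard against over-predicting
deleteriousness, which is the dominant failure mode of in-silico variant
classifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import (
    ClassifierConfig,
    LabeledLatentSet,
    compute_metrics,
    smote_balance,
    train_classifier,
)
from .datatypes import ValidationError

logger = logging.getLogger(__name__)

#: seed grid: 0 to 10,000 with a bin size of 100
DEFAULT_SEED_GRID = tuple(range(0, 10001, 100))


@dataclass
class CVReport:
    """Per-(repeat, fold) train/test AUC and accuracy, plus fold bookkeeping."""

    results: pd.DataFrame  # columns: repeat, fold, train_auc, test_auc, ...
    fold_assignments: list[np.ndarray]  # per repeat: fold id of every sample
    folds: int
    repeats: int

    @property
    def n_models(self) -> int:
        return len(self.results)

    @property
    def mean_train_auc(self) -> float:
        return float(self.results["train_auc"].mean())

    @property
    def mean_test_auc(self) -> float:
        return float(self.results["test_auc"].mean())

    def summary(self) -> dict:
        return {
            "folds": self.folds,
            "repeats": self.repeats,
            "n_models": self.n_models,
            "mean_train_auc": self.mean_train_auc,
            "mean_test_auc": self.mean_test_auc,
            "mean_train_accuracy": float(self.results["train_accuracy"].mean()),
            "mean_test_accuracy": float(self.results["test_accuracy"].mean()),
            "mean_test_balanced_accuracy": float(
                self.results["test_balanced_accuracy"].mean()
            ),
        }


def cross_validate(
    data: LabeledLatentSet,
    folds: int = 4,
    repeats: int = 5,
    seed: int = 0,
    classifier_config: ClassifierConfig | None = None,
    apply_smote: bool = True,
    smote_k: int = 5,
    groups: np.ndarray | None = None,
) -> CVReport:
    """Repeated stratified cross-validation at frame level.

    Each repeat permutes the samples, stratifies them into ``folds`` folds
    (class proportions within one sample of each other across folds) and
    trains ``folds`` classifiers, for ``folds * repeats`` models overall.

    ``groups`` switches to variant-grouped splitting: all frames of a
    variant land in the same fold, removing the within-variant train/test
    leakage that frame-level splitting allows.
    """
    counts = np.bincount(data.labels, minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"smallest class has {counts.min()} samples, fewer than {folds} folds"
        )
    if classifier_config is None:
        classifier_config = ClassifierConfig(seed=seed)

    rows = []
    assignments: list[np.ndarray] = []
    for repeat in range(repeats):
        rep_seed = seed + repeat
        if groups is None:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
            split_iter = splitter.split(data.latents, data.labels)
        else:
            split_iter = _grouped_stratified_splits(
                data.labels, np.asarray(groups), folds, rep_seed
            )
        fold_of = np.full(data.n, -1, dtype=int)
        for fold, (train_idx, test_idx) in enumerate(split_iter):
            fold_of[test_idx] = fold
            train = LabeledLatentSet(
                data.latents[train_idx],
                data.labels[train_idx],
                data.variant_ids[train_idx],
            )
            if apply_smote:
                train = smote_balance(train, k_neighbors=smote_k, seed=rep_seed)
            cfg = ClassifierConfig(
                hidden_layers=classifier_config.hidden_layers,
                width=classifier_config.width,
                dropout=classifier_config.dropout,
                learning_rate=classifier_config.learning_rate,
                epochs=classifier_config.epochs,
                batch_size=classifier_config.batch_size,
                leaky_slope=classifier_config.leaky_slope,
                seed=rep_seed * folds + fold + classifier_config.seed,
            )
            model = train_classifier(train, cfg)
            m_train = compute_metrics(
                model.predict_deleterious(data.latents[train_idx]),
                data.labels[train_idx],
            )
            m_test = compute_metrics(
                model.predict_deleterious(data.latents[test_idx]),
                data.labels[test_idx],
            )
            rows.append(
                {
                    "repeat": repeat,
                    "fold": fold,
                    "train_auc": m_train.auc,
                    "test_auc": m_test.auc,
                    "train_accuracy": m_train.accuracy,
                    "test_accuracy": m_test.accuracy,
                    "train_balanced_accuracy": m_train.balanced_accuracy,
                    "test_balanced_accuracy": m_test.balanced_accuracy,
                }
            )
            logger.info(
                "cv repeat %d fold %d: train AUC %.4f test AUC %.4f",
                repeat, fold, m_train.auc, m_test.auc,
            )
        assignments.append(fold_of)
    return CVReport(
        results=pd.DataFrame(rows),
        fold_assignments=assignments,
        folds=folds,
        repeats=repeats,
    )


def _grouped_stratified_splits(labels, groups, folds, seed):
    """Variant-grouped folds balancing class counts greedily."""
    rng = np.random.default_rng(seed)
    uniq = np.unique(groups)
    rng.shuffle(uniq)
    # assign groups round-robin per class so each fold sees both classes
    fold_of_group: dict = {}
    for cls in (0, 1):
        cls_groups = [g for g in uniq if labels[groups == g][0] == cls]
        for i, g in enumerate(cls_groups):
            fold_of_group[g] = i % folds
    fold_ids = np.array([fold_of_group[g] for g in groups])
    for f in range(folds):
        test = np.flatnonzero(fold_ids == f)
        train = np.flatnonzero(fold_ids != f)
        yield train, test


@dataclass
class SeedScanResult:
    """Outcome of the pseudo-seed grid search."""

    table: pd.DataFrame  # columns: seed, n_deleterious_calls, mean_test_auc, failed
    chosen_seed: int = field(init=False)

    def __post_init__(self) -> None:
        ok = self.table[~self.table["failed"]]
        if ok.empty:
            raise ValidationError("every seed in the scan failed")
        # fewest deleterious calls; ties broken by the smallest seed
        ok = ok.sort_values(["n_deleterious_calls", "seed"])
        self.chosen_seed = int(ok.iloc[0]["seed"])


def scan_seeds(
    labeled_trajectories=None,
    unlabeled_trajectories=None,
    seeds: Sequence[int] = DEFAULT_SEED_GRID,
    pipeline_config=None,
    evaluate: Callable[[int], tuple[int, float]] | None = None,
) -> SeedScanResult:
    """Choose the pseudo seed that minimizes deleterious calls on the VUS set.

    For each seed the full pipeline (autoencoder + classifier) is retrained
    and the unlabeled variants are classified; the seed with the lowest
    number of deleterious calls wins.  ``evaluate`` overrides the default
    pipeline run with any ``seed -> (n_deleterious_calls, mean_test_auc)``
    callable (used for fast scans and testing).
    """
    if not len(seeds):
        raise ValidationError("seed list must be non-empty")
    if evaluate is None:
        if labeled_trajectories is None or not unlabeled_trajectories:
            raise ValidationError(
                "seed scan needs labeled and unlabeled trajectories (or an "
                "evaluate callable)"
            )
        from .pipeline import PipelineConfig, fit_pipeline, predict_variants

        config = pipeline_config or PipelineConfig()

        def evaluate(seed: int) -> tuple[int, float]:
            fitted = fit_pipeline(labeled_trajectories, config, seed=seed)
            preds = predict_variants(fitted, unlabeled_trajectories)
            n_del = sum(p.call == "deleterious" for p in preds)
            return n_del, fitted.cv_report.mean_test_auc if fitted.cv_report else np.nan

    rows = []
    for s in seeds:
        try:
            n_del, auc = evaluate(int(s))
            rows.append(
                {"seed": int(s), "n_deleterious_calls": n_del,
                 "mean_test_auc": auc, "failed": False}
            )
        except Exception as exc:  # a diverged seed is excluded, not fatal
            warnings.warn(f"seed {s} failed: {exc}", stacklevel=2)
            rows.append(
                {"seed": int(s), "n_deleterious_calls": -1,
                 "mean_test_auc": np.nan, "failed": True}
            )
    return SeedScanResult(table=pd.DataFrame(rows))
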