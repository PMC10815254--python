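"""End-to-end orchestration: manifest to per-variant probability table.

Stage order: parse -> (optional window) -> fit FeatureSpace on labeled
frames only -> time-lagged pairs -> autoencoder training -> encode all
frames -> SMOTE-balance the labeled latents -> classifier training ->
cross-validation -> classify unknown variants -> aggregate frame
probabilities per variant.

Unknown (VUS) trajectories never influence standardization, the
autoencoder, or the classifier: they are encoded with the frozen model and
scored only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autoencoder import AEConfig, AutoencoderModel, encode, save_checkpoint, train_autoencoder
from .classifier import (
    ClassifierConfig,
    ClassifierModel,
    LabeledLatentSet,
    binary_labels_from_meta,
    smote_balance,
    train_classifier,
)
from .datatypes import RSPTrajectory, ValidationError
from .features import FeatureSpace, fit_feature_space, make_lagged_pairs, standardized_frames
from .model_selection import CVReport, cross_validate
from .torsion_io import LabelManifest

logger = logging.getLogger(__name__)

HIGH_CONFIDENCE_THRESHOLD = 0.85


@dataclass(frozen=True)
class VariantPrediction:
    """Per-variant classification: P(U) + P(D) = 1, call = argmax.

    An exact 0.5/0.5 tie is called "unknown" (conservative).  A call is
    high-confidence when the winning probability exceeds 0.85.
    """

    variant_id: str
    n_frames: int
    p_unknown: float
    p_deleterious: float
    call: str
    high_confidence: bool


def aggregate_variant(
    frame_probs: np.ndarray, variant_id: str, aggregator: str = "mean"
) -> VariantPrediction:
    """Collapse per-frame P(deleterious) values into one variant call.

    ``mean`` averages frame probabilities; ``majority`` uses the fraction
    of frames voting deleterious at 0.5.
    """
    p = np.asarray(frame_probs, dtype=float)
    if p.size == 0:
        raise ValidationError(f"no frame probabilities for {variant_id!r}")
    if p.min() < 0 or p.max() > 1:
        raise ValidationError("frame probabilities must lie in [0, 1]")
    if aggregator == "mean":
        p_d = float(p.mean())
    elif aggregator == "majority":
        p_d = float(np.mean(p > 0.5))
    else:
        raise ValidationError(f"unknown aggregator {aggregator!r}")
    call = "deleterious" if p_d > 0.5 else "unknown"
    return VariantPrediction(
        variant_id=variant_id,
        n_frames=int(p.size),
        p_unknown=1.0 - p_d,
        p_deleterious=p_d,
        call=call,
        high_confidence=max(p_d, 1.0 - p_d) > HIGH_CONFIDENCE_THRESHOLD,
    )


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs besides the data."""

    autoencoder: AEConfig = field(default_factory=AEConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    lag: int = 1
    smote_k: int = 5
    apply_smote: bool = True
    smote_space: str = "latent"  # or "input": balance standardized frames pre-encoding
    cv_folds: int = 4
    cv_repeats: int = 5
    run_cv: bool = True
    aggregator: str = "mean"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FittedPipeline:
    feature_space: FeatureSpace
    autoencoder: AutoencoderModel
    classifier: ClassifierModel
    cv_report: CVReport | None
    config: PipelineConfig
    seed: int


def _with_seed(cfg, seed: int):
    return dataclasses.replace(cfg, seed=seed)


def fit_pipeline(
    labeled: list[RSPTrajectory], config: PipelineConfig | None = None, seed: int = 0
) -> FittedPipeline:
    """Train feature space, autoencoder and classifier on labeled data."""
    config = config or PipelineConfig()
    train_labels = {t.label for t in labeled}
    if "pathogenic" not in train_labels or not train_labels & {"benign", "wildtype"}:
        raise ValidationError(
            "training needs at least one pathogenic and one benign/wildtype trajectory"
        )
    if any(t.label == "unknown" for t in labeled):
        raise ValidationError("unknown-labeled trajectories cannot be used for training")

    logger.info("fitting feature space on %d labeled trajectories", len(labeled))
    space = fit_feature_space(labeled)

    logger.info("building time-lagged pairs (lag=%d)", config.lag)
    pairs = make_lagged_pairs(labeled, space, lag=config.lag)

    logger.info("training autoencoder on %d pairs", pairs.n_pairs)
    ae = train_autoencoder(pairs, _with_seed(config.autoencoder, seed), space)

    logger.info("encoding labeled frames")
    Z, meta = standardized_frames(labeled, space)
    y = binary_labels_from_meta(meta)
    ids = meta["variant_id"].to_numpy()
    if config.smote_space not in ("latent", "input"):
        raise ValidationError(f"unknown smote_space {config.smote_space!r}")
    if config.apply_smote and config.smote_space == "input":
        # balance standardized frames before encoding
        balanced_in = smote_balance(
            LabeledLatentSet(latents=Z, labels=y, variant_ids=ids),
            k_neighbors=config.smote_k, seed=seed,
        )
        Z, y, ids = balanced_in.latents, balanced_in.labels, balanced_in.variant_ids
    latents = LabeledLatentSet(
        latents=encode(ae, Z), labels=y, variant_ids=ids
    )

    cv_report = None
    if config.run_cv:
        logger.info(
            "cross-validation: %d folds x %d repeats", config.cv_folds, config.cv_repeats
        )
        cv_report = cross_validate(
            latents,
            folds=config.cv_folds,
            repeats=config.cv_repeats,
            seed=seed,
            classifier_config=_with_seed(config.classifier, seed),
            apply_smote=config.apply_smote and config.smote_space == "latent",
            smote_k=config.smote_k,
        )

    balanced = (
        smote_balance(latents, k_neighbors=config.smote_k, seed=seed)
        if config.apply_smote and config.smote_space == "latent"
        else latents
    )
    logger.info(
        "training final classifier on %d latent rows (%d after balancing)",
        latents.n, balanced.n,
    )
    clf = train_classifier(balanced, _with_seed(config.classifier, seed))
    return FittedPipeline(
        feature_space=space,
        autoencoder=ae,
        classifier=clf,
        cv_report=cv_report,
        config=config,
        seed=seed,
    )


def predict_variants(
    fitted: FittedPipeline, unknowns: list[RSPTrajectory]
) -> list[VariantPrediction]:
    """Score unknown variants with the frozen pipeline, one row per variant."""
    preds = []
    for traj in unknowns:
        Z, _ = standardized_frames([traj], fitted.feature_space)
        frame_p = fitted.classifier.predict_deleterious(encode(fitted.autoencoder, Z))
        preds.append(
            aggregate_variant(frame_p, traj.variant_id, fitted.config.aggregator)
        )
    return preds


def predictions_frame(preds: list[VariantPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [p.variant_id for p in preds],
            "n_frames": [p.n_frames for p in preds],
            "P_unknown": [p.p_unknown for p in preds],
            "P_deleterious": [p.p_deleterious for p in preds],
            "call": [p.call for p in preds],
            "high_confidence": [p.high_confidence for p in preds],
        }
    )


def run_pipeline(
    manifest: LabelManifest,
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> tuple[pd.DataFrame | None, CVReport | None, FittedPipeline]:
    """Full run from a label manifest; optionally write all artifacts.

    Returns (predictions table or None if the manifest has no unknowns,
    CV report, fitted pipeline).
    """
    config = config or PipelineConfig()
    trajectories = manifest.load_trajectories()
    labeled = [t for t in trajectories if t.label != "unknown"]
    unknowns = [t for t in trajectories if t.label == "unknown"]
    logger.info(
        "manifest: %d labeled, %d unknown trajectories", len(labeled), len(unknowns)
    )

    fitted = fit_pipeline(labeled, config, seed=seed)
    preds_df = None
    if unknowns:
        preds_df = predictions_frame(predict_variants(fitted, unknowns))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if preds_df is not None:
            preds_df.to_csv(out / "predictions.csv", index=False)
        if fitted.cv_report is not None:
            fitted.cv_report.results.to_csv(out / "cv_report.csv", index=False)
            (out / "cv_summary.json").write_text(
                json.dumps(fitted.cv_report.summary(), indent=2)
            )
        save_checkpoint(fitted.autoencoder, out / "autoencoder.ckpt")
        np.savez(
            out / "classifier.npz",
            **{f"W{i}": w for i, w in enumerate(fitted.classifier.net.weights)},
            **{f"b{i}": b for i, b in enumerate(fitted.classifier.net.biases)},
        )
        run_manifest = {
            "seed": seed,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_labeled": len(labeled),
            "n_unknown": len(unknowns),
            "python": platform.python_version(),
            "numpy": np.__version__,
        }
        (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
        logger.info("artifacts written to %s", out)
    return preds_df, fitted.cv_report, fitted
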