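"""End-to-end orchestration: images → segmentation → features →
training/prediction, plus evaluation metrics and cross-validation.

The evaluation report follows the conventions of the classification
study it supports: sensitivity, specificity and accuracy in percent,
AUROC in [0, 1].  For two classes, sensitivity/specificity use the usual
positive-class (label 1) definition; for more classes they are
one-vs-rest per class and macro-averaged.  AUROC is the macro-averaged
one-vs-rest area computed from the raw network scores by the rank
statistic, so it is invariant under any strictly monotone rescaling of
the scores.

Features are min-max scaled to [0, 1] using training-fold statistics
only: the raw descriptor ranges differ by orders of magnitude (LRHGE vs
angular second moment) and would otherwise saturate the Gaussian units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import confusion_matrix, roc_auc_score

from . import gaussian_net as gnet
from .image import GrayImage, load_image, quantize
from .rcga import RCGAConfig
from .segmentation import segment
from .texture import FEATURE_NAMES, feature_vector

logger = logging.getLogger("lungtex")

LABEL_COLUMN = "label"
ID_COLUMN = "id"


@dataclass
class PipelineConfig:
    """Aggregated settings for the full image-to-prediction pipeline."""

    gray_levels: int = 8
    glcm_distance: int = 1
    threshold: int | None = None          # None -> Otsu
    selem_radius: int = 2
    feature_scope: str = "segmented"      # "segmented" | "whole"
    training: gnet.TrainingConfig = field(default_factory=gnet.TrainingConfig)
    ga: RCGAConfig = field(default_factory=RCGAConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_scope not in ("segmented", "whole"):
            raise ValueError("feature_scope must be 'segmented' or 'whole'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        training = gnet.TrainingConfig(**doc.pop("training", {}))
        ga = RCGAConfig(**doc.pop("ga", {}))
        return cls(training=training, ga=ga, **doc)


@dataclass(frozen=True)
class EvaluationReport:
    confusion: np.ndarray                 # K x K, rows = truth
    sensitivity: float                    # percent
    specificity: float                    # percent
    accuracy: float                       # percent
    auroc: float | None                   # [0, 1]; None when no scores given
    per_class_accuracy: np.ndarray        # percent, NaN for absent classes

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion.tolist(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "per_class_accuracy": self.per_class_accuracy.tolist(),
        }


def evaluate(truths: np.ndarray, predictions: np.ndarray,
             scores: np.ndarray | None = None,
             n_classes: int | None = None) -> EvaluationReport:
    """Confusion-matrix metrics and macro one-vs-rest AUROC.

    ``scores`` is the (n_samples, K) matrix of raw classifier outputs;
    without it AUROC is reported as None.  Classes absent from the truth
    vector are excluded from the macro averages with a logged warning.
    """
    truths = np.asarray(truths, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if truths.shape != predictions.shape:
        raise ValueError("truths and predictions must have equal length")
    k = n_classes or int(max(truths.max(), predictions.max())) + 1
    cm = confusion_matrix(truths, predictions, labels=np.arange(k))
    total = cm.sum()
    accuracy = 100.0 * cm.trace() / total

    present = np.flatnonzero(cm.sum(axis=1) > 0)
    absent = sorted(set(range(k)) - set(present))
    if absent:
        logger.warning("classes %s absent from truths; excluded from macro averages",
                       absent)
    sens, spec, aucs = [], [], []
    per_class = np.full(k, np.nan)
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        if c in present:
            per_class[c] = 100.0 * tp / (tp + fn)
    if k == 2 and 1 in present and 0 in present:
        # binary convention: class 1 is the positive class
        tp, fn = cm[1, 1], cm[1, 0]
        tn, fp = cm[0, 0], cm[0, 1]
        sens = [100.0 * tp / (tp + fn)]
        spec = [100.0 * tn / (tn + fp)]
    else:
        for c in present:
            tp = cm[c, c]
            fn = cm[c].sum() - tp
            fp = cm[:, c].sum() - tp
            tn = total - tp - fn - fp
            sens.append(100.0 * tp / (tp + fn))
            spec.append(100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan)
    auroc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        for c in present:
            y_true = (truths == c).astype(int)
            if y_true.min() == y_true.max():
                continue                      # one-class fold: AUC undefined
            aucs.append(roc_auc_score(y_true, scores[:, c]))
        auroc = float(np.mean(aucs)) if aucs else None
    return EvaluationReport(cm, float(np.nanmean(sens)), float(np.nanmean(spec)),
                            float(accuracy), auroc, per_class)


class MinMaxScaler:
    """Per-feature min-max scaling to [0, 1] from training statistics only."""

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        span = X.max(axis=0) - self.min_
        self.span_ = np.where(span > 0, span, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.min_) / self.span_


def train_on_features(features: np.ndarray, labels: np.ndarray,
                      config: PipelineConfig, rng: np.random.Generator
                      ) -> tuple[gnet.NetworkParams, MinMaxScaler, gnet.TrainingHistory]:
    """Scale features, one-hot the labels, and run hybrid training."""
    labels = np.asarray(labels, dtype=int)
    n_classes = int(labels.max()) + 1
    scaler = MinMaxScaler().fit(features)
    one_hot = np.eye(n_classes)[labels]
    params, history = gnet.train_hybrid(scaler.transform(features), one_hot,
                                        config.training, config.ga, rng)
    return params, scaler, history


def cross_validate(features: np.ndarray, labels: np.ndarray,
                   config: PipelineConfig, n_splits: int | None = None
                   ) -> EvaluationReport:
    """Stratified k-fold (or leave-one-out) evaluation of the full classifier.

    ``n_splits=None`` performs leave-one-out: each sample is classified by
    a model trained on all the others.  Every fold reuses the same
    configuration with a fold-derived seed, and scaling statistics come
    from the training fold only.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_splits is None:
        folds = [np.array([i]) for i in range(n)]
    else:
        # stratified round-robin assignment keeps class balance per fold
        folds = [[] for _ in range(n_splits)]
        for c in np.unique(y):
            for pos, idx in enumerate(np.flatnonzero(y == c)):
                folds[pos % n_splits].append(idx)
        folds = [np.asarray(sorted(f)) for f in folds if len(f)]
    n_classes = int(y.max()) + 1
    predictions = np.empty(n, dtype=int)
    scores = np.empty((n, n_classes))
    for fold_id, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        rng = np.random.default_rng([config.seed, fold_id])
        params, scaler, _ = train_on_features(X[train_mask], y[train_mask],
                                              config, rng)
        pred, sc = gnet.predict(params, scaler.transform(X[test_idx]))
        predictions[test_idx] = pred
        scores[test_idx] = sc
    return evaluate(y, predictions, scores, n_classes=n_classes)


def loocv(features: np.ndarray, labels: np.ndarray,
          config: PipelineConfig) -> EvaluationReport:
    """Leave-one-out cross-validation: fold count equals sample count."""
    return cross_validate(features, labels, config, n_splits=None)


def extract_features(image: GrayImage, config: PipelineConfig) -> dict[str, float]:
    """Texture features of one 8-bit image under the configured scope.

    With scope "segmented", the image is thresholded and morphologically
    segmented first, and features are computed on the quantized bounding
    box of the extracted region (falling back to the whole image when the
    segmenter finds nothing).
    """
    px = image.pixels
    if config.feature_scope == "segmented":
        result = segment(image, config.threshold, config.selem_radius)
        if not result.is_empty:
            r0, r1, c0, c1 = result.bounding_box
            if r1 - r0 >= 1 and c1 - c0 >= 1:
                px = px[r0:r1 + 1, c0:c1 + 1]
    quantized = quantize(px, config.gray_levels, max_value=image.gray_levels - 1)
    return feature_vector(quantized, distance=config.glcm_distance)


def features_from_images(paths: list[str | Path], config: PipelineConfig
                         ) -> pd.DataFrame:
    """Feature table (one row per image) from PNG/PGM files."""
    rows = []
    for path in paths:
        image = load_image(path, gray_levels=None)
        feats = extract_features(image, config)
        rows.append({ID_COLUMN: Path(path).name, **feats})
    return pd.DataFrame(rows, columns=[ID_COLUMN, *FEATURE_NAMES])


def read_feature_csv(path: str | Path
                     ) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    """Read a feature CSV; returns (features, labels or None, ids)."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    features = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    labels = df[LABEL_COLUMN].to_numpy(dtype=int) if LABEL_COLUMN in df else None
    ids = (df[ID_COLUMN].astype(str).tolist() if ID_COLUMN in df
           else [str(i) for i in range(len(df))])
    return features, labels, ids


def write_feature_csv(path: str | Path, features: np.ndarray,
                      labels: np.ndarray | None = None,
                      ids: list[str] | None = None) -> None:
    df = pd.DataFrame(np.asarray(features, dtype=float), columns=list(FEATURE_NAMES))
    if ids is not None:
        df.insert(0, ID_COLUMN, ids)
    if labels is not None:
        df[LABEL_COLUMN] = np.asarray(labels, dtype=int)
    df.to_csv(path, index=False)


def write_history_csv(path: str | Path, history: gnet.TrainingHistory) -> None:
    pd.DataFrame({"epoch": history.epochs, "phase": history.phases,
                  "mse": history.mses, "best_mse": history.best_mses}
                 ).to_csv(path, index=False)


def save_model(path: str | Path, params: gnet.NetworkParams,
               scaler: MinMaxScaler | None = None) -> None:
    """Model JSON: network parameters plus the feature-scaling statistics."""
    import json
    n_in, n_hidden, n_out = params.topology
    doc = {
        "format": "lungtex-model",
        "version": 1,
        "topology": [n_in, n_hidden, n_out],
        "ordering": "v-rowmajor,v0,w-rowmajor,w0",
        "spread": params.spread,
        "genes": gnet.encode_params(params).tolist(),
    }
    if scaler is not None:
        doc["scaler_min"] = scaler.min_.tolist()
        doc["scaler_span"] = scaler.span_.tolist()
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> tuple[gnet.NetworkParams, MinMaxScaler | None]:
    import json
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "lungtex-model":
        raise ValueError(f"{path}: not a lungtex model file")
    n_in, n_hidden, n_out = doc["topology"]
    params = gnet.decode_params(np.asarray(doc["genes"], dtype=float),
                                n_in, n_hidden, n_out, doc["spread"])
    scaler = None
    if "scaler_min" in doc:
        scaler = MinMaxScaler()
        scaler.min_ = np.asarray(doc["scaler_min"], dtype=float)
        scaler.span_ = np.asarray(doc["scaler_span"], dtype=float)
    return params, scaler


def run_classify(features: np.ndarray, ids: list[str],
                 params: gnet.NetworkParams, scaler: MinMaxScaler | None = None
                 ) -> pd.DataFrame:
    """Per-sample predictions: one row per input (id, class, K scores)."""
    X = np.asarray(features, dtype=float)
    if scaler is not None:
        X = scaler.transform(X)
    pred, scores = gnet.predict(params, X)
    out = pd.DataFrame({ID_COLUMN: ids, "predicted_class": pred})
    for k in range(scores.shape[1]):
        out[f"score_{k}"] = scores[:, k]
    return out
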