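"""Trainable per-pixel classification of stained root micrographs.

A supervised classifier (random forest by default) is trained on manually
annotated pixels — fungal structures, uncolonized root tissue, and slide
background — each described by the 25-component feature vector from
:mod:`rootquant.feature_bank`.  Applied to a whole image it yields a total
label map from which the ml-index is computed.

Three classes are used rather than two so that the ml-index denominator
can be restricted to root tissue (colonized + non-colonized root), with
the slide background excluded; a flag allows including the background for
comparison.  The trained model is stored together with its feature
configuration and refuses to predict under a different configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier

from .errors import (
    ModelConfigMismatch,
    ModelVersionError,
    ValidationError,
)
from .feature_bank import FeatureConfig, compute_feature_stack, sample_features
from .metrics import ColonizationMeasure, ml_index, trouvelot_class
from .raster_io import GrayImage

__all__ = [
    "CLASS_NAMES",
    "AnnotationSet",
    "PixelModel",
    "LabelMap",
    "build_training_set",
    "train",
    "predict",
    "measure_ml",
    "save_model",
    "load_model",
    "export_training_folder",
    "import_training_folder",
]

MODEL_VERSION = "rootquant-pixel-model-1"

#: Label codes used in annotation masks and label maps.
UNLABELED = 0
CLASS_NAMES = ("colonized", "root_tissue", "background")
CLASS_CODES = {"colonized": 1, "root_tissue": 2, "background": 3}


@dataclass(frozen=True)
class AnnotationSet:
    """Paired images and sparse label masks.

    Each entry is ``(GrayImage, mask)`` where the mask assigns annotated
    pixels a code from :data:`CLASS_CODES` and leaves the rest 0
    (unlabeled).  At least two distinct classes must be present.
    """

    entries: tuple

    def __post_init__(self):
        entries = tuple(self.entries)
        for img, mask in entries:
            mask = np.asarray(mask)
            if mask.shape != img.geometry:
                raise ValidationError(
                    f"label mask shape {mask.shape} != image geometry {img.geometry}"
                )
            if mask.max(initial=0) > 3 or mask.min(initial=0) < 0:
                raise ValidationError("label masks may only contain codes 0..3")
        object.__setattr__(self, "entries", entries)

    @property
    def class_counts(self) -> dict:
        counts = {name: 0 for name in CLASS_NAMES}
        for _, mask in self.entries:
            mask = np.asarray(mask)
            for name, code in CLASS_CODES.items():
                counts[name] += int((mask == code).sum())
        return counts


@dataclass
class PixelModel:
    """A trained pixel classifier plus everything needed to reapply it."""

    classifier: RandomForestClassifier
    feature_config: FeatureConfig
    classes: tuple
    metadata: dict
    version: str = MODEL_VERSION


@dataclass(frozen=True)
class LabelMap:
    """Total per-pixel labeling; per-class areas partition the image."""

    labels: np.ndarray  # H x W of codes 1..3
    class_names: tuple

    def area(self, class_name: str) -> int:
        return int((self.labels == CLASS_CODES[class_name]).sum())

    @property
    def areas(self) -> dict:
        return {name: self.area(name) for name in self.class_names}


def config_hash(cfg: FeatureConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def build_training_set(annotations: AnnotationSet, cfg: FeatureConfig | None = None):
    """Turn sparse pixel annotations into a feature matrix and label vector.

    Returns ``(X, y)`` with one row of 25 features per annotated pixel and
    integer class codes in ``y``.  Requires at least two distinct classes
    and at least one annotated pixel.
    """
    if cfg is None:
        cfg = FeatureConfig()
    X_parts, y_parts = [], []
    for img, mask in annotations.entries:
        mask = np.asarray(mask)
        rows, cols = np.nonzero(mask)
        if len(rows) == 0:
            continue
        stack = compute_feature_stack(img, cfg)
        X_parts.append(sample_features(stack, list(zip(rows, cols))))
        y_parts.append(mask[rows, cols].astype(int))
    if not X_parts:
        raise ValidationError("annotation set contains no labeled pixels")
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValidationError(
            "training needs >= 2 annotated classes; got "
            + ", ".join(sorted({CLASS_NAMES[c - 1] for c in np.unique(y)}))
        )
    return X, y


def train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: FeatureConfig | None = None,
    n_trees: int = 100,
    max_depth: int | None = None,
    seed: int = 0,
    images_used: tuple = (),
    created: str | None = None,
) -> PixelModel:
    """Fit the per-pixel classifier (random forest by default).

    Deterministic for a fixed seed.  The model records an out-of-bag
    accuracy estimate, the feature configuration, and training metadata.
    Constant (zero-variance) feature matrices are accepted with a warning
    flag in the metadata rather than an error.
    """
    if cfg is None:
        cfg = FeatureConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != 25:
        raise ValidationError(f"feature matrix must be n x 25, got {X.shape}")
    if len(X) != len(y) or len(X) == 0:
        raise ValidationError("feature matrix and labels must be non-empty and aligned")
    present = np.unique(y)
    if len(present) < 2:
        raise ValidationError("need >= 2 classes to train")

    warnings = []
    if np.allclose(X.std(axis=0), 0.0):
        warnings.append("degenerate-features: all feature columns are constant")

    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )
    clf.fit(X, y)
    classes = tuple(CLASS_NAMES[c - 1] for c in clf.classes_)
    metadata = {
        "n_training_pixels": int(len(y)),
        "class_counts": {CLASS_NAMES[c - 1]: int((y == c).sum()) for c in present},
        "oob_accuracy": float(clf.oob_score_),
        "training_accuracy": float(clf.score(X, y)),
        "seed": int(seed),
        "n_trees": int(n_trees),
        "max_depth": max_depth,
        "images_used": list(images_used),
        "created": created,
        "feature_config_hash": config_hash(cfg),
        "warnings": warnings,
    }
    return PixelModel(classifier=clf, feature_config=cfg, classes=classes,
                      metadata=metadata)


def predict(model: PixelModel, img: GrayImage,
            cfg: FeatureConfig | None = None) -> LabelMap:
    """Label every pixel of an image with the trained model.

    If ``cfg`` is given it must match the configuration the model was
    trained with; a mismatch is refused, naming both config hashes.  Ties
    in class probability are broken toward the class listed first in the
    model's class list.
    """
    if cfg is not None and config_hash(cfg) != config_hash(model.feature_config):
        raise ModelConfigMismatch(
            f"feature config {config_hash(cfg)} does not match the model's "
            f"{config_hash(model.feature_config)}"
        )
    stack = compute_feature_stack(img, model.feature_config)
    h, w = stack.geometry
    X = stack.channels.reshape(25, -1).T
    proba = model.classifier.predict_proba(X)
    # stable argmax: first class in the model's class list wins ties
    pred = model.classifier.classes_[np.argmax(proba, axis=1)]
    return LabelMap(labels=pred.reshape(h, w).astype(np.uint8),
                    class_names=CLASS_NAMES)


def measure_ml(model: PixelModel, img: GrayImage, image_id: str = "",
               include_background: bool = False) -> ColonizationMeasure:
    """Predict an image and compute its ml-index.

    The denominator is colonized + non-colonized root tissue; with
    ``include_background`` it extends to the whole frame.
    """
    label_map = predict(model, img)
    colonized = label_map.area("colonized")
    non_col = label_map.area("root_tissue")
    if include_background:
        non_col += label_map.area("background")
    value = ml_index(colonized, non_col)
    flags = [] if colonized + non_col > 0 else ["empty"]
    return ColonizationMeasure(
        image_id=image_id,
        colonized_area=colonized,
        reference_area=colonized + non_col,
        index_value=value,
        method="ml",
        trouvelot_class=trouvelot_class(value),
        flags=tuple(flags),
    )


def save_model(model: PixelModel, path) -> None:
    """Serialize a model (classifier + feature config + metadata) to disk."""
    payload = {
        "version": model.version,
        "classifier": model.classifier,
        "feature_config": model.feature_config.to_dict(),
        "classes": list(model.classes),
        "metadata": model.metadata,
    }
    joblib.dump(payload, Path(path), compress=3)


def load_model(path) -> PixelModel:
    """Load a model saved by :func:`save_model`; checks the version tag."""
    payload = joblib.load(Path(path))
    version = payload.get("version")
    if version != MODEL_VERSION:
        raise ModelVersionError(
            f"unsupported model version {version!r}; expected {MODEL_VERSION!r}"
        )
    return PixelModel(
        classifier=payload["classifier"],
        feature_config=FeatureConfig.from_dict(payload["feature_config"]),
        classes=tuple(payload["classes"]),
        metadata=payload["metadata"],
        version=version,
    )


def export_training_folder(annotations: AnnotationSet, path,
                           cfg: FeatureConfig | None = None) -> None:
    """Write a shareable training folder: images/, labels/, config.yaml.

    Images are stored as grayscale PNGs and label masks as PNGs holding
    the raw class codes 0..3, paired by filename, so another group can
    re-import them and reproduce the training matrix exactly.
    """
    from PIL import Image

    if not annotations.entries:
        raise ValidationError("cannot export an empty annotation set")
    if cfg is None:
        cfg = FeatureConfig()
    path = Path(path)
    (path / "images").mkdir(parents=True, exist_ok=True)
    (path / "labels").mkdir(parents=True, exist_ok=True)
    for i, (img, mask) in enumerate(annotations.entries):
        name = f"train_{i:03d}.png"
        px = np.clip(np.asarray(img.pixels), 0, 255)
        Image.fromarray(np.floor(px + 0.5).astype(np.uint8), mode="L").save(
            path / "images" / name
        )
        Image.fromarray(np.asarray(mask).astype(np.uint8), mode="L").save(
            path / "labels" / name
        )
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump({"features": cfg.to_dict(),
                        "classes": list(CLASS_NAMES)}, fh)


def import_training_folder(path):
    """Re-import a folder written by :func:`export_training_folder`.

    Returns ``(AnnotationSet, FeatureConfig)``.
    """
    from PIL import Image

    path = Path(path)
    with open(path / "config.yaml") as fh:
        doc = yaml.safe_load(fh)
    cfg = FeatureConfig.from_dict(doc["features"])
    entries = []
    for img_path in sorted((path / "images").glob("*.png")):
        with Image.open(img_path) as im:
            img = GrayImage(np.asarray(im.convert("L"), dtype=np.float64))
        with Image.open(path / "labels" / img_path.name) as lm:
            mask = np.asarray(lm)
        entries.append((img, mask))
    if not entries:
        raise ValidationError(f"no training images found under {path}")
    return AnnotationSet(tuple(entries)), cfg
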