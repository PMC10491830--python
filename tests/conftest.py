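"""Shared fixtures.

The ml-index recovery experiment (generate training scenes, build the
feature matrix, fit the forest, predict a held-out gradient) is by far
the most expensive part of the suite, so it is computed once per session
and shared by the classifier tests and the acceptance tests.
"""

from dataclasses import replace

import numpy as np
import pytest

import rootquant as rq
from rootquant.pixel_classifier import AnnotationSet, build_training_set, train
from rootquant.synthetic_roots import SceneParams, generate_scene

#: geometry used for the classifier experiments (kept modest so the whole
#: experiment fits comfortably in a test run)
ML_GEOMETRY = (144, 192)
N_TRAIN_SCENES = 10
N_GRADIENT_SCENES = 12
PER_CLASS_ANNOTATIONS = 800


def annotate_scene(scene, rng, per_class=PER_CLASS_ANNOTATIONS):
    """Ground-truth annotation masks: a random subsample of pixels per class,
    emulating an operator scribbling on fungal structures, clean root
    tissue, and background."""
    col = scene.colonized_mask.pixels.astype(bool)
    root = scene.root_mask.pixels.astype(bool)
    full = np.zeros(scene.root_mask.geometry, np.uint8)
    full[col] = 1
    full[root & ~col] = 2
    full[~root] = 3
    sparse = np.zeros_like(full)
    for code in (1, 2, 3):
        ys, xs = np.nonzero(full == code)
        if len(ys) == 0:
            continue
        k = min(per_class, len(ys))
        idx = rng.choice(len(ys), size=k, replace=False)
        sparse[ys[idx], xs[idx]] = code
    return sparse


def build_experiment(seed: int, n_trees: int = 60):
    """Train a pixel model on ground-truth-annotated sibling scenes and
    predict a 12-scene colonization gradient (true fractions 0-0.6)."""
    rng = np.random.default_rng(seed)
    base = SceneParams(geometry=ML_GEOMETRY, noise_sd=4.0, seed=0)
    train_scenes = [
        generate_scene(replace(base, target_colonization=f, seed=seed * 1000 + i))
        for i, f in enumerate(np.linspace(0.05, 0.5, N_TRAIN_SCENES))
    ]
    entries = tuple(
        (rq.to_grayscale(s.image), annotate_scene(s, rng)) for s in train_scenes
    )
    annotations = AnnotationSet(entries)
    X, y = build_training_set(annotations)
    model = train(X, y, n_trees=n_trees, seed=seed)
    test_scenes = [
        generate_scene(replace(base, target_colonization=f, seed=seed * 1000 + 500 + i))
        for i, f in enumerate(np.linspace(0.0, 0.6, N_GRADIENT_SCENES))
    ]
    from rootquant.pixel_classifier import measure_ml

    measurements = [
        (s.true_fraction, measure_ml(model, rq.to_grayscale(s.image)).index_value)
        for s in test_scenes
    ]
    return {
        "annotations": annotations,
        "X": X,
        "y": y,
        "model": model,
        "train_scenes": train_scenes,
        "test_scenes": test_scenes,
        "measurements": measurements,
    }


@pytest.fixture(scope="session")
def ml_experiment():
    return build_experiment(seed=7)


@pytest.fixture(scope="session")
def noise_free_scene():
    return generate_scene(SceneParams(
        target_colonization=0.30, noise_sd=0.0, illumination_gradient=0.0, seed=3,
    ))
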