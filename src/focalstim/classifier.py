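"""Five-class response-shape labeling: explicit rules and a trained model.

Classes follow the shape vocabulary of calcium activity maps:

====  ==============================  ==================================
label semantics                       rule (ellipse descriptors)
====  ==============================  ==================================
0     no meaningful activity          active pixels below the sparse floor
1     round and small response        ecc < 0.5 and area < 2x electrode
2     elongated and small response    ecc >= 0.5 and area < 2x electrode
3     round and large response        ecc < 0.5 and area >= 2x electrode
4     elongated and large response    ecc >= 0.5 and area >= 2x electrode
====  ==============================  ==================================

The 2x-electrode-area boundary marks overlap with neighboring electrodes at
the array pitch; 0.5 is the midpoint of the eccentricity range.  Equality is
assigned to the elongated/large side.

The trained model classifies downsampled dF/F images directly.  The intended
architecture is a small CNN (three 128-kernel 3x3 conv/ReLU/max-pool blocks
feeding four 128-node dense layers); with no deep-learning backend available
this build trains the dense block as a scikit-learn MLP on the flattened
image, keeping the rest of the protocol (Adam, learning rate 0.001,
cross-entropy, L2 lambda 0.0007, batch 32, 25 epochs, 90-10 train-test then
90-10 train-validation splits).  The acceptance contract — per-class recall
on held-out synthetic images — is unchanged.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from focalstim.imaging import (ActivityMap, DFF_THRESHOLD, ResponseShape,
                               SPARSE_ACTIVITY_FLOOR_PX, compute_activity_map,
                               downsample_map, fit_response_shape)
from focalstim.synthetic import ELECTRODE_AREA_UM2, footprint_axes_px

CLASS_SEMANTICS = {
    0: "no meaningful activity",
    1: "round and small response",
    2: "elongated and small response",
    3: "round and large response",
    4: "elongated and large response",
}
N_CLASSES = 5
ECC_BOUNDARY = 0.5
AREA_BOUNDARY_FACTOR = 2.0


def rule_label(shape: ResponseShape, electrode_area: float = ELECTRODE_AREA_UM2) -> int:
    """Assign the response-shape class from ellipse descriptors.

    Images with fewer active pixels than the sparse floor are class 0
    regardless of their (degenerate) ellipse fit — one or two isolated cells
    are not meaningful spatial activity.
    """
    if shape.n_active_pixels < SPARSE_ACTIVITY_FLOOR_PX:
        return 0
    elongated = shape.eccentricity >= ECC_BOUNDARY
    large = shape.area >= AREA_BOUNDARY_FACTOR * electrode_area
    return 1 + int(elongated) + 2 * int(large)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training protocol for the image classifier.

    The conv fields document the intended convolutional front end; the dense
    block and training protocol are what the MLP realization uses.
    """

    conv_layers: int = 3
    conv_kernels: int = 128
    conv_kernel_size: int = 3
    pool_size: int = 2
    dense_layers: tuple[int, ...] = (128, 128, 128, 128)
    n_classes: int = N_CLASSES
    learning_rate: float = 0.001
    dropout: float = 0.20            # recorded; no dropout in the MLP backend
    l2_lambda: float = 0.0007
    batch_size: int = 32
    epochs: int = 25
    test_fraction: float = 0.10
    val_fraction: float = 0.10       # of the remaining training data
    input_side: int = 64

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


DEFAULT_CNN_CONFIG = CnnConfig()


# ---------------------------------------------------------------------------
# synthetic training corpus

# per-class sampling bands, with a margin away from the decision boundaries
# (ecc 0.5, area 2x electrode): the corpus teaches visually distinguishable
# exemplars of each class, mirroring how borderline images were manually
# relabeled out of ambiguous categories in practice
_CLASS_BANDS = {
    1: {"ecc": (0.05, 0.40), "area": (0.4, 1.7)},
    2: {"ecc": (0.60, 0.92), "area": (0.3, 1.7)},
    3: {"ecc": (0.05, 0.40), "area": (2.4, 3.2)},
    4: {"ecc": (0.60, 0.85), "area": (2.4, 3.2)},
}
_CORPUS_SIDE_PX = 128
_CORPUS_PIXEL_UM = 4.0
_DFF_NOISE = 0.022     # std of dF/F noise after frame averaging


def _render_corpus_map(rng: np.random.Generator, label: int) -> np.ndarray:
    """One noisy dF/F map of the given class at full resolution."""
    side, px = _CORPUS_SIDE_PX, _CORPUS_PIXEL_UM
    dff = _DFF_NOISE * rng.standard_normal((side, side))
    if label == 0:
        return dff
    band = _CLASS_BANDS[label]
    ecc = rng.uniform(*band["ecc"])
    area = rng.uniform(*band["area"]) * ELECTRODE_AREA_UM2
    p, q = footprint_axes_px(area, ecc, px)
    cy = side / 2.0 + rng.normal(0, 2.0)
    cx = side / 2.0 + rng.normal(0, 2.0)
    theta = math.radians(rng.uniform(0, 180))
    yy, xx = np.mgrid[0:side, 0:side]
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    d = np.sqrt((u / p) ** 2 + (v / q) ** 2)
    peak, w = 0.6, 0.05
    d0 = 1.0 + w * math.log(DFF_THRESHOLD / (peak - DFF_THRESHOLD))
    dff += peak / (1.0 + np.exp((d - d0) / w))
    return dff


def build_corpus(n_images: int, seed: int,
                 config: CnnConfig = DEFAULT_CNN_CONFIG) -> tuple[np.ndarray, np.ndarray]:
    """Generate a balanced, rule-labeled synthetic corpus of dF/F images.

    Returns (images, labels): images are (n, side, side) downsampled dF/F
    maps; every label is recomputed with :func:`rule_label` on the rendered
    full-resolution map, so labels are consistent with the printed rules even
    when a footprint clips the field of view.
    """
    rng = np.random.default_rng(seed)
    per_class = n_images // N_CLASSES
    images, labels = [], []
    for label in range(N_CLASSES):
        count = per_class + (1 if label < n_images % N_CLASSES else 0)
        made = 0
        while made < count:
            dff = _render_corpus_map(rng, label)
            mask = dff > DFF_THRESHOLD
            shape = fit_response_shape(ActivityMap(dff=dff, active_mask=mask), _CORPUS_PIXEL_UM)
            got = rule_label(shape)
            if got != label:
                continue        # boundary clip pushed it over; redraw
            images.append(downsample_map(dff, config.input_side))
            labels.append(label)
            made += 1
    order = rng.permutation(len(labels))
    return np.asarray(images)[order], np.asarray(labels)[order]


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentConfig:
    """Which transforms to apply, and to which classes."""

    classes: tuple[int, ...] = (1, 2, 3)
    rotations: tuple[int, ...] = (1, 2, 3)       # multiples of 90 degrees
    flips: tuple[str, ...] = ("lr", "ud")
    n_gaussian: int = 1
    gaussian_sigma: float = 0.03
    n_salt_pepper: int = 1
    salt_pepper_rate: float = 0.01


def augment(images: np.ndarray, labels: np.ndarray,
            config: AugmentConfig = AugmentConfig(),
            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Expand the corpus with orthogonal rotations, flips and noisy copies.

    Only the configured classes are augmented (balancing the rarer shape
    classes); labels are preserved — the shape descriptors behind the rules
    are invariant to orthogonal rotation and flipping.
    """
    rng = np.random.default_rng(seed)
    out_imgs = list(images)
    out_labels = list(labels)
    for img, lab in zip(images, labels):
        if lab not in config.classes:
            continue
        for k in config.rotations:
            out_imgs.append(np.rot90(img, k).copy())
            out_labels.append(lab)
        for fl in config.flips:
            out_imgs.append((np.fliplr(img) if fl == "lr" else np.flipud(img)).copy())
            out_labels.append(lab)
        for _ in range(config.n_gaussian):
            out_imgs.append(img + rng.normal(0, config.gaussian_sigma, img.shape))
            out_labels.append(lab)
        for _ in range(config.n_salt_pepper):
            noisy = img.copy()
            mask = rng.random(img.shape) < config.salt_pepper_rate
            noisy[mask] = rng.choice([0.0, float(img.max()) if img.max() > 0 else 1.0],
                                     size=int(mask.sum()))
            out_imgs.append(noisy)
            out_labels.append(lab)
    return np.asarray(out_imgs), np.asarray(out_labels)


# ---------------------------------------------------------------------------
# model training and inference


@dataclass
class ShapeClassifier:
    """Trained image classifier plus its provenance."""

    model: MLPClassifier
    config: CnnConfig
    confusion: np.ndarray            # rows true, cols predicted, test split
    per_class_recall: np.ndarray
    config_hash: str

    def predict_image(self, image: np.ndarray) -> int:
        img = np.asarray(image, dtype=float)
        if img.shape != (self.config.input_side, self.config.input_side):
            img = downsample_map(img, self.config.input_side)
        return int(self.model.predict(img.reshape(1, -1))[0])


def train_cnn(images: np.ndarray, labels: np.ndarray,
              config: CnnConfig = DEFAULT_CNN_CONFIG, seed: int = 0) -> ShapeClassifier:
    """Train the shape classifier on a labeled image corpus.

    Splits 90-10 into train and test, then 90-10 of the training data into
    train and validation (validation loss is recorded during training for
    monitoring); reports the test-split confusion matrix and per-class
    recall.  Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        if any of the five classes is absent from the corpus.
    """
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist())
    missing = sorted(set(range(config.n_classes)) - present)
    if missing:
        raise ValueError(f"corpus is missing classes {missing}")
    X = np.asarray(images, dtype=float).reshape(len(labels), -1)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, labels, test_size=config.test_fraction, random_state=seed, stratify=labels)
    model = MLPClassifier(
        hidden_layer_sizes=config.dense_layers,
        activation="relu",
        solver="adam",
        alpha=config.l2_lambda,
        batch_size=config.batch_size,
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        shuffle=True,
        random_state=seed,
        early_stopping=True,
        validation_fraction=config.val_fraction,
        n_iter_no_change=config.epochs,      # monitor only; never stop early
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    cm = confusion_matrix(y_te, pred, labels=list(range(config.n_classes)))
    with np.errstate(invalid="ignore"):
        recall = np.diag(cm) / cm.sum(axis=1)
    return ShapeClassifier(model=model, config=config, confusion=cm,
                           per_class_recall=recall, config_hash=config.config_hash())


@dataclass
class ClassifiedResponse:
    label: int                       # model prediction
    rule: int | None = None          # rule label for cross-checking


def classify(image, model: ShapeClassifier,
             pixel_size: float | None = None,
             electrode_area: float = ELECTRODE_AREA_UM2) -> ClassifiedResponse:
    """Classify a dF/F image (or ActivityMap) with the trained model.

    When given an :class:`ActivityMap` and a pixel size, the rule label is
    computed alongside for cross-checking.
    """
    if isinstance(image, ActivityMap):
        rule = None
        if pixel_size is not None:
            rule = rule_label(fit_response_shape(image, pixel_size), electrode_area)
        return ClassifiedResponse(label=model.predict_image(image.dff), rule=rule)
    return ClassifiedResponse(label=model.predict_image(np.asarray(image)))
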