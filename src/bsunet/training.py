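"""Preprocessing, patient-exclusive folds, and the optimization loop.

Training follows the published recipe: Adam at learning rate 1e-3,
pixel-wise binary cross-entropy (the networks emit sigmoid probability
maps), inputs resized to a square matrix and min-max normalized to [0, 1].
Cascade variants train in two stages: the conventional U-net first, then —
with its weights frozen — the second-stage network consuming its
probability maps.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ConfigError, NormalizationError
from .image import ImageSlice
from .phantom import PhantomCohort

__all__ = ["Hyperparams", "FoldSplit", "preprocess", "preprocess_mask",
           "make_folds", "cohort_arrays", "train", "train_cascaded",
           "predict"]


@dataclass(frozen=True)
class Hyperparams:
    """Optimization settings; defaults follow the published recipe."""
    learning_rate: float = 1e-3
    epochs: int = 200
    optimizer: str = "adam"
    batch_size: int = 4
    seed: int = 0
    binarize_threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ConfigError("binarize_threshold must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ConfigError("only the adam optimizer is supported")


def preprocess(image, target_size: int = 256,
               spacing_mm: float | None = None) -> ImageSlice:
    """Bilinear resize to a square matrix and min-max normalize to [0, 1]."""
    arr = image.data if isinstance(image, ImageSlice) else np.asarray(image, np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ConfigError("expected a nonempty 2-D image")
    if arr.shape != (target_size, target_size):
        scale = arr.shape[0] / target_size
        arr = resize(arr, (target_size, target_size), order=1,
                     preserve_range=True, anti_aliasing=scale > 1)
    else:
        scale = 1.0
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise NormalizationError("constant image cannot be min-max normalized")
    arr = (arr - lo) / (hi - lo)
    if spacing_mm is None:
        spacing_mm = (image.spacing_mm if isinstance(image, ImageSlice) else 1.5) * scale
    return ImageSlice(arr.astype(np.float32), spacing_mm)


def preprocess_mask(mask, target_size: int = 256) -> np.ndarray:
    """Nearest-neighbour resize and re-binarization at 0.5."""
    arr = np.asarray(mask, np.float64)
    if arr.shape != (target_size, target_size):
        arr = resize(arr, (target_size, target_size), order=0,
                     preserve_range=True, anti_aliasing=False)
    return (arr > 0.5).astype(np.uint8)


@dataclass
class FoldSplit:
    """Patient-exclusive k-fold assignment with per-fold case lists."""
    k: int
    assignments: dict                       # patient_id -> fold index
    folds: list = field(default_factory=list)  # [(train_case_ids, test_case_ids)]

    def fold_cases(self, i: int):
        return self.folds[i]


def make_folds(cohort: PhantomCohort, k: int, seed: int) -> FoldSplit:
    """Shuffle patients and partition them into k folds, balancing per-fold
    image counts as evenly as possible.  All slices of a patient land in the
    same fold."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    if len(cohort.patients) < k:
        raise ConfigError("need at least k patients for k folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort.patients))
    patients = [cohort.patients[i] for i in order]
    # largest-first greedy balancing on slice counts (stable w.r.t. shuffle)
    patients.sort(key=lambda p: -p.n_slices)
    loads = [0] * k
    assignments = {}
    for p in patients:
        f = int(np.argmin(loads))
        assignments[p.patient_id] = f
        loads[f] += p.n_slices
    case_fold = {}
    for pid, cid, _img, _mask in cohort.cases():
        case_fold[cid] = assignments[pid]
    folds = []
    for f in range(k):
        test = [c for c, ff in case_fold.items() if ff == f]
        train_ = [c for c, ff in case_fold.items() if ff != f]
        folds.append((train_, test))
    return FoldSplit(k=k, assignments=assignments, folds=folds)


def cohort_arrays(cohort: PhantomCohort, case_ids=None):
    """Stack cohort cases into (X, y, case_ids) arrays of shape (n, H, W)."""
    sel = None if case_ids is None else set(case_ids)
    X, y, ids = [], [], []
    for _pid, cid, img, mask in cohort.cases():
        if sel is None or cid in sel:
            X.append(img.data)
            y.append(mask)
            ids.append(cid)
    return np.stack(X), np.stack(y).astype(np.uint8), ids


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator interface

def train(config, X, y, hp: Hyperparams):
    """Train a non-cascade network described by ``config`` and return the
    fitted estimator."""
    from .estimators import DiscSegmenter
    est = DiscSegmenter(variant=config.variant,
                        image_size=config.input_shape.width,
                        width_multiplier=config.width_multiplier,
                        learning_rate=hp.learning_rate, epochs=hp.epochs,
                        batch_size=hp.batch_size,
                        binarize_threshold=hp.binarize_threshold,
                        random_state=hp.seed)
    return est.fit(X, y)


def train_cascaded(config, X, y, hp: Hyperparams, stage1=None,
                   front_end: bool = False):
    """Two-stage cascade training; ``stage1`` may supply an already trained
    conventional U-net (it stays frozen)."""
    from .estimators import DiscSegmenter
    est = DiscSegmenter(variant=config.variant,
                        image_size=config.input_shape.width,
                        width_multiplier=config.width_multiplier,
                        learning_rate=hp.learning_rate, epochs=hp.epochs,
                        batch_size=hp.batch_size,
                        binarize_threshold=hp.binarize_threshold,
                        front_end_guidance=front_end,
                        random_state=hp.seed)
    return est.fit(X, y, stage1=stage1)


def predict(model, X, threshold: float | None = None) -> np.ndarray:
    """Binary masks from a fitted estimator (threshold defaults to the
    estimator's)."""
    proba = model.predict_proba(X)
    thr = model.binarize_threshold if threshold is None else threshold
    return (proba > thr).astype(np.uint8)
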