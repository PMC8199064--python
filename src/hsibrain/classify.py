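"""The three supervised pixel classifiers: linear SVM, random forest, 3D-CNN.

SVM and RF classify a pixel from its normalized 25-band spectrum; the CNN
classifies it from the 9x9x25 patch centered on it (mirror padding at
image borders so no labeled pixel is dropped).  ``train`` dispatches on a
:class:`ModelSpec`; ``predict_image`` produces a full classification map.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .classes import CLASS_IDS
from .cnn import CNN3DClassifier
from .labeling import GroundTruthMap
from .preprocess import STAGE_NORMALIZED, HyperCube

ALGORITHMS = ("svm-linear", "rf", "cnn3d")

DEFAULT_HYPERPARAMETERS = {
    "svm-linear": {"C": 1.0},
    "rf": {"n_estimators": 100},
    "cnn3d": {
        "filters": (128, 256),
        "kernel": (3, 3, 5),
        "pool": 2,
        "fc": (256, 128),
        "dropout": (0.3, 0.5),
        "patch_size": 9,
        "batch_size": 1024,
        "n_passes": 2,
        "lr": 5e-5,
        "weight_decay": 0.01,
    },
}


@dataclass
class ModelSpec:
    """Algorithm choice plus its complete hyperparameter record and seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    @property
    def needs_patches(self) -> bool:
        return self.algorithm == "cnn3d"

    @property
    def patch_size(self) -> int:
        return self.hyperparameters.get("patch_size", 9)

    def with_seed(self, seed: int) -> "ModelSpec":
        return ModelSpec(self.algorithm, dict(self.hyperparameters), seed)


@dataclass
class LabeledDataset:
    """Features (spectra or patches), labels in 1-5, and per-sample provenance.

    Provenance rows are ``(image_id, r, c)``; duplicates are rejected so
    fold-isolation checks can rely on sample identity.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # (N, 3) int: image id, row, col

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.provenance = np.asarray(self.provenance, dtype=np.int64)
        if self.X.shape[0] == 0:
            raise ValueError("dataset must be nonempty")
        if not (self.X.shape[0] == self.y.shape[0] == self.provenance.shape[0]):
            raise ValueError("features, labels and provenance lengths differ")
        if not np.isin(self.y, CLASS_IDS).all():
            raise ValueError("labels must lie in 1..5")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        uniq = np.unique(self.provenance, axis=0)
        if uniq.shape[0] != self.provenance.shape[0]:
            raise ValueError("duplicate (image, r, c) provenance entries")

    def __len__(self) -> int:
        return int(self.y.shape[0])

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.provenance[idx])

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.y).tobytes())
        h.update(np.ascontiguousarray(self.provenance).tobytes())
        h.update(str(self.X.shape).encode())
        return h.hexdigest()[:16]

    @staticmethod
    def concat(parts: list["LabeledDataset"]) -> "LabeledDataset":
        return LabeledDataset(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.provenance for p in parts]),
        )


@dataclass
class TrainedModel:
    """A fitted classifier plus its training provenance."""

    spec: ModelSpec
    estimator: object
    fingerprint: str
    context: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=np.int64)


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def mirror_pad(data: np.ndarray, margin: int) -> np.ndarray:
    """Mirror-reflect spatial padding (border pixel not repeated)."""
    return np.pad(data, ((margin, margin), (margin, margin), (0, 0)),
                  mode="reflect")


def extract_patches(
    cube: HyperCube,
    gt: GroundTruthMap,
    size: int = 9,
    image_id: int = 0,
    pixels: Optional[np.ndarray] = None,
) -> LabeledDataset:
    """One size x size x bands patch per labeled pixel, center-labeled.

    Patches overlap; borders are handled by mirror padding of (size-1)/2
    pixels.  ``pixels`` optionally restricts extraction to given (r, c)
    rows (used for subsampling).
    """
    if size % 2 == 0:
        raise ValueError("patch size must be odd")
    if cube.stage != STAGE_NORMALIZED:
        raise ValueError("patch extraction expects a normalized cube")
    if gt.labels.shape != cube.spatial_shape:
        raise ValueError("ground-truth shape does not match cube")
    if pixels is None:
        rr, cc = np.nonzero(gt.labels)
    else:
        rr, cc = np.asarray(pixels)[:, 0], np.asarray(pixels)[:, 1]
    if rr.size == 0:
        raise ValueError("no labeled pixels to extract")
    m = (size - 1) // 2
    padded = mirror_pad(cube.data, m)
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (size, size), axis=(0, 1))          # (R, C, bands, size, size)
    patches = windows[rr, cc].transpose(0, 2, 3, 1)  # (N, size, size, bands)
    labels = gt.labels[rr, cc]
    prov = np.stack([np.full(rr.size, image_id), rr, cc], axis=1)
    return LabeledDataset(np.ascontiguousarray(patches, dtype=np.float32),
                          labels, prov)


def spectra_dataset(cube: HyperCube, gt: GroundTruthMap,
                    image_id: int = 0,
                    pixels: Optional[np.ndarray] = None) -> LabeledDataset:
    """Per-pixel spectra dataset (SVM/RF features)."""
    if cube.stage != STAGE_NORMALIZED:
        raise ValueError("expects a normalized cube")
    if pixels is None:
        rr, cc = np.nonzero(gt.labels)
    else:
        rr, cc = np.asarray(pixels)[:, 0], np.asarray(pixels)[:, 1]
    if rr.size == 0:
        raise ValueError("no labeled pixels")
    prov = np.stack([np.full(rr.size, image_id), rr, cc], axis=1)
    return LabeledDataset(cube.data[rr, cc].astype(np.float64),
                          gt.labels[rr, cc], prov)


def build_dataset(cube: HyperCube, gt: GroundTruthMap, spec: ModelSpec,
                  image_id: int = 0,
                  pixels: Optional[np.ndarray] = None) -> LabeledDataset:
    """Features appropriate to the algorithm: patches for cnn3d, else spectra."""
    if spec.needs_patches:
        return extract_patches(cube, gt, spec.patch_size, image_id, pixels)
    return spectra_dataset(cube, gt, image_id, pixels)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

def _make_estimator(spec: ModelSpec):
    hp = spec.hyperparameters
    if spec.algorithm == "svm-linear":
        return SVC(kernel="linear", C=hp["C"], random_state=spec.seed)
    if spec.algorithm == "rf":
        return RandomForestClassifier(n_estimators=hp["n_estimators"],
                                      random_state=spec.seed, n_jobs=1)
    return CNN3DClassifier(
        filters=tuple(hp["filters"]), kernel=tuple(hp["kernel"]),
        pool=hp["pool"], fc=tuple(hp["fc"]), dropout=tuple(hp["dropout"]),
        lr=hp["lr"], weight_decay=hp["weight_decay"],
        batch_size=hp["batch_size"], n_passes=hp["n_passes"], seed=spec.seed,
    )


def train(spec: ModelSpec, data: LabeledDataset, **context) -> TrainedModel:
    """Fit the classifier named by ``spec`` on ``data``.

    Deterministic given (spec.seed, data order).  Single-class data is
    rejected: there is nothing to discriminate.
    """
    if len(np.unique(data.y)) < 2:
        raise ValueError("cannot train on single-class data")
    if spec.needs_patches and data.X.ndim != 4:
        raise ValueError("cnn3d requires patch features (N, ph, pw, bands)")
    if not spec.needs_patches and data.X.ndim != 2:
        raise ValueError(f"{spec.algorithm} requires spectral features (N, bands)")
    est = _make_estimator(spec)
    est.fit(data.X, data.y)
    return TrainedModel(spec=spec, estimator=est,
                        fingerprint=data.fingerprint(), context=dict(context))


@dataclass
class ClassificationMap:
    """Per-pixel predicted labels (1-5) covering every cube pixel."""

    labels: np.ndarray
    model_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2:
            raise ValueError("classification map must be 2D")
        if not np.isin(self.labels, CLASS_IDS).all():
            raise ValueError("classification map labels must lie in 1..5")


def predict_image(model: TrainedModel, cube: HyperCube,
                  row_chunk: int = 16) -> ClassificationMap:
    """Classify every pixel of a normalized cube.

    CNN patches are built with the same mirror-padding rule as training;
    the image is processed in row chunks to bound memory.
    """
    if cube.stage != STAGE_NORMALIZED:
        raise ValueError("prediction expects a normalized cube")
    rows, cols = cube.spatial_shape
    if model.spec.needs_patches:
        size = model.spec.patch_size
        m = (size - 1) // 2
        padded = mirror_pad(cube.data, m)
        windows = np.lib.stride_tricks.sliding_window_view(
            padded, (size, size), axis=(0, 1))
        out = np.empty((rows, cols), dtype=np.int64)
        for r0 in range(0, rows, row_chunk):
            chunk = windows[r0:r0 + row_chunk].reshape(-1, cube.data.shape[2],
                                                       size, size)
            patches = np.ascontiguousarray(chunk.transpose(0, 2, 3, 1),
                                           dtype=np.float32)
            pred = model.predict(patches)
            out[r0:r0 + row_chunk] = pred.reshape(-1, cols)
        labels = out
    else:
        labels = model.predict(cube.data.reshape(-1, cube.data.shape[2]))
        labels = labels.reshape(rows, cols)
    return ClassificationMap(labels, model_fingerprint=model.fingerprint)
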