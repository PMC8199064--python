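"""Spectral-angle-mapper (SAM) labeling: building ground-truth maps.

Ground truth for this pipeline is produced interactively: an annotator picks
a seed pixel of known tissue type and a tolerance angle; every pixel of the
normalized cube whose spectral angle to the seed spectrum falls within the
tolerance receives the class label.  This module reproduces that tool's
semantics (global thresholding, later actions overwrite earlier labels, a
replayable provenance log) without the GUI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .classes import CLASS_IDS, CLASS_NAMES, UNLABELED
from .preprocess import STAGE_NORMALIZED, HyperCube

VALID_LABELS = (UNLABELED,) + CLASS_IDS

#: overwrite policies for repeated labeling actions
OVERWRITE = "overwrite"      # later actions overwrite earlier labels
KEEP_FIRST = "keep-first"    # earlier labels are frozen


@dataclass
class GroundTruthMap:
    """Per-pixel labels (0 unlabeled, 1-5 tissue classes) plus provenance.

    Provenance records every labeling action as
    ``(seed_pixel, class_id, threshold, policy)`` so a map can be replayed
    bit-for-bit from the same cube.
    """

    labels: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label grid must be 2D")
        if not np.isin(self.labels, VALID_LABELS).all():
            raise ValueError(f"labels must be in {VALID_LABELS}")
        self.labels = self.labels.astype(np.int8)

    @classmethod
    def empty(cls, rows: int, cols: int) -> "GroundTruthMap":
        return cls(np.zeros((rows, cols), dtype=np.int8))


def sam(x: np.ndarray, ref: np.ndarray) -> float:
    """Spectral angle between two spectra, in radians in [0, pi].

    ``arccos(<x, ref> / (|x| |ref|))`` with the cosine clamped into [-1, 1]
    before arccos; invariant to positive rescaling of either argument.
    """
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    nx = np.linalg.norm(x)
    nr = np.linalg.norm(ref)
    if nx == 0.0 or nr == 0.0:
        raise ValueError("SAM is undefined for a zero spectrum")
    c = np.clip(float(x @ ref) / (nx * nr), -1.0, 1.0)
    return float(np.arccos(c))


def sam_image(cube: HyperCube, ref: np.ndarray) -> np.ndarray:
    """Spectral angle of every cube pixel to a reference spectrum.

    Zero-spectrum pixels get angle pi (maximally dissimilar) so they are
    never swept up by a finite threshold.
    """
    ref = np.asarray(ref, dtype=np.float64)
    nr = np.linalg.norm(ref)
    if nr == 0.0:
        raise ValueError("SAM is undefined for a zero reference")
    norms = np.linalg.norm(cube.data, axis=2)
    dots = cube.data @ ref
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = dots / (norms * nr)
    cosine = np.where(norms == 0.0, -1.0, np.clip(cosine, -1.0, 1.0))
    return np.arccos(cosine)


def label_by_threshold(
    cube: HyperCube,
    seed_pixel: tuple[int, int],
    class_id: int,
    threshold: float,
    gt: GroundTruthMap,
    policy: str = OVERWRITE,
) -> GroundTruthMap:
    """Label every pixel within ``threshold`` radians of the seed spectrum.

    The reference spectrum is the single seed pixel's spectrum.  All image
    pixels are compared (no connectivity constraint).  Returns a new map;
    the action is appended to its provenance.
    """
    if cube.stage != STAGE_NORMALIZED:
        raise ValueError(f"labeling expects a normalized cube, got stage "
                         f"'{cube.stage}'")
    if class_id not in CLASS_IDS:
        raise ValueError(f"class_id must be one of {CLASS_IDS}")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    r, c = seed_pixel
    rows, cols = cube.spatial_shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"seed pixel {seed_pixel} out of bounds for "
                         f"{rows}x{cols} cube")
    if gt.labels.shape != (rows, cols):
        raise ValueError("ground-truth map shape does not match cube")

    angles = sam_image(cube, cube.data[r, c])
    hit = angles <= threshold
    labels = gt.labels.copy()
    if policy == OVERWRITE:
        labels[hit] = class_id
    elif policy == KEEP_FIRST:
        labels[hit & (labels == UNLABELED)] = class_id
    else:
        raise ValueError(f"unknown overwrite policy '{policy}'")
    prov = list(gt.provenance) + [
        {"seed_pixel": (int(r), int(c)), "class_id": int(class_id),
         "threshold": float(threshold), "policy": policy}
    ]
    return GroundTruthMap(labels, prov)


def replay_provenance(cube: HyperCube, provenance: list) -> GroundTruthMap:
    """Re-run a provenance log on a cube, reproducing the map exactly."""
    gt = GroundTruthMap.empty(*cube.spatial_shape)
    for action in provenance:
        gt = label_by_threshold(cube, tuple(action["seed_pixel"]),
                                action["class_id"], action["threshold"], gt,
                                policy=action.get("policy", OVERWRITE))
    return gt


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13 at 2 decimals)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def gt_class_counts(gt) -> dict:
    """Labeled-pixel census of a ground-truth map (or a counts mapping).

    Returns ``{"counts": {class: n}, "total": n, "percent": {class: pct}}``
    with percentages of the labeled total, round-half-up to 2 decimals.
    With no labeled pixels the percentages are undefined and reported as
    ``None``.  Accepts either a :class:`GroundTruthMap` or a ready-made
    ``{class_id: count}`` mapping (e.g. a published census row).
    """
    if isinstance(gt, GroundTruthMap):
        counts = {cid: int(np.count_nonzero(gt.labels == cid))
                  for cid in CLASS_IDS}
    else:
        counts = {cid: int(gt.get(cid, 0)) for cid in CLASS_IDS}
    total = sum(counts.values())
    if total == 0:
        percent = {cid: None for cid in CLASS_IDS}
    else:
        percent = {cid: round_half_up(100.0 * counts[cid] / total)
                   for cid in CLASS_IDS}
    return {"counts": counts, "total": total, "percent": percent,
            "names": {cid: CLASS_NAMES[cid] for cid in CLASS_IDS}}
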