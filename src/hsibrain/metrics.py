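"""Confusion-matrix construction and the evaluation metric suite.

All metrics derive from a 5x5 confusion matrix (rows = true class, columns
= predicted class) by one-vs-rest decomposition:

* OACC  = trace / total                      (overall accuracy)
* ACC_k = (TP + TN) / total                  (per-class accuracy)
* SEN_k = TP / (TP + FN)                     (sensitivity / recall)
* SPE_k = TN / (TN + FP)                     (specificity)
* Err_k = (FP + FN) / total  (= 1 - ACC_k)

Two study-specific metrics are included: the merged-blood sensitivity
(vein/artery distinction is clinically secondary, so cross-predictions
between the two blood classes count as merged-class hits by default) and
the band-efficiency ratio OACC/bands used to compare cameras with very
different spectral resolution.

Metrics that are undefined for a given matrix (e.g. sensitivity of an
absent class) are reported as ``None``, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classes import ARTERIAL, CLASS_IDS, CLASS_NAMES, VENOUS
from .labeling import round_half_up

N = len(CLASS_IDS)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> np.ndarray:
    """5x5 confusion matrix; ``cm[i, j]`` counts true class i+1 predicted j+1."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1D and of equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 1 or y.max() > N):
            raise ValueError(f"{name} labels must lie in 1..{N}")
    cm = np.zeros((N, N), dtype=np.int64)
    np.add.at(cm, (y_true - 1, y_pred - 1), 1)
    return cm


def oacc(cm: np.ndarray) -> float:
    """Overall accuracy: correct predictions over all predictions made."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def one_vs_rest(cm: np.ndarray, class_id: int) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) for one class against all others."""
    if class_id not in CLASS_IDS:
        raise ValueError(f"class_id must be in {CLASS_IDS}")
    k = class_id - 1
    cm = np.asarray(cm)
    tp = int(cm[k, k])
    fn = int(cm[k].sum() - tp)
    fp = int(cm[:, k].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return tp, tn, fp, fn


def class_metrics(cm: np.ndarray, class_id: int) -> dict:
    """ACC, SEN, SPE and Error for one class (one-vs-rest).

    SEN is ``None`` when the class has no true samples; SPE is ``None``
    when it has no negatives.  ACC + Error = 1 identically.
    """
    tp, tn, fp, fn = one_vs_rest(cm, class_id)
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "ACC": (tp + tn) / total,
        "SEN": tp / (tp + fn) if (tp + fn) else None,
        "SPE": tn / (tn + fp) if (tn + fp) else None,
        "Error": (fp + fn) / total,
    }


def blood_sen(cm: np.ndarray, strict: bool = False) -> Optional[float]:
    """Sensitivity of the merged venous+arterial blood class.

    ``(TP_art + TP_ven) / ((TP_art + FN_art) + (TP_ven + FN_ven))``.  By
    default cross-predictions between the two blood classes count as
    merged-class true positives (telling vein from artery is not clinically
    crucial); ``strict=True`` keeps them as errors.  ``None`` when there are
    no blood samples.
    """
    cm = np.asarray(cm)
    v, a = VENOUS - 1, ARTERIAL - 1
    denom = int(cm[v].sum() + cm[a].sum())
    if denom == 0:
        return None
    if strict:
        tp = int(cm[v, v] + cm[a, a])
    else:
        tp = int(cm[v, v] + cm[v, a] + cm[a, v] + cm[a, a])
    return tp / denom


def oacc_per_band(oacc_percent: float, n_bands: int) -> float:
    """Band-efficiency metric: mean OACC (%) per spectral band.

    Normalizing overall accuracy by the camera's band count lets systems
    with very different spectral resolution be compared on contributed
    accuracy per band.  Reported to 2 decimals, round-half-up.
    """
    if n_bands <= 0:
        raise ValueError("n_bands must be positive")
    return round_half_up(oacc_percent / n_bands, 2)


@dataclass
class MetricReport:
    """Full metric suite for one evaluated prediction set."""

    cm: np.ndarray
    oacc: float
    per_class: dict[int, dict]
    blood_sen: Optional[float]
    n: int
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "MetricReport":
        cm = confusion(y_true, y_pred)
        return cls(
            cm=cm,
            oacc=oacc(cm),
            per_class={cid: class_metrics(cm, cid) for cid in CLASS_IDS},
            blood_sen=blood_sen(cm),
            n=int(cm.sum()),
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "oacc": self.oacc,
            "blood_sen": self.blood_sen,
            "per_class": {CLASS_NAMES[cid]: m
                          for cid, m in self.per_class.items()},
            "confusion": self.cm.tolist(),
            **self.extra,
        }


def aggregate(values: Sequence[Optional[float]], population_sd: bool = True) -> dict:
    """Mean +/- SD across images, skipping undefined entries.

    Population SD (ddof=0) by default, matching the summary-row convention
    of the per-patient result tables; switchable to sample SD.
    """
    vals = np.array([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        return {"mean": None, "sd": None, "n": 0}
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=0 if population_sd else 1)) if vals.size > 1
        else 0.0,
        "n": int(vals.size),
    }
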