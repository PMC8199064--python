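"""Four-step pre-processing chain for snapshot-mosaic hyperspectral captures.

A 5x5 snapshot-mosaic sensor interleaves 25 spectral bands on a single 2D
frame.  Processing runs raw frame -> hypercube -> calibrated reflectance ->
crosstalk-corrected -> RMS-normalized:

1. ``demosaic``       - rearrange mosaic blocks into an (R, C, 25) cube.
2. ``calibrate``      - flat-field against white/dark reference cubes,
                        ``Ic = (I - D) / (W - D)`` per band.
3. ``spectral_correct`` - right-multiply each pixel spectrum by the 25x25
                        spectral correction matrix that un-mixes sensor
                        crosstalk.
4. ``rms_normalize``  - divide each pixel spectrum by its root-mean-square
                        over bands, removing brightness variation caused by
                        the curved tissue surface while preserving spectral
                        shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

log = logging.getLogger(__name__)

#: number of spectral bands of the snapshot sensor
N_BANDS = 25
#: mosaic period (bands are laid out in 5x5 repeating blocks)
MOSAIC_PERIOD = 5

#: processing stage tags, in pipeline order
STAGE_RAW = "raw-cube"
STAGE_CALIBRATED = "calibrated"
STAGE_CORRECTED = "corrected"
STAGE_NORMALIZED = "normalized"

#: default clamp for near-zero calibration denominators
DEFAULT_EPS = 1e-6


@dataclass
class RawMosaicFrame:
    """A 2D sensor frame carrying 25 bands in repeating 5x5 mosaic blocks.

    Band layout convention (config-overridable, row-major within the block):
    band ``b`` lives at sensor position ``(5*r + b // 5, 5*c + b % 5)`` for
    cube pixel ``(r, c)``.
    """

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("raw mosaic frame must be 2D")
        h, w = self.pixels.shape
        if h % MOSAIC_PERIOD or w % MOSAIC_PERIOD:
            raise ValueError(
                f"raw frame dims {h}x{w} must be divisible by {MOSAIC_PERIOD}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class HyperCube:
    """rows x cols x 25 array plus a stage tag tracking the pipeline position."""

    data: np.ndarray
    stage: str = STAGE_RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != N_BANDS:
            raise ValueError(
                f"hypercube must be rows x cols x {N_BANDS}, got {self.data.shape}"
            )

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class SpectralCorrectionMatrix:
    """25x25 matrix; each row holds one virtual band's correction coefficients.

    Pixel spectra are treated as row vectors and right-multiplied by it.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (N_BANDS, N_BANDS):
            raise ValueError(f"SCM must be {N_BANDS}x{N_BANDS}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("SCM entries must be finite")


@dataclass
class NormalizationCoefficients:
    """Per-pixel RMS normalizing coefficients; zero-spectrum pixels are flagged."""

    coef: np.ndarray
    degenerate: np.ndarray  # boolean mask of all-zero pixels


def demosaic(raw: RawMosaicFrame) -> HyperCube:
    """Rearrange a mosaic frame into a hypercube without interpolation.

    ``cube[r, c, b] = raw[5*r + b // 5, 5*c + b % 5]``.
    """
    p = MOSAIC_PERIOD
    h, w = raw.shape
    rows, cols = h // p, w // p
    # (rows, p, cols, p) -> (rows, cols, p, p) -> flatten the block row-major
    cube = (
        raw.pixels.reshape(rows, p, cols, p)
        .transpose(0, 2, 1, 3)
        .reshape(rows, cols, p * p)
    )
    return HyperCube(cube.copy(), stage=STAGE_RAW,
                     meta={**raw.meta, "band_layout": "row-major-5x5"})


def remosaic(cube: HyperCube) -> RawMosaicFrame:
    """Inverse of :func:`demosaic` (demosaicking is a bijection)."""
    p = MOSAIC_PERIOD
    rows, cols = cube.spatial_shape
    raw = (
        cube.data.reshape(rows, cols, p, p)
        .transpose(0, 2, 1, 3)
        .reshape(rows * p, cols * p)
    )
    return RawMosaicFrame(raw.copy(), meta=dict(cube.meta))


def calibrate(
    I: HyperCube,
    W: HyperCube,
    D: HyperCube,
    eps: float = DEFAULT_EPS,
) -> HyperCube:
    """Flat-field calibration ``Ic = (I - D) / (W - D)`` per band.

    Near-zero denominators (white ~ dark) are clamped at ``eps``; the number
    of clamped entries is logged as a warning because those pixels carry no
    usable signal.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if I.data.shape != W.data.shape or I.data.shape != D.data.shape:
        raise ValueError(
            f"cube shapes differ: I {I.data.shape}, W {W.data.shape}, D {D.data.shape}"
        )
    den = W.data - D.data
    n_clamped = int(np.count_nonzero(den < eps))
    if n_clamped:
        log.warning("calibrate: clamped %d denominator entries below eps=%g",
                    n_clamped, eps)
    den = np.maximum(den, eps)
    ic = (I.data - D.data) / den
    meta = {**I.meta, "eps": eps, "n_clamped": n_clamped}
    return HyperCube(ic, stage=STAGE_CALIBRATED, meta=meta)


def spectral_correct(Ic: HyperCube, scm: SpectralCorrectionMatrix) -> HyperCube:
    """Un-mix sensor crosstalk: each pixel row-vector is multiplied by the SCM."""
    isc = Ic.data @ scm.matrix
    return HyperCube(isc, stage=STAGE_CORRECTED, meta=dict(Ic.meta))


def rms_normalize(Isc: HyperCube) -> tuple[HyperCube, NormalizationCoefficients]:
    """Divide each pixel spectrum by its RMS over bands.

    ``coef[r, c] = sqrt(sum_b Isc[r, c, b]^2 / B)``.  All-zero pixels have no
    direction; they propagate as zeros and are flagged degenerate rather than
    producing NaN.
    """
    if not np.all(np.isfinite(Isc.data)):
        raise ValueError("cube contains non-finite values")
    coef = np.sqrt(np.mean(np.square(Isc.data), axis=2))
    degenerate = coef == 0.0
    safe = np.where(degenerate, 1.0, coef)
    norm = Isc.data / safe[:, :, None]
    meta = {**Isc.meta, "n_degenerate": int(np.count_nonzero(degenerate))}
    return (
        HyperCube(norm, stage=STAGE_NORMALIZED, meta=meta),
        NormalizationCoefficients(coef=coef, degenerate=degenerate),
    )


def preprocess_capture(
    raw: RawMosaicFrame,
    white: RawMosaicFrame,
    dark: RawMosaicFrame,
    scm: SpectralCorrectionMatrix,
    eps: float = DEFAULT_EPS,
) -> tuple[HyperCube, NormalizationCoefficients]:
    """Run the full chain: demosaic -> calibrate -> correct -> normalize.

    White and dark references are demosaicked with the same band layout.
    Returns the normalized cube and its normalizing coefficients.
    """
    cube = demosaic(raw)
    w = demosaic(white)
    d = demosaic(dark)
    ic = calibrate(cube, w, d, eps=eps)
    isc = spectral_correct(ic, scm)
    return rms_normalize(isc)


def corrected_reflectance(
    raw: RawMosaicFrame,
    white: RawMosaicFrame,
    dark: RawMosaicFrame,
    scm: SpectralCorrectionMatrix,
    eps: float = DEFAULT_EPS,
) -> HyperCube:
    """Chain up to the corrected (pre-normalization) reflectance cube."""
    ic = calibrate(demosaic(raw), demosaic(white), demosaic(dark), eps=eps)
    return spectral_correct(ic, scm)
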