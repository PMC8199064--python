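"""File formats and rendering: ENVI cubes, paletted PNG maps, CSV, JSON.

Cubes travel as ENVI (text header + flat binary, BSQ interleave, float32)
with a JSON sidecar recording the processing stage, band layout and any
calibration metadata.  Label maps travel as paletted PNG (lossless label
round trip) plus CSV ``(r, c, label)``.  The ENVI reader/writer here is a
minimal self-contained implementation of the header-plus-raster layout.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from PIL import Image

from .classes import CLASS_COLORS, CLASS_IDS, UNLABELED
from .labeling import GroundTruthMap
from .preprocess import HyperCube, RawMosaicFrame, SpectralCorrectionMatrix

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 1: np.uint8}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5,
               np.dtype(np.uint16): 12, np.dtype(np.uint8): 1}


# ---------------------------------------------------------------------------
# ENVI
# ---------------------------------------------------------------------------

def _write_envi_raster(base: Path, data: np.ndarray) -> None:
    """data: (bands, lines, samples) float32, BSQ order."""
    bands, lines, samples = data.shape
    hdr = "\n".join([
        "ENVI",
        "description = {hsibrain export}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[data.dtype]}",
        "interleave = bsq",
        "byte order = 0",
        "",
    ])
    base.with_suffix(".hdr").write_text(hdr)
    data.tofile(base.with_suffix(".img"))


def _read_envi_header(path: Path) -> dict:
    text = path.read_text()
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip().lower()] = v.strip().strip("{}").strip()
    return fields


def _read_envi_raster(base: Path) -> np.ndarray:
    hdr = _read_envi_header(base.with_suffix(".hdr"))
    if hdr.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    dtype = _ENVI_DTYPES[int(hdr["data type"])]
    shape = (int(hdr["bands"]), int(hdr["lines"]), int(hdr["samples"]))
    data = np.fromfile(base.with_suffix(".img"), dtype=dtype)
    return data.reshape(shape)


def write_cube(path: Union[str, Path], cube: HyperCube) -> None:
    """Write a cube as ENVI BSQ float32 with a JSON sidecar."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    _write_envi_raster(base, cube.data.transpose(2, 0, 1).astype(np.float32))
    sidecar = {"stage": cube.stage, "meta": _jsonable(cube.meta)}
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_cube(path: Union[str, Path]) -> HyperCube:
    base = Path(path)
    data = _read_envi_raster(base).transpose(1, 2, 0).astype(np.float64)
    stage, meta = "raw-cube", {}
    sidecar = base.with_suffix(".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        stage = info.get("stage", stage)
        meta = info.get("meta", {})
    return HyperCube(data, stage=stage, meta=meta)


def write_frame(path: Union[str, Path], frame: RawMosaicFrame) -> None:
    """Write a raw mosaic frame as a single-band ENVI raster."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    _write_envi_raster(base, frame.pixels[None].astype(np.float32))


def read_frame(path: Union[str, Path]) -> RawMosaicFrame:
    data = _read_envi_raster(Path(path))
    if data.shape[0] != 1:
        raise ValueError("raw mosaic frame must be single-band")
    return RawMosaicFrame(data[0].astype(np.float64))


def write_scm(path: Union[str, Path], scm: SpectralCorrectionMatrix) -> None:
    np.savetxt(path, scm.matrix, delimiter=",")


def read_scm(path: Union[str, Path]) -> SpectralCorrectionMatrix:
    return SpectralCorrectionMatrix(np.loadtxt(path, delimiter=","))


# ---------------------------------------------------------------------------
# label maps
# ---------------------------------------------------------------------------

@dataclass
class RenderPalette:
    """Class id -> RGB color; five distinct classes plus black background."""

    colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(CLASS_COLORS))

    def __post_init__(self) -> None:
        vals = [self.colors[c] for c in CLASS_IDS]
        if len(set(vals)) != len(CLASS_IDS):
            raise ValueError("palette colors must be distinct")

    def flat(self) -> list[int]:
        table = []
        for i in range(256):
            table.extend(self.colors.get(i, (0, 0, 0)))
        return table


def render_map(labels, path: Optional[Union[str, Path]] = None,
               palette: Optional[RenderPalette] = None) -> Image.Image:
    """Render a label grid as a paletted PNG (deterministic bytes).

    Accepts a GroundTruthMap, a ClassificationMap or a bare integer array.
    Unknown labels are rejected.
    """
    palette = palette or RenderPalette()
    grid = np.asarray(getattr(labels, "labels", labels))
    known = set(palette.colors) | {UNLABELED}
    present = set(np.unique(grid).tolist())
    if not present <= known:
        raise ValueError(f"labels {sorted(present - known)} not in palette")
    img = Image.fromarray(grid.astype(np.uint8), mode="P")
    img.putpalette(palette.flat())
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        img.save(Path(path), format="PNG")
    return img


def read_map(path: Union[str, Path]) -> np.ndarray:
    """Read a paletted label PNG back to the integer label grid."""
    img = Image.open(Path(path))
    if img.mode != "P":
        raise ValueError("expected a paletted PNG label map")
    return np.asarray(img, dtype=np.int8)


def write_gt_csv(path: Union[str, Path], gt: GroundTruthMap) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["r", "c", "label"])
        for r, c in zip(*np.nonzero(gt.labels)):
            w.writerow([int(r), int(c), int(gt.labels[r, c])])


def read_gt_csv(path: Union[str, Path], rows: int, cols: int) -> GroundTruthMap:
    gt = GroundTruthMap.empty(rows, cols)
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            gt.labels[int(rec["r"]), int(rec["c"])] = int(rec["label"])
    return gt


# ---------------------------------------------------------------------------
# configs / reports
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One experiment run: image paths, algorithm, experiment id, seed."""

    images: list            # list of {"cube": path, "gt": path}
    algorithm: str
    experiment: str         # "A" or "B"
    seed: int
    out_dir: Path

    def __post_init__(self) -> None:
        if self.experiment not in ("A", "B"):
            raise ValueError("experiment must be 'A' or 'B'")
        self.out_dir = Path(self.out_dir)
        for entry in self.images:
            for key in ("cube", "gt"):
                p = Path(entry[key])
                probe = p if p.suffix else p.with_suffix(".hdr")
                if not probe.exists():
                    raise FileNotFoundError(f"missing input path: {p}")


def load_config(path: Union[str, Path]) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig(images=raw["images"], algorithm=raw["algorithm"],
                     experiment=str(raw["experiment"]).upper(),
                     seed=int(raw.get("seed", 0)),
                     out_dir=raw.get("out_dir", "."))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(path: Union[str, Path], payload: dict) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))
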