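"""Calibrated likelihood-map containers and their on-disk PNG16+JSON format.

Slide-level analysis never touches pixels of the original whole-slide image:
every stage consumes patch-level class likelihoods on a regular grid with a
physical calibration (microns per pixel, ``mpp``).  Two grid resolutions occur
in practice: a coarse per-patch grid (one cell per 1024-px patch) for the
invasive-carcinoma and NP/TF softmax maps, and a fine grid for the mitosis
likelihood heatmap.

On disk a C-class map is stored as C 16-bit grayscale PNGs (likelihood scaled
to 0..65535) plus a single JSON sidecar holding class names and calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LikelihoodMap",
    "MitosisHeatmap",
    "TumorMask",
    "INVASIVE_CLASSES",
    "SCORE_CLASSES",
]

#: canonical class orders
INVASIVE_CLASSES = ("non_tumor", "cis", "invasive")
SCORE_CLASSES = ("score1", "score2", "score3")

_PNG16_MAX = 65535


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class LikelihoodMap:
    """Per-patch class probabilities on a regular grid.

    Parameters
    ----------
    grid
        ``(H, W, C)`` float array of class probabilities; each cell sums to 1.
    class_names
        Ordered class labels, e.g. ``("non_tumor", "cis", "invasive")``.
    patch_size_px
        Side of the square patch each cell summarises, in full-resolution
        pixels.
    mpp
        Microns per full-resolution pixel; one cell covers
        ``patch_size_px * mpp`` microns. Origin (0, 0) is the slide top-left.
    """

    grid: np.ndarray
    class_names: tuple[str, ...]
    patch_size_px: int
    mpp: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.class_names = tuple(self.class_names)
        _require(self.grid.ndim == 3, "grid must be H x W x C")
        _require(self.grid.shape[2] == len(self.class_names),
                 "class_names length must match grid channels")
        _require(self.patch_size_px > 0, "patch_size_px must be positive")
        _require(self.mpp > 0, "mpp must be positive")
        _require(bool(np.all((self.grid >= 0) & (self.grid <= 1))),
                 "likelihoods must lie in [0, 1]")
        sums = self.grid.sum(axis=2)
        _require(bool(np.all(np.abs(sums - 1.0) <= 1e-6)),
                 "per-cell probabilities must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]

    @property
    def patch_um(self) -> float:
        """Physical side of one grid cell in microns."""
        return self.patch_size_px * self.mpp

    # ---- IO ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the map as ``<path>_c<k>.png`` 16-bit PNGs + ``<path>.json``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        for k in range(self.grid.shape[2]):
            _write_png16(self.grid[:, :, k], path.with_name(path.name + f"_c{k}.png"))
        sidecar = {
            "kind": "likelihood_map",
            "class_names": list(self.class_names),
            "patch_size_px": int(self.patch_size_px),
            "mpp": float(self.mpp),
            "shape": [int(s) for s in self.grid.shape],
        }
        path.with_name(path.name + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LikelihoodMap":
        path = Path(path)
        meta = json.loads(path.with_name(path.name + ".json").read_text())
        h, w, c = meta["shape"]
        grid = np.stack(
            [_read_png16(path.with_name(path.name + f"_c{k}.png")) for k in range(c)],
            axis=2,
        )
        # renormalise away 16-bit quantisation so invariants hold exactly
        grid /= grid.sum(axis=2, keepdims=True)
        return cls(grid, tuple(meta["class_names"]), meta["patch_size_px"], meta["mpp"])


@dataclass
class MitosisHeatmap:
    """Fine-grid mitotic-figure likelihood surface.

    ``grid[r, c]`` is the likelihood (0-1) that the cell centred at
    ``((c + 0.5) * mpp, (r + 0.5) * mpp)`` microns contains a mitotic figure.
    """

    grid: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        _require(self.grid.ndim == 2, "heatmap grid must be 2-D")
        _require(self.mpp > 0, "mpp must be positive")
        _require(bool(np.all((self.grid >= 0) & (self.grid <= 1))),
                 "likelihoods must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_png16(self.grid, path.with_name(path.name + ".png"))
        sidecar = {"kind": "mitosis_heatmap", "mpp": float(self.mpp),
                   "shape": [int(s) for s in self.grid.shape]}
        path.with_name(path.name + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MitosisHeatmap":
        path = Path(path)
        meta = json.loads(path.with_name(path.name + ".json").read_text())
        return cls(_read_png16(path.with_name(path.name + ".png")), meta["mpp"])


@dataclass
class TumorMask:
    """Binary invasive-carcinoma mask on the same grid as its source map."""

    grid: np.ndarray
    patch_size_px: int
    mpp: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        _require(self.grid.ndim == 2, "mask grid must be 2-D")
        _require(self.patch_size_px > 0, "patch_size_px must be positive")
        _require(self.mpp > 0, "mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def patch_um(self) -> float:
        return self.patch_size_px * self.mpp

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_png16(self.grid.astype(float), path.with_name(path.name + ".png"))
        sidecar = {"kind": "tumor_mask", "patch_size_px": int(self.patch_size_px),
                   "mpp": float(self.mpp), "shape": [int(s) for s in self.grid.shape]}
        path.with_name(path.name + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TumorMask":
        path = Path(path)
        meta = json.loads(path.with_name(path.name + ".json").read_text())
        grid = _read_png16(path.with_name(path.name + ".png")) > 0.5
        return cls(grid, meta["patch_size_px"], meta["mpp"])

    def to_interval_table(self, slide_id: str):
        """Mask as a BED-like table of patch pixel intervals (half-open)."""
        import pandas as pd

        rows, cols = np.nonzero(self.grid)
        p = self.patch_size_px
        return pd.DataFrame(
            {
                "slide_id": slide_id,
                "x_px_start": cols * p,
                "x_px_end": (cols + 1) * p,
                "y_px_start": rows * p,
                "y_px_end": (rows + 1) * p,
            }
        )


def _write_png16(arr: np.ndarray, path: Path) -> None:
    scaled = np.round(np.clip(arr, 0.0, 1.0) * _PNG16_MAX).astype(np.uint16)
    Image.fromarray(scaled).save(path)


def _read_png16(path: Path) -> np.ndarray:
    img = np.asarray(Image.open(path), dtype=np.float64)
    return img / _PNG16_MAX
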