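"""Voxel-grid containers shared across the reconstruction and morphometry stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: class codes used throughout the package
CLASS_NON_MINERALIZED = 0
CLASS_BONE = 1
CLASS_GRAFT = 2
CLASS_MISSING = 255

CLASS_NAMES = {0: "non-mineralized", 1: "bone", 2: "graft", 255: "missing"}


@dataclass
class LabeledVolume:
    """3D grid of tissue classes with (possibly anisotropic) voxel spacing.

    ``voxels`` is indexed ``(z, y, x)``; ``spacing_um`` is ``(z, y, x)`` in
    micrometres.  ``frame`` tags the coordinate frame the volume lives in
    (e.g. ``"ct"`` after cross-modal registration); ``missing_planes`` lists
    z-indices with no corresponding histology slide.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    frame: str = "native"
    missing_planes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("LabeledVolume requires a 3D voxel grid")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def class_fraction(self, classes=(CLASS_BONE, CLASS_GRAFT)) -> float:
        """Fraction of (non-missing) voxels belonging to ``classes``."""
        valid = self.voxels != CLASS_MISSING
        fg = np.isin(self.voxels, classes) & valid
        return float(fg.sum()) / float(valid.sum())

    def save(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.voxels.astype(np.uint8))
        meta = {
            "spacing_um": list(self.spacing_um),
            "frame": self.frame,
            "missing_planes": [int(z) for z in self.missing_planes],
            "classes": {str(k): v for k, v in CLASS_NAMES.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "LabeledVolume":
        path = Path(path)
        voxels = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            voxels=voxels,
            spacing_um=tuple(meta["spacing_um"]),
            frame=meta.get("frame", "native"),
            missing_planes=list(meta.get("missing_planes", [])),
        )


@dataclass
class BinaryVolume:
    """Boolean voxel grid (True = mineralized) with spacing in micrometres."""

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("BinaryVolume requires a 3D grid")
        if self.voxels.size == 0:
            raise ValueError("BinaryVolume must be nonempty")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_isotropic(self) -> bool:
        z, y, x = self.spacing_um
        return abs(z - y) < 1e-9 and abs(y - x) < 1e-9

    def resampled_isotropic(self) -> "BinaryVolume":
        """Nearest-neighbour resample to isotropic voxels at the coarsest spacing."""
        if self.is_isotropic:
            return self
        from scipy import ndimage

        target = max(self.spacing_um)
        zoom = [s / target for s in self.spacing_um]
        vox = ndimage.zoom(self.voxels.astype(np.uint8), zoom, order=0) > 0
        return BinaryVolume(vox, (target, target, target))


def save_grayscale_volume(path, volume: np.ndarray, spacing_um) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32))
    path.with_suffix(".json").write_text(json.dumps({"spacing_um": list(spacing_um)}))


def load_grayscale_volume(path):
    path = Path(path)
    vol = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return vol, tuple(meta["spacing_um"])
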