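"""Voxel grid containers shared across the pipeline.

Conventions: arrays are indexed ``(z, y, x)``; ``spacing`` and ``origin`` are
``(z, y, x)`` in millimetres; the world coordinate of a voxel center is
``origin + (index + 0.5) * spacing``.  Axial slices lie in the x-y plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Volume:
    """A scalar voxel grid with spacing/origin metadata.

    ``kind`` tags the physical quantity ("HU", "Gy", "density", "label").
    """

    values: np.ndarray
    spacing: tuple[float, float, float]  # mm, (z, y, x)
    origin: tuple[float, float, float]   # mm, (z, y, x)
    kind: str = "HU"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume expects a 3-D (z, y, x) array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other: "Volume") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def require_same_grid(self, other: "Volume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch between {what}: {self.shape}/{self.spacing} vs "
                f"{other.shape}/{other.spacing}")

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "Volume":
        return replace(self, values=np.asarray(values),
                       kind=self.kind if kind is None else kind,
                       meta=dict(self.meta))

    def voxel_centers_xy(self):
        """World (x, y) coordinates of in-plane voxel centers, in mm."""
        nz, ny, nx = self.shape
        x = self.origin[2] + (np.arange(nx) + 0.5) * self.spacing[2]
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing[1]
        return np.meshgrid(x, y)


@dataclass
class LabeledVolume:
    """Material-index grid: 0 = surrounding air, then one index per region."""

    labels: np.ndarray  # integer material index per voxel
    material_names: list[str]  # index-aligned; repeats allowed
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    slot_labels: dict[str, int] = field(default_factory=dict)  # slot name -> label

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.max(initial=0) >= len(self.material_names):
            raise ValueError("label indexes undefined material")

    @property
    def shape(self):
        return self.labels.shape

    def as_volume(self) -> Volume:
        return Volume(self.labels, self.spacing, self.origin, kind="label")

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class StructureMask:
    """Named boolean mask on the grid of a reference volume."""

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> "StructureMask":
        if not self.mask.any():
            raise ValueError(f"structure {self.name!r} is empty")
        return self
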