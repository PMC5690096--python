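"""Shared image container and coordinate conventions.

All modules use one physical frame: coordinates in millimetres, origin at
the magnet isocenter, voxel-center convention with 0-based indices, axes
(x = right-left, y = anterior-posterior, z = foot-head).  The physical
position of voxel ``(i, j, k)`` is ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

AXES = ("x", "y", "z")

TWO_PI = 2.0 * np.pi


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase into the repo-wide interval [-pi, pi)."""
    return (np.asarray(phi) + np.pi) % TWO_PI - np.pi


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid in the isocenter frame.

    Parameters
    ----------
    data
        3D array indexed ``[ix, iy, iz]``; intensities in arbitrary units.
    spacing
        Per-axis voxel size in mm, all positive.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    meta
        Free-form tags (modality, echo time in ms, masks, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- construction -----------------------------------------------------
    @classmethod
    def centered(cls, shape: Sequence[int], spacing: Sequence[float],
                 dtype=np.float32, meta: dict | None = None) -> "ImageVolume":
        """Zero-filled volume whose grid is centered on the isocenter."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls(np.zeros(shape, dtype=dtype), spacing, origin, meta or {})

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse physical meshgrid (mm) broadcastable to ``data``."""
        return np.meshgrid(*(self.coords(a) for a in range(3)),
                           indexing="ij", sparse=True)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for physical points (mm)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    # -- I/O ---------------------------------------------------------------
    def to_nifti(self, path) -> None:
        """Write as NIfTI-1 with an affine built from spacing/origin."""
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32),
                                 affine), str(path))

    @classmethod
    def from_nifti(cls, path, meta: dict | None = None) -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, origin,
                   meta or {})


def require_same_grid(a: ImageVolume, b: ImageVolume, what: str = "volumes") -> None:
    if not a.same_grid(b):
        raise ValueError(f"{what} are on different grids: "
                         f"{a.shape}/{a.spacing} vs {b.shape}/{b.spacing}")
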