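"""B0 field-homogeneity analysis via dual-echo phase difference.

The phase accrued between two gradient-echo acquisitions at TE1 < TE2 is
proportional to the local field offset: unwrapping the wrapped TE2-TE1
phase difference and dividing by 2 pi f0 dTE gives the field deviation,
expressed in ppm relative to the masked mean (homogeneity is conventionally
a deviation, not an absolute frequency).  The volume RMS over a centered
sphere (the DSV) is the reported homogeneity figure, compared against the
ACR <2 ppm recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap

from .core import ImageVolume, require_same_grid, wrap_phase

ACR_HOMOGENEITY_LIMIT_PPM = 2.0


@dataclass
class FieldMap:
    """Per-voxel field deviation in ppm with a validity mask."""

    ppm: ImageVolume
    mask: np.ndarray
    f0_hz: float
    delta_te_ms: float
    dsv_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if self.delta_te_ms <= 0:
            raise ValueError("dTE must be positive")
        if not np.all(np.isfinite(self.ppm.data[self.mask])):
            raise ValueError("field map has non-finite values on the mask")


def _mask_of(p: ImageVolume) -> np.ndarray:
    return p.meta.get("mask", np.ones(p.shape, dtype=bool))


def phase_difference_map(p1: ImageVolume, p2: ImageVolume) -> ImageVolume:
    """Wrapped phase difference wrap(p2 - p1); carries dTE = TE2 - TE1."""
    require_same_grid(p1, p2, "phase images")
    te1, te2 = p1.meta.get("TE_ms"), p2.meta.get("TE_ms")
    if te1 is None or te2 is None or te2 <= te1:
        raise ValueError("phase images must carry TE_ms with TE2 > TE1")
    mask = _mask_of(p1) & _mask_of(p2)
    dphi = wrap_phase(np.asarray(p2.data, float) - np.asarray(p1.data, float))
    return ImageVolume(dphi, p1.spacing, p1.origin,
                       meta={"dTE_ms": te2 - te1, "mask": mask,
                             "f0_hz": p1.meta.get("f0_hz")})


def unwrap_phase_map(wrapped: ImageVolume) -> ImageVolume:
    """Spatially unwrap a wrapped phase image on its validity mask.

    Uses reliability-sorted (quality-guided) unwrapping; the result is the
    true phase up to one global 2 pi k offset per connected mask component.
    Disconnected components are unwrapped independently and the ambiguity is
    flagged in ``meta['disconnected_components']``.
    """
    mask = _mask_of(wrapped)
    if not mask.any():
        raise ValueError("empty mask: nothing to unwrap")
    data = np.asarray(wrapped.data, dtype=np.float64)
    # drop singleton axes for the unwrapper (2D slices stored as 3D)
    ma = np.ma.array(data.squeeze(), mask=~mask.squeeze())
    res = _unwrap(ma)
    out = np.where(mask, np.ma.filled(res, 0.0).reshape(data.shape), 0.0)
    _, ncomp = ndimage.label(mask)
    meta = dict(wrapped.meta)
    meta["mask"] = mask
    meta["disconnected_components"] = int(ncomp)
    return ImageVolume(out, wrapped.spacing, wrapped.origin, meta=meta)


def phase_to_ppm(unwrapped_delta: ImageVolume, f0_hz: float) -> FieldMap:
    """Convert an unwrapped dual-echo phase difference to a ppm field map.

    ppm = (dphi - mean(dphi over mask)) / (2 pi f0 dTE) * 1e6, i.e. the
    deviation of the field relative to the masked mean.
    """
    dte = unwrapped_delta.meta.get("dTE_ms")
    if not dte:
        raise ValueError("input must carry dTE_ms > 0")
    if f0_hz <= 0:
        raise ValueError("f0 must be positive")
    mask = _mask_of(unwrapped_delta)
    dphi = np.asarray(unwrapped_delta.data, float)
    dev = dphi - dphi[mask].mean()
    ppm = np.where(mask, dev / (2 * np.pi * f0_hz * dte * 1e-3) * 1e6, 0.0)
    img = ImageVolume(ppm, unwrapped_delta.spacing, unwrapped_delta.origin,
                      meta={"units": "ppm", "mask": mask})
    return FieldMap(ppm=img, mask=mask, f0_hz=f0_hz, delta_te_ms=float(dte))


def dsv_rms(fmap: FieldMap, diameter_mm: float) -> float:
    """RMS of the ppm deviation over a centered sphere of the given diameter."""
    X, Y, Z = fmap.ppm.grid()
    sphere = (X ** 2 + Y ** 2 + Z ** 2) <= (diameter_mm / 2.0) ** 2
    sel = sphere & fmap.mask
    if not sel.any():
        raise ValueError(f"no masked voxels inside a {diameter_mm} mm sphere")
    vals = fmap.ppm.data[sel]
    return float(np.sqrt(np.mean(vals ** 2)))


def b0_pipeline(p1: ImageVolume, p2: ImageVolume, f0_hz: float,
                dsv_diameter_mm: float = 310.0) -> tuple[FieldMap, float]:
    """Full chain: difference, unwrap, ppm conversion, DSV volume RMS."""
    dphi = phase_difference_map(p1, p2)
    unwrapped = unwrap_phase_map(dphi)
    fmap = phase_to_ppm(unwrapped, f0_hz)
    fmap.dsv_diameter_mm = dsv_diameter_mm
    return fmap, dsv_rms(fmap, dsv_diameter_mm)
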