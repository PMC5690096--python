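"""Geometric-distortion quantification from grid-phantom image pairs.

Markers are detected by center-of-mass analysis of thresholded connected
components, matched one-to-one to the reference lattice, and the resulting
displacement vector field is summarized by radial shells about the
isocenter (the convention on scanners: a 5 cm radius sphere and 5 cm thick
annuli out to 20 cm).  A 2D analysis interpolates the in-plane distortion
magnitude, extracts 2-6 mm isocontours and grows the daily-QA "compliant
rectangle" in which >=75% of control points distort by less than 2 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import griddata
from scipy.spatial import cKDTree
from skimage import measure

from .core import ImageVolume

DEFAULT_SHELL_EDGES = (0.0, 50.0, 100.0, 150.0, 200.0)


@dataclass
class ControlPointSet:
    """Detected marker centroids in the physical (isocenter) frame."""

    centroids: np.ndarray          # (N, 3) mm
    lattice_index: np.ndarray      # (N, 3) int
    mass: np.ndarray               # summed intensity per marker
    voxel_count: np.ndarray
    collisions: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class DisplacementField:
    """Matched reference->measured marker pairs and their vectors (mm)."""

    reference: np.ndarray          # (M, 3) mm
    measured: np.ndarray           # (M, 3) mm
    lattice_index: np.ndarray      # (M, 3)
    unmatched_reference: np.ndarray  # (U, 3) mm

    @property
    def vectors(self) -> np.ndarray:
        return self.measured - self.reference

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def to_csv(self, path) -> None:
        v = self.vectors
        pd.DataFrame({
            "x_ref": self.reference[:, 0], "y_ref": self.reference[:, 1],
            "z_ref": self.reference[:, 2],
            "dx": v[:, 0], "dy": v[:, 1], "dz": v[:, 2],
            "magnitude": self.magnitudes,
        }).to_csv(path, index=False)


def detect_markers(volume: ImageVolume, intensity_threshold: float = 0.5,
                   min_voxels: int = 4,
                   lattice_spacing: tuple[float, float, float] = (25.0, 25.0, 27.0),
                   lattice_origin: np.ndarray | None = None,
                   ) -> ControlPointSet:
    """Find grid markers by thresholded connected-component center of mass.

    ``intensity_threshold`` is a fraction of the volume's intensity range
    above background.  Centroids are intensity-weighted centers of mass in
    physical mm; lattice indices follow from rounding
    ``(centroid - lattice_origin) / lattice_spacing``.  When two components
    round to the same lattice index the larger mass wins and the collision
    is reported.
    """
    data = np.asarray(volume.data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return ControlPointSet(np.empty((0, 3)), np.empty((0, 3), int),
                               np.empty(0), np.empty(0, int))
    thr = lo + intensity_threshold * (hi - lo)
    fg = data > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return ControlPointSet(np.empty((0, 3)), np.empty((0, 3), int),
                               np.empty(0), np.empty(0, int))
    ids = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(data), labels, ids)
    keep = counts >= min_voxels
    ids, counts = ids[keep], counts[keep]
    # grow each component by one voxel so the anti-aliased marker skirt
    # (partial-volume edge voxels below threshold) contributes to the
    # center of mass; otherwise the threshold cut biases sub-voxel centroids
    grown = ndimage.grey_dilation(labels, size=3)
    grown = np.where(labels > 0, labels, grown)
    weight = np.clip(data - lo, 0.0, None)
    com = np.array(ndimage.center_of_mass(weight, grown, ids))  # index coords
    centroids = volume.index_to_physical(com)
    mass = ndimage.sum_labels(weight, grown, ids)

    sp = np.asarray(lattice_spacing, dtype=float)
    if lattice_origin is None:
        # infer the lattice phase from the centroids themselves: circular
        # mean of the per-axis residues, robust at the wrap point
        ang = (centroids % sp) / sp * 2 * np.pi
        offset = (np.arctan2(np.mean(np.sin(ang), axis=0),
                             np.mean(np.cos(ang), axis=0))
                  / (2 * np.pi)) % 1.0 * sp
        lattice_origin = offset
    lat_idx = np.round((centroids - np.asarray(lattice_origin)) / sp).astype(int)

    # resolve lattice-index collisions: keep the larger mass
    order = np.argsort(-mass)
    seen: dict[tuple, int] = {}
    keep_rows, collisions = [], []
    for row in order:
        key = tuple(lat_idx[row])
        if key in seen:
            collisions.append((key, int(row)))
        else:
            seen[key] = row
            keep_rows.append(row)
    keep_rows = np.sort(np.array(keep_rows, dtype=int))
    return ControlPointSet(centroids[keep_rows], lat_idx[keep_rows],
                           mass[keep_rows], counts[keep_rows].astype(int),
                           collisions=collisions)


def rigid_prealign(reference: ControlPointSet, measured: ControlPointSet,
                   central_radius: float = 50.0) -> np.ndarray:
    """Rigidly align measured centroids to the reference (Kabsch fit).

    The fit uses only markers within ``central_radius`` of the isocenter so
    that the system distortion (which grows radially) is not absorbed into
    the rigid transform.  Returns the transformed measured centroids.
    """
    ref_c = reference.centroids
    mea_c = measured.centroids
    tree = cKDTree(mea_c)
    central = np.linalg.norm(ref_c, axis=1) <= central_radius
    if central.sum() < 3:
        return mea_c
    d, j = tree.query(ref_c[central])
    A = mea_c[j]          # measured, paired by nearest neighbour
    B = ref_c[central]    # reference
    ca, cb = A.mean(0), B.mean(0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    return (R @ mea_c.T).T + t


def match_control_points(reference: ControlPointSet, measured: ControlPointSet,
                         max_radius: float = 12.0) -> DisplacementField:
    """Greedy one-to-one nearest matching of reference to measured markers.

    Candidate pairs within ``max_radius`` are assigned in ascending order of
    distance (ties broken by lattice-index lexicographic order); leftover
    reference points are reported unmatched.
    """
    ref_c, mea_c = reference.centroids, measured.centroids
    if len(mea_c) == 0 or len(ref_c) == 0:
        return DisplacementField(np.empty((0, 3)), np.empty((0, 3)),
                                 np.empty((0, 3), int), ref_c.copy())
    tree = cKDTree(mea_c)
    pairs = []  # (distance, lattice_key, ref_row, mea_row)
    for i, p in enumerate(ref_c):
        for j in tree.query_ball_point(p, max_radius):
            pairs.append((float(np.linalg.norm(mea_c[j] - p)),
                          tuple(reference.lattice_index[i]), i, j))
    pairs.sort(key=lambda x: (x[0], x[1]))
    used_ref: set[int] = set()
    used_mea: set[int] = set()
    assigned: list[tuple[int, int]] = []
    for _, _, i, j in pairs:
        if i in used_ref or j in used_mea:
            continue
        used_ref.add(i)
        used_mea.add(j)
        assigned.append((i, j))
    assigned.sort(key=lambda ij: tuple(reference.lattice_index[ij[0]]))
    ri = np.array([i for i, _ in assigned], int)
    mi = np.array([j for _, j in assigned], int)
    unmatched = np.array([p for i, p in enumerate(ref_c) if i not in used_ref])
    if unmatched.size == 0:
        unmatched = np.empty((0, 3))
    return DisplacementField(ref_c[ri], mea_c[mi],
                             reference.lattice_index[ri], unmatched)


@dataclass
class DistortionSummary:
    """Radial-shell statistics of the displacement magnitude."""

    table: pd.DataFrame  # one row per shell
    sd_convention: str = "population"

    def to_json_dict(self) -> dict:
        return {"sd_convention": self.sd_convention,
                "shells": self.table.to_dict(orient="records")}


def radial_distortion_summary(dfield: DisplacementField,
                              shell_edges=DEFAULT_SHELL_EDGES,
                              ) -> DistortionSummary:
    """Mean / population SD / max |d| and 2-3 mm / >=3 mm fractions per shell.

    Points are binned by the radius of their *reference* position.  Empty
    shells are reported as NaN (not zero).
    """
    if len(dfield.reference) == 0:
        raise ValueError("displacement field is empty")
    r = np.linalg.norm(dfield.reference, axis=1)
    mags = dfield.magnitudes
    rows = []
    edges = list(shell_edges)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (r >= lo) & (r < hi)
        m = mags[sel]
        if m.size == 0:
            rows.append({"r_min_mm": lo, "r_max_mm": hi, "n": 0,
                         "mean_mm": np.nan, "sd_mm": np.nan, "max_mm": np.nan,
                         "frac_2_3mm": np.nan, "frac_ge_3mm": np.nan})
        else:
            rows.append({"r_min_mm": lo, "r_max_mm": hi, "n": int(m.size),
                         "mean_mm": float(m.mean()),
                         "sd_mm": float(m.std(ddof=0)),
                         "max_mm": float(m.max()),
                         "frac_2_3mm": float(np.mean((m >= 2.0) & (m < 3.0))),
                         "frac_ge_3mm": float(np.mean(m >= 3.0))})
    return DistortionSummary(pd.DataFrame(rows))


@dataclass
class PlanarDistortionResult:
    """In-plane distortion map, isocontours, and the compliant rectangle."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    magnitude_map: np.ndarray          # mm, NaN outside the marker hull
    isocontours: dict[float, list]     # level mm -> list of (K, 2) polylines
    rect_center: tuple[float, float]
    rect_width: float                  # mm, first in-plane axis
    rect_height: float                 # mm, second in-plane axis
    compliant_fraction: float

    def to_json_dict(self) -> dict:
        return {"rect_center_mm": list(self.rect_center),
                "rect_width_mm": self.rect_width,
                "rect_height_mm": self.rect_height,
                "compliant_fraction": self.compliant_fraction,
                "isocontour_levels_mm": sorted(self.isocontours)}


def planar_distortion_analysis(dfield: DisplacementField, plane_axis: int = 2,
                               grid_step: float = 2.0,
                               lattice_step: float = 25.0,
                               compliance_mm: float = 2.0,
                               compliance_fraction: float = 0.75,
                               levels=(2.0, 3.0, 4.0, 5.0, 6.0),
                               ) -> PlanarDistortionResult:
    """2D distortion analysis of the control points in one plane.

    The in-plane |d| is linearly interpolated onto a dense grid inside the
    marker convex hull, isocontours are extracted at 2-6 mm, and an
    axis-aligned rectangle centered on the isocenter is grown alternately
    one lattice step per axis while at least ``compliance_fraction`` of the
    enclosed control points distort by less than ``compliance_mm``.
    """
    axes = [a for a in range(3) if a != plane_axis]
    pts = dfield.reference[:, axes]
    if len(pts) < 4:
        raise ValueError("need at least 4 in-plane control points")
    mags = dfield.magnitudes

    gx = np.arange(pts[:, 0].min(), pts[:, 0].max() + grid_step / 2, grid_step)
    gy = np.arange(pts[:, 1].min(), pts[:, 1].max() + grid_step / 2, grid_step)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    dense = griddata(pts, mags, (GX, GY), method="linear")

    contours: dict[float, list] = {}
    filled = np.where(np.isnan(dense), -1.0, dense)
    for lev in levels:
        polys = measure.find_contours(filled, lev)
        out = []
        for poly in polys:
            xy = np.column_stack([np.interp(poly[:, 0], np.arange(len(gx)), gx),
                                  np.interp(poly[:, 1], np.arange(len(gy)), gy)])
            out.append(xy)
        contours[lev] = out

    # compliant rectangle: symmetric expansion from the isocenter
    def compliant(hw: float, hh: float) -> tuple[bool, float]:
        sel = (np.abs(pts[:, 0]) <= hw + 1e-9) & (np.abs(pts[:, 1]) <= hh + 1e-9)
        if not np.any(sel):
            return True, 1.0
        frac = float(np.mean(mags[sel] < compliance_mm))
        return frac >= compliance_fraction, frac

    max_hw = float(np.max(np.abs(pts[:, 0])))
    max_hh = float(np.max(np.abs(pts[:, 1])))
    hw = hh = lattice_step / 2.0
    while True:
        grew = False
        cand_w = min(hw + lattice_step, max_hw)
        if cand_w > hw + 1e-9 and compliant(cand_w, hh)[0]:
            hw = cand_w
            grew = True
        cand_h = min(hh + lattice_step, max_hh)
        if cand_h > hh + 1e-9 and compliant(hw, cand_h)[0]:
            hh = cand_h
            grew = True
        if not grew:
            break
    _, frac = compliant(hw, hh)
    return PlanarDistortionResult(gx, gy, dense, contours, (0.0, 0.0),
                                  2 * hw, 2 * hh, frac)


def analyze_pair(reference: ImageVolume, measured: ImageVolume,
                 intensity_threshold: float = 0.5, min_voxels: int = 4,
                 max_radius: float = 12.0, prealign: bool = True,
                 ) -> tuple[DisplacementField, DistortionSummary]:
    """Full 3D chain: detect markers in both volumes, match, summarize."""
    ref_pts = detect_markers(reference, intensity_threshold, min_voxels)
    mea_pts = detect_markers(measured, intensity_threshold, min_voxels)
    if prealign:
        aligned = rigid_prealign(ref_pts, mea_pts)
        mea_pts = ControlPointSet(aligned, mea_pts.lattice_index,
                                  mea_pts.mass, mea_pts.voxel_count)
    dfield = match_control_points(ref_pts, mea_pts, max_radius=max_radius)
    return dfield, radial_distortion_summary(dfield)
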