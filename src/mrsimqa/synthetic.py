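"""Synthetic phantoms and waveforms with known ground truth.

Every input the analysis modules consume can be generated here, emulating
the physical QA objects used on the scanner: a capsule-grid distortion
phantom, a uniform sphere with a programmed ppm inhomogeneity imaged at two
echo times, a crossed-ramp slice-thickness insert, a multi-compartment
(water/fat/bone/air) object sampled at several echo times, marker cylinders
for spatial fidelity, and a sinusoidally translating object driven by a
respiratory waveform.

All generators are deterministic given their parameters and a seed, and
each returns the ground truth alongside the rendered images so the analysis
chain can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import ImageVolume, wrap_phase

GAMMA_BAR_1T_HZ = 42_587_276.0  # proton resonance frequency of the 1.0 T system, Hz
FAT_WATER_PPM = 3.4             # chemical-shift separation, ppm


# ---------------------------------------------------------------------------
# distortion model + capsule grid phantom
# ---------------------------------------------------------------------------

@dataclass
class DistortionModel:
    """Smooth geometric-distortion field about the isocenter.

    ``radial_cubic`` is the coefficient a of a pure radial term
    d(r) = a r^3 directed outward (mm displacement at radius r mm);
    ``poly`` optionally adds per-output-axis polynomial terms up to total
    degree 5 as ``{axis: {(i, j, k): coef}}`` over isocenter-centered mm
    coordinates.  Displacement at the isocenter is exactly zero.
    """

    radial_cubic: float = 0.0
    poly: dict[int, dict[tuple[int, int, int], float]] = field(default_factory=dict)

    @classmethod
    def cubic(cls, magnitude_mm: float, at_radius_mm: float) -> "DistortionModel":
        """Radial cubic model with |d| = magnitude_mm at the given radius."""
        return cls(radial_cubic=magnitude_mm / at_radius_mm ** 3)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Displacement vectors (mm) at physical points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        disp = np.zeros_like(pts)
        if self.radial_cubic != 0.0:
            r2 = np.sum(pts ** 2, axis=1, keepdims=True)
            disp += self.radial_cubic * r2 * pts  # a r^3 * (p / r) = a r^2 p
        for axis, terms in self.poly.items():
            for (i, j, k), c in terms.items():
                if i + j + k > 5:
                    raise ValueError("polynomial terms limited to total degree 5")
                if i == j == k == 0:
                    raise ValueError("constant term would displace the isocenter")
                disp[:, axis] += c * pts[:, 0] ** i * pts[:, 1] ** j * pts[:, 2] ** k
        return disp if np.asarray(points).ndim == 2 else disp[0]


@dataclass
class LatticeSpec:
    """Capsule-grid phantom geometry.

    Defaults follow the prototype 3D distortion phantom: 2.5 cm in-plane
    and 2.7 cm z centroid spacing over a 40 cm cube, capsules ~12 mm long
    and 6 mm in diameter, trimmed to the scanner acquisition FOV
    (450 x 450 x 400 mm ellipsoid), which yields ~2450 control points.
    """

    in_plane_spacing: float = 25.0
    z_spacing: float = 27.0
    extent: float = 400.0
    capsule_length: float = 12.0
    capsule_diameter: float = 6.0
    marker_intensity: float = 1000.0
    background_intensity: float = 0.0
    fov_semi_axes: tuple[float, float, float] = (225.0, 225.0, 200.0)
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        if self.in_plane_spacing <= self.capsule_diameter:
            raise ValueError("lattice spacing must exceed the capsule diameter")

    @property
    def spacing_vec(self) -> np.ndarray:
        return np.array([self.in_plane_spacing, self.in_plane_spacing,
                         self.z_spacing])

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Lattice centroids (N, 3) mm and their integer lattice indices."""
        axes, indices = [], []
        for sp in self.spacing_vec:
            n = int(np.floor(self.extent / sp))
            axes.append((np.arange(n) - (n - 1) / 2.0) * sp)
            indices.append(np.arange(n))
        X = np.meshgrid(*axes, indexing="ij")
        I = np.meshgrid(*indices, indexing="ij")
        pts = np.column_stack([x.ravel() for x in X])
        idx = np.column_stack([i.ravel() for i in I])
        a, b, c = self.fov_semi_axes
        keep = ((pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2
                + (pts[:, 2] / c) ** 2) <= 1.0
        return pts[keep], idx[keep]

    def lattice_origin(self) -> np.ndarray:
        """Physical position of lattice index (0, 0, 0)."""
        out = []
        for sp in self.spacing_vec:
            n = int(np.floor(self.extent / sp))
            out.append(-(n - 1) / 2.0 * sp)
        return np.array(out)


def _render_capsules(volume: ImageVolume, centers: np.ndarray,
                     length: float, diameter: float, intensity: float) -> None:
    """Add anti-aliased solid capsules (axis along x) into ``volume``.

    Edge voxels get partial-volume weights from the signed distance to the
    capsule surface so centroids are recoverable with sub-voxel accuracy.
    """
    radius = diameter / 2.0
    half_seg = max(length / 2.0 - radius, 0.0)  # capsule = segment + radius
    sp = np.asarray(volume.spacing)
    aa = float(np.max(sp))  # anti-aliasing band ~ one voxel
    pad = radius + half_seg + aa
    cx, cy, cz = (volume.coords(a) for a in range(3))
    for c in np.atleast_2d(centers):
        sl = []
        for axis, (coord, cc) in enumerate(zip((cx, cy, cz), c)):
            lo = np.searchsorted(coord, cc - pad)
            hi = np.searchsorted(coord, cc + pad, side="right")
            if lo >= hi:
                break
            sl.append(slice(lo, hi))
        else:
            X, Y, Z = np.meshgrid(cx[sl[0]] - c[0], cy[sl[1]] - c[1],
                                  cz[sl[2]] - c[2], indexing="ij", sparse=True)
            # distance from each voxel to the capsule's axis segment
            Xc = np.clip(X, -half_seg, half_seg)
            dist = np.sqrt((X - Xc) ** 2 + Y ** 2 + Z ** 2) - radius
            frac = np.clip(0.5 - dist / aa, 0.0, 1.0)
            volume.data[sl[0], sl[1], sl[2]] += (intensity * frac).astype(
                volume.data.dtype)


@dataclass
class ControlPointTruth:
    """Ground-truth control points of a generated grid-phantom pair."""

    lattice_index: np.ndarray   # (N, 3) int
    reference: np.ndarray       # (N, 3) mm
    displacement: np.ndarray    # (N, 3) mm
    ambiguous: bool = False     # any |d| > half the lattice spacing

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "i": self.lattice_index[:, 0], "j": self.lattice_index[:, 1],
            "k": self.lattice_index[:, 2],
            "x_ref": self.reference[:, 0], "y_ref": self.reference[:, 1],
            "z_ref": self.reference[:, 2],
            "dx": self.displacement[:, 0], "dy": self.displacement[:, 1],
            "dz": self.displacement[:, 2],
        })
        df.to_csv(path, index=False)


def gen_grid_phantom_pair(lattice: LatticeSpec | None = None,
                          model: DistortionModel | None = None,
                          noise_sd: float = 0.0,
                          seed: int = 0,
                          ) -> tuple[ImageVolume, ImageVolume, ControlPointTruth]:
    """Render the capsule-grid phantom without (reference) and with distortion.

    The reference volume plays the CT role (markers at exact lattice
    centroids); the distorted volume plays the MR role (each marker shifted
    by the model displacement).  The truth table lists every centroid and
    its displacement vector.
    """
    lattice = lattice or LatticeSpec()
    model = model or DistortionModel()
    pts, idx = lattice.centroids()
    disp = model.displacement(pts)
    nvox = int(np.ceil(lattice.extent / lattice.voxel_size)) + 1
    shape = (nvox, nvox, nvox)
    spacing = (lattice.voxel_size,) * 3

    reference = ImageVolume.centered(shape, spacing, meta={"modality": "grid-ref"})
    reference.data += lattice.background_intensity
    _render_capsules(reference, pts, lattice.capsule_length,
                     lattice.capsule_diameter, lattice.marker_intensity)

    distorted = ImageVolume.centered(shape, spacing, meta={"modality": "grid-distorted"})
    distorted.data += lattice.background_intensity
    _render_capsules(distorted, pts + disp, lattice.capsule_length,
                     lattice.capsule_diameter, lattice.marker_intensity)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        reference.data += rng.normal(0, noise_sd, shape).astype(np.float32)
        distorted.data += rng.normal(0, noise_sd, shape).astype(np.float32)

    half_min_spacing = float(np.min(lattice.spacing_vec)) / 2.0
    ambiguous = bool(np.any(np.linalg.norm(disp, axis=1) > half_min_spacing))
    truth = ControlPointTruth(idx, pts, disp, ambiguous=ambiguous)
    return reference, distorted, truth


# ---------------------------------------------------------------------------
# B0 inhomogeneity sphere, dual-echo phase images
# ---------------------------------------------------------------------------

@dataclass
class ParabolicPPMField:
    """Rotationally symmetric parabolic field deviation, ppm(r) = c r^2."""

    coefficient: float        # ppm / mm^2
    radius: float = 155.0     # sphere radius over which the field is defined, mm

    @classmethod
    def from_peak(cls, peak_ppm: float, radius: float = 155.0) -> "ParabolicPPMField":
        """Parabola reaching ``peak_ppm`` at the sphere surface."""
        return cls(coefficient=peak_ppm / radius ** 2, radius=radius)

    @classmethod
    def from_sphere_rms(cls, rms_ppm: float, radius: float = 155.0) -> "ParabolicPPMField":
        """Parabola whose mean-removed RMS over the sphere is ``rms_ppm``.

        For f(r) = c r^2 over a ball of radius R the mean is (3/5) c R^2 and
        the mean-removed RMS is c R^2 sqrt(12/175).
        """
        return cls(coefficient=rms_ppm / (radius ** 2 * np.sqrt(12.0 / 175.0)),
                   radius=radius)

    def __call__(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        return self.coefficient * (x ** 2 + y ** 2 + z ** 2)

    def analytic_sphere_rms(self) -> float:
        """Mean-removed RMS of the parabola over its sphere (closed form)."""
        return abs(self.coefficient) * self.radius ** 2 * np.sqrt(12.0 / 175.0)


def gen_phase_pair(ppm_field: Callable[..., np.ndarray],
                   te1_ms: float = 10.0, te2_ms: float = 12.0,
                   f0_hz: float = GAMMA_BAR_1T_HZ,
                   noise_sd: float = 0.0, seed: int = 0,
                   phi0: float = 0.3,
                   sphere_diameter: float = 310.0,
                   fov: float = 350.0, voxel_size: float = 2.5,
                   ) -> tuple[ImageVolume, ImageVolume, ImageVolume]:
    """Dual-echo wrapped phase images of a uniform sphere with a ppm field.

    phase_k = wrap(2 pi f0 ppm 1e-6 TE_k + phi0) into [-pi, pi).  Returns
    (phase1, phase2, truth) where truth is the unwrapped ppm field over the
    sphere mask (stored as an ImageVolume with ``meta['mask']``).

    Raises if the phase-difference field violates the Itoh condition
    (adjacent-voxel differences of the TE2-TE1 phase exceeding pi), which
    would make unwrapping ill-posed.
    """
    if te2_ms <= te1_ms:
        raise ValueError("TE2 must exceed TE1")
    n = int(np.ceil(fov / voxel_size)) + 1
    vol = ImageVolume.centered((n, n, n), (voxel_size,) * 3)
    X, Y, Z = vol.grid()
    mask = (X ** 2 + Y ** 2 + Z ** 2) <= (sphere_diameter / 2.0) ** 2
    ppm = np.where(mask, ppm_field(X, Y, Z), 0.0)

    dphi_true = 2 * np.pi * f0_hz * ppm * 1e-6 * (te2_ms - te1_ms) * 1e-3
    for axis in range(3):
        d = np.abs(np.diff(dphi_true, axis=axis))
        pair_ok = np.logical_and(np.take(mask, range(0, mask.shape[axis] - 1), axis),
                                 np.take(mask, range(1, mask.shape[axis]), axis))
        if np.any(d[pair_ok] >= np.pi):
            raise ValueError("ppm field too steep: Itoh condition violated, "
                             "phase unwrapping would be ill-posed")

    rng = np.random.default_rng(seed)
    phases = []
    for te in (te1_ms, te2_ms):
        phi = 2 * np.pi * f0_hz * ppm * 1e-6 * te * 1e-3 + phi0
        if noise_sd > 0:
            phi = phi + rng.normal(0, noise_sd, phi.shape)
        img = ImageVolume(wrap_phase(phi).astype(np.float64), vol.spacing,
                          vol.origin, meta={"TE_ms": te, "mask": mask,
                                            "f0_hz": f0_hz})
        phases.append(img)
    truth = ImageVolume(ppm.astype(np.float64), vol.spacing, vol.origin,
                        meta={"mask": mask, "dsv_mm": sphere_diameter,
                              "f0_hz": f0_hz})
    return phases[0], phases[1], truth


# ---------------------------------------------------------------------------
# crossed-ramp slice-thickness insert
# ---------------------------------------------------------------------------

def gen_ramp_volume(true_thickness: float = 5.0, ramp_angle_deg: float = 11.0,
                    spacing: float = 0.5, fov: float = 120.0,
                    intensity: float = 1000.0,
                    ) -> tuple[ImageVolume, float]:
    """Image of an angled-ramp insert whose in-plane band width encodes
    slice thickness.

    A ramp crossing the slice at ``ramp_angle_deg`` projects the slice
    thickness into an in-plane band of full width
    ``true_thickness / tan(angle)`` (profile along y).  Returns the image
    and that ground-truth profile width (mm).
    """
    if not 0.0 < ramp_angle_deg < 45.0:
        raise ValueError("ramp angle must be in (0, 45) degrees")
    width = true_thickness / np.tan(np.radians(ramp_angle_deg))
    if width >= fov:
        raise ValueError(f"ramp band ({width:.1f} mm) wider than the image FOV")
    n = int(np.ceil(fov / spacing)) + 1
    vol = ImageVolume.centered((n, n, 1), (spacing, spacing, 5.0),
                               meta={"modality": "ramp",
                                     "ramp_angle_deg": ramp_angle_deg})
    y = vol.coords(1)
    # top-hat of full width `width` centered at y=0, anti-aliased edges
    frac = np.clip((width / 2.0 - np.abs(y)) / spacing + 0.5, 0.0, 1.0)
    vol.data[:, :, 0] = intensity * frac[np.newaxis, :]
    return vol, float(width)


# ---------------------------------------------------------------------------
# multi-compartment (water / fat / bone / air) multi-echo phantom
# ---------------------------------------------------------------------------

@dataclass
class TissuePhantomSpec:
    """Compartment geometry and MR constants for the multi-echo phantom.

    A cylindrical body of water holds a cortical-bone annulus and a fat
    cylinder; outside the body is air.  T2* values are standard literature
    magnitudes (only their ordering matters downstream): cortical bone has
    T2* short enough that it is bright only at the ultrashort echo time.
    """

    fov: float = 160.0
    voxel_size: float = 2.0
    body_radius: float = 60.0
    bone_outer_radius: float = 40.0
    bone_inner_radius: float = 32.0
    fat_radius: float = 14.0
    fat_center: tuple[float, float] = (0.0, 34.0)
    bone_center: tuple[float, float] = (0.0, -10.0)
    # "density" is the effective signal amplitude, not literal proton
    # density: the generator has no T1 weighting, so the short-T1 boost
    # that makes cortical bone bright on short-TR UTE images is folded
    # into the bone amplitude
    density: dict = field(default_factory=lambda: {
        "water": 1.0, "fat": 0.95, "bone": 0.7, "air": 0.0})
    t2star_ms: dict = field(default_factory=lambda: {
        "water": 40.0, "fat": 30.0, "bone": 0.4, "air": 1.0})
    fat_fraction: dict = field(default_factory=lambda: {
        "water": 0.0, "fat": 1.0, "bone": 0.0, "air": 0.0})
    f0_hz: float = GAMMA_BAR_1T_HZ

    @property
    def fat_water_offset_hz(self) -> float:
        return FAT_WATER_PPM * 1e-6 * self.f0_hz

    def label_map(self) -> tuple[ImageVolume, dict[str, np.ndarray]]:
        """Render the compartment masks; labels partition the volume."""
        n = int(np.ceil(self.fov / self.voxel_size)) + 1
        nz = max(int(np.ceil(40.0 / self.voxel_size)), 3)
        vol = ImageVolume.centered((n, n, nz), (self.voxel_size,) * 3)
        X, Y, Z = vol.grid()
        r_body = np.sqrt(X ** 2 + Y ** 2)
        bx, by = self.bone_center
        r_bone = np.sqrt((X - bx) ** 2 + (Y - by) ** 2)
        fx, fy = self.fat_center
        r_fat = np.sqrt((X - fx) ** 2 + (Y - fy) ** 2)
        body = np.broadcast_to(r_body <= self.body_radius, vol.shape)
        # bone and fat stop short of the z faces so they are fully
        # enclosed by soft tissue, as anatomy would be
        z_half = (vol.coords(2).max() - self.voxel_size * 1.5)
        interior = np.broadcast_to(np.abs(Z) <= z_half, vol.shape)
        bone = np.broadcast_to((r_bone <= self.bone_outer_radius)
                               & (r_bone > self.bone_inner_radius),
                               vol.shape) & body & interior
        fat = np.broadcast_to(r_fat <= self.fat_radius,
                              vol.shape) & body & interior & ~bone
        air = ~body
        water = body & ~bone & ~fat
        masks = {"water": water, "fat": fat, "bone": bone, "air": air}
        labels = vol
        lab = np.zeros(vol.shape, dtype=np.int8)
        for i, name in enumerate(("air", "water", "fat", "bone")):
            lab[masks[name]] = i
        labels.data = lab
        return labels, masks


def gen_multiecho_phantom(spec: TissuePhantomSpec | None = None,
                          tes_ms: Sequence[float] = (0.144, 2.44, 4.74),
                          noise_sd: float = 0.0, seed: int = 0,
                          ) -> tuple[list[tuple[ImageVolume, ImageVolume]], dict]:
    """Magnitude+phase image pairs of the tissue phantom at each echo time.

    The complex voxel signal follows
    ``s(TE) = rho [(1-ff) + ff exp(i 2 pi df_fw TE)] exp(-TE / T2*)``
    with TE in ms converted to seconds for the chemical-shift phasor.
    Returns the echo images and a truth dict with compartment masks and the
    per-voxel density / T2* / fat-fraction maps.
    """
    spec = spec or TissuePhantomSpec()
    tes = list(tes_ms)
    if sorted(tes) != tes:
        raise ValueError("echo times must be sorted ascending")
    _, masks = spec.label_map()
    if not any(m.any() for m in masks.values()):
        raise ValueError("empty compartment map")
    shape = next(iter(masks.values())).shape
    rho = np.zeros(shape)
    t2s = np.full(shape, 1.0)
    ff = np.zeros(shape)
    for name, m in masks.items():
        rho[m] = spec.density[name]
        t2s[m] = spec.t2star_ms[name]
        ff[m] = spec.fat_fraction[name]

    rng = np.random.default_rng(seed)
    sample = ImageVolume.centered(shape, (spec.voxel_size,) * 3)
    echoes = []
    for te in tes:
        phasor = (1.0 - ff) + ff * np.exp(
            1j * 2 * np.pi * spec.fat_water_offset_hz * te * 1e-3)
        s = rho * phasor * np.exp(-te / t2s)
        if noise_sd > 0:
            s = s + rng.normal(0, noise_sd, shape) \
                + 1j * rng.normal(0, noise_sd, shape)
        mag = ImageVolume(np.abs(s), sample.spacing, sample.origin,
                          meta={"TE_ms": te, "kind": "magnitude"})
        pha = ImageVolume(np.angle(s), sample.spacing, sample.origin,
                          meta={"TE_ms": te, "kind": "phase"})
        echoes.append((mag, pha))
    truth = {"masks": masks, "density": rho, "t2star_ms": t2s,
             "fat_fraction": ff, "spec": spec}
    return echoes, truth


# ---------------------------------------------------------------------------
# respiratory waveform + moving object
# ---------------------------------------------------------------------------

@dataclass
class RespiratoryWaveform:
    """Uniformly sampled respiratory surrogate signal."""

    t: np.ndarray          # s
    a: np.ndarray          # amplitude, a.u.
    dt: float              # s
    period: float          # nominal breathing period, s
    peak_to_peak: float    # programmed amplitude, a.u.
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "amplitude": self.a}).to_csv(path, index=False)


def gen_waveform(period: float = 3.0, peak_to_peak: float = 2.0,
                 duration: float = 60.0, dt: float = 0.02,
                 anomaly: dict | None = None, seed: int = 0,
                 ) -> RespiratoryWaveform:
    """Sinusoidal breathing trace a(t) = (pp/2) sin(2 pi t / T).

    ``anomaly`` may add {"drift": mm_per_s}, {"spike": {"time": s,
    "amplitude": a.u.}} or {"jitter": sd_fraction} (per-cycle period
    irregularity, seeded).
    """
    if dt > period / 50.0:
        raise ValueError(f"dt={dt} s undersamples a {period} s cycle "
                         "(need dt <= T/50)")
    if duration < 2 * period:
        raise ValueError("duration must cover at least 2 cycles "
                         "(the trigger calibration window)")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    phase = 2 * np.pi * t / period
    anomaly = anomaly or {}
    if "jitter" in anomaly:
        rng = np.random.default_rng(seed)
        # slowly varying instantaneous period
        n_cycles = int(np.ceil(duration / period)) + 2
        factors = 1.0 + anomaly["jitter"] * rng.standard_normal(n_cycles)
        inst_period = np.repeat(period * np.clip(factors, 0.5, 1.5),
                                max(int(round(period / dt)), 1))[:n]
        phase = 2 * np.pi * np.cumsum(np.full(n, dt) / inst_period)
    a = (peak_to_peak / 2.0) * np.sin(phase)
    if "drift" in anomaly:
        a = a + anomaly["drift"] * t
    if "spike" in anomaly:
        ts, amp = anomaly["spike"]["time"], anomaly["spike"]["amplitude"]
        a = a + amp * np.exp(-((t - ts) / (0.05 * period)) ** 2)
    return RespiratoryWaveform(t=t, a=a, dt=dt, period=period,
                               peak_to_peak=peak_to_peak,
                               meta={"anomaly": anomaly, "seed": seed})


@dataclass
class MotionSampler:
    """Renders a coronal-stack frame of the moving phantom at any time.

    A cube of side ``object_size`` translates along z (superior-inferior)
    with position ``excursion * a(t) / peak_to_peak`` (full realized range =
    ``excursion``); a round static reference object sits at a fixed offset
    in the same FOV.
    """

    waveform: RespiratoryWaveform
    object_size: float = 55.0
    excursion: float = 20.0
    fov: tuple[float, float, float] = (160.0, 125.0, 200.0)
    spacing: tuple[float, float, float] = (2.0, 5.0, 2.0)
    cube_center_xy: tuple[float, float] = (-35.0, 0.0)
    static_center: tuple[float, float, float] = (40.0, 0.0, 0.0)
    static_radius: float = 15.0
    intensity: float = 1000.0

    def __post_init__(self) -> None:
        if self.object_size + self.excursion > self.fov[2]:
            raise ValueError("object plus excursion does not fit the FOV")
        self._shape = tuple(int(np.ceil(f / s)) + 1
                            for f, s in zip(self.fov, self.spacing))

    @property
    def n_slices(self) -> int:
        return self._shape[1]

    def position(self, time_s: float) -> float:
        """S-I object position (mm) at a given time."""
        i = int(round(time_s / self.waveform.dt))
        i = min(max(i, 0), len(self.waveform.a) - 1)
        return self.excursion * self.waveform.a[i] / self.waveform.peak_to_peak

    def frame(self, time_s: float) -> ImageVolume:
        vol = ImageVolume.centered(self._shape, self.spacing,
                                   meta={"time_s": time_s})
        X, Y, Z = vol.grid()
        z0 = self.position(time_s)
        half = self.object_size / 2.0
        aa = np.asarray(self.spacing)
        cx, cy = self.cube_center_xy
        fx = np.clip((half - np.abs(X - cx)) / aa[0] + 0.5, 0, 1)
        fy = np.clip((half - np.abs(Y - cy)) / aa[1] + 0.5, 0, 1)
        fz = np.clip((half - np.abs(Z - z0)) / aa[2] + 0.5, 0, 1)
        vol.data += (self.intensity * fx * fy * fz).astype(vol.data.dtype)
        sx, sy, sz = self.static_center
        r = np.sqrt((X - sx) ** 2 + (Y - sy) ** 2 + (Z - sz) ** 2)
        fs = np.clip((self.static_radius - r) / float(np.max(aa)) + 0.5, 0, 1)
        vol.data += (self.intensity * fs).astype(vol.data.dtype)
        return vol


def gen_motion_series(waveform: RespiratoryWaveform, object_size: float = 55.0,
                      excursion: float = 20.0, **kwargs) -> MotionSampler:
    """Frame sampler for the 4D-MRI motion experiment (see MotionSampler)."""
    return MotionSampler(waveform=waveform, object_size=object_size,
                         excursion=excursion, **kwargs)


# ---------------------------------------------------------------------------
# spatial-fidelity marker cylinders and simple test objects
# ---------------------------------------------------------------------------

def gen_marker_volume(positions_mm: Sequence[float] = (-30.0, 30.0),
                      sigma_mm: float = 2.0, fov: float = 120.0,
                      spacing: float = 1.0, intensity: float = 1000.0,
                      ) -> ImageVolume:
    """Marker cylinders along x rendered as Gaussian peaks (default 60 mm apart)."""
    n = int(np.ceil(fov / spacing)) + 1
    vol = ImageVolume.centered((n, n, 3), (spacing, spacing, 2.0),
                               meta={"modality": "markers"})
    X, Y, _ = vol.grid()
    for p in positions_mm:
        vol.data += intensity * np.exp(-((X - p) ** 2 + Y ** 2)
                                       / (2 * sigma_mm ** 2)).astype(np.float32)
    return vol


def gen_sphere_volume(radius_mm: float = 10.0, spacing: float = 1.0,
                      fov: float | None = None, intensity: float = 1000.0,
                      center: tuple[float, float, float] = (0.0, 0.0, 0.0),
                      ) -> ImageVolume:
    """Anti-aliased solid sphere for volumetric-analysis tests."""
    fov = fov or (4 * radius_mm)
    n = int(np.ceil(fov / spacing)) + 1
    vol = ImageVolume.centered((n, n, n), (spacing,) * 3,
                               meta={"modality": "sphere"})
    X, Y, Z = vol.grid()
    r = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    vol.data += (intensity * np.clip((radius_mm - r) / spacing + 0.5, 0, 1)
                 ).astype(np.float32)
    return vol
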