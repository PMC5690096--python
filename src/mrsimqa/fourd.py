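"""Amplitude-triggered 4D-MRI acquisition simulation and motion metrics.

Respiratory-resolved imaging is emulated on a synthetic moving object: the
first two breathing cycles calibrate amplitude trigger levels (bin centers
of the observed min-max range, with rising/falling slope tags so the
inhale and exhale limbs map to distinct phases, 0% = end-inhale); the
waveform is then scanned forward in time and each level crossing of a
still-needed phase acquires one slice, occupying one TR window, with at
most one acquisition per breathing cycle so the magnetization relaxes
fully between samplings of a slice.  The metrics of
interest are the duty cycle (nominal programmed acquisition time divided by
overall scan time), the scan-time scaling with phase count, and the
superior-inferior extent of the motion envelope on the maximum-intensity
projection (MIP) across phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageVolume, require_same_grid
from .synthetic import MotionSampler, RespiratoryWaveform


@dataclass
class TriggerScheme:
    """Per-phase amplitude trigger levels with slope tags.

    ``levels[p]`` is the amplitude at which phase p triggers; ``slopes[p]``
    is +1 for rising (exhale-to-inhale limb) and -1 for falling.  Phase 0
    is end-inhale (waveform maximum side), phase N/2 end-exhale.
    """

    levels: np.ndarray
    slopes: np.ndarray
    calibration_min: float
    calibration_max: float
    calibration_window_s: float
    meta: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return len(self.levels)

    def phase_labels(self) -> list[str]:
        n = self.n_phases
        return [f"{100 * p // n}%" for p in range(n)]


def calibrate_trigger_levels(w: RespiratoryWaveform, n_phases: int,
                             ) -> TriggerScheme:
    """Derive trigger levels from the first two breathing cycles.

    The min/max of the calibration window define N amplitude bins; the
    levels sit at bin centers ``min + (k + 0.5)(max - min)/N``.  Falling
    (inhale-to-exhale) phases take the odd-stepped levels from the top
    down, rising phases the remaining levels from the bottom up, so every
    bin-center level is used exactly once and the two limbs get distinct
    phases.  A transient anomaly inside the window shifts the levels with
    it; this is flagged when the calibration range deviates from the rest
    of the trace.
    """
    if n_phases < 2:
        raise ValueError("need at least 2 respiratory phases")
    window = w.t <= 2.0 * w.period
    if window.sum() < 2:
        raise ValueError("waveform does not cover the 2-cycle calibration window")
    amin, amax = float(w.a[window].min()), float(w.a[window].max())
    if amax <= amin:
        raise ValueError("flat waveform: trigger levels undefined")
    centers = amin + (np.arange(n_phases) + 0.5) * (amax - amin) / n_phases
    n_fall = (n_phases + 1) // 2
    falling = centers[::-1][0:2 * n_fall:2]          # top level downward, step 2
    rising = np.sort(np.setdiff1d(centers, falling))  # remainder, bottom up
    levels = np.concatenate([falling, rising])
    slopes = np.concatenate([-np.ones(len(falling), int),
                             np.ones(len(rising), int)])
    rest = ~window
    anomaly = False
    if rest.any():
        full_range = float(w.a[rest].max() - w.a[rest].min())
        anomaly = abs((amax - amin) - full_range) > 0.05 * max(full_range, 1e-12)
    return TriggerScheme(levels, slopes, amin, amax,
                         calibration_window_s=2.0 * w.period,
                         meta={"calibration_anomaly": bool(anomaly)})


@dataclass
class AcquisitionTimeline:
    """Trigger events and total times of one simulated 4D acquisition."""

    events: pd.DataFrame        # columns: t_s, slice, phase, window_s
    nominal_time_s: float       # N_phases * n_slices * TR
    overall_time_s: float       # last window end - calibration end
    calibration_time_s: float
    complete: bool = True

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


@dataclass
class PhaseSortedVolumes:
    """One image volume per respiratory phase on a common grid."""

    volumes: list[ImageVolume]
    labels: list[str]

    def __post_init__(self) -> None:
        for v in self.volumes[1:]:
            require_same_grid(self.volumes[0], v, "phase volumes")


class AcquisitionIncompleteError(RuntimeError):
    """Waveform exhausted before every (slice, phase) pair was acquired."""

    def __init__(self, msg: str, timeline: AcquisitionTimeline,
                 volumes: PhaseSortedVolumes):
        super().__init__(msg)
        self.timeline = timeline
        self.volumes = volumes


def simulate_triggered_acquisition(sampler: MotionSampler,
                                   w: RespiratoryWaveform,
                                   scheme: TriggerScheme,
                                   n_slices: int | None = None,
                                   tr_ms: float = 2000.0,
                                   ) -> tuple[AcquisitionTimeline, PhaseSortedVolumes]:
    """Scan the waveform forward and acquire slices at trigger crossings.

    Acquisition is slice-major: the current slice collects its N phase
    images, one per crossing of a still-needed phase's trigger level (with
    matching slope), before the next slice starts.  Each acquisition
    occupies one TR window, and to let the magnetization fully relax the
    trigger is re-armed only at the start of the next breathing cycle
    (first rising mid-level crossing after the event), so at most one
    slice-phase is sampled per cycle.  Slice rows for a phase are taken
    from the motion frame at trigger time.  Completion requires every
    (slice, phase) pair exactly once; if the waveform runs out first an
    AcquisitionIncompleteError carrying the partial result is raised.
    """
    n_slices = n_slices or sampler.n_slices
    if n_slices > sampler.n_slices:
        raise ValueError(f"sampler provides {sampler.n_slices} slices")
    tr_s = tr_ms / 1000.0
    n_phases = scheme.n_phases
    t_cal = scheme.calibration_window_s
    mid = 0.5 * (scheme.calibration_min + scheme.calibration_max)
    template = sampler.frame(0.0)
    phase_vols = [ImageVolume.centered(template.shape, template.spacing,
                                       meta={"phase": p}) for p in range(n_phases)]
    events = []
    a, t = w.a, w.t
    s_idx = 0
    needed = set(range(n_phases))
    t_arm = t_cal
    i = max(int(np.searchsorted(t, t_cal)), 1)
    while s_idx < n_slices and i < len(t):
        if t[i] < t_arm:
            i = max(int(np.searchsorted(t, t_arm)), i + 1)
            continue
        prev, cur = a[i - 1], a[i]
        fired = None
        for p in sorted(needed):
            L, s = scheme.levels[p], scheme.slopes[p]
            if (s > 0 and prev < L <= cur) or (s < 0 and prev > L >= cur):
                fired = p
                break
        if fired is not None:
            frame = sampler.frame(t[i])
            phase_vols[fired].data[:, s_idx, :] = frame.data[:, s_idx, :]
            events.append({"t_s": float(t[i]), "slice": int(s_idx),
                           "phase": int(fired), "window_s": tr_s})
            needed.discard(fired)
            if not needed:
                s_idx += 1
                needed = set(range(n_phases))
            # re-arm after the TR window and not before the next cycle
            # begins (magnetization relaxation across breathing cycles)
            j = i + 1
            while j < len(t) and not (a[j - 1] < mid <= a[j]):
                j += 1
            t_next_cycle = t[j] if j < len(t) else np.inf
            t_arm = max(t[i] + tr_s, t_next_cycle)
        i += 1

    ev = pd.DataFrame(events, columns=["t_s", "slice", "phase", "window_s"])
    nominal = n_phases * n_slices * tr_s
    overall = (float(ev.t_s.iloc[-1]) + tr_s - t_cal) if len(ev) else 0.0
    complete = s_idx >= n_slices
    timeline = AcquisitionTimeline(ev, nominal, overall, t_cal,
                                   complete=complete)
    volumes = PhaseSortedVolumes(phase_vols, scheme.phase_labels())
    if not complete:
        missing = n_phases * n_slices - len(events)
        raise AcquisitionIncompleteError(
            f"waveform exhausted with {missing} slice-phase pairs still "
            "unacquired", timeline, volumes)
    return timeline, volumes


def duty_cycle(timeline: AcquisitionTimeline) -> float:
    """Nominal programmed acquisition time divided by overall scan time."""
    if timeline.overall_time_s <= 0:
        raise ValueError("overall scan time must be positive")
    acquired = float(timeline.events.window_s.sum())
    return acquired / timeline.overall_time_s


def compute_mip(phases: PhaseSortedVolumes,
                subset: list[int] | None = None) -> ImageVolume:
    """Voxelwise maximum intensity over a subset of phases (default: all)."""
    subset = list(range(len(phases.volumes))) if subset is None else list(subset)
    if not subset:
        raise ValueError("phase subset is empty")
    base = phases.volumes[subset[0]]
    out = np.array(base.data, dtype=np.float32, copy=True)
    for p in subset[1:]:
        require_same_grid(base, phases.volumes[p], "phase volumes")
        np.maximum(out, phases.volumes[p].data, out=out)
    return ImageVolume(out, base.spacing, base.origin,
                       meta={"kind": "MIP", "phases": subset})


def object_extent(volume: ImageVolume, axis: int = 2,
                  threshold: float = 0.5) -> float:
    """Edge-inclusive extent (mm) of the above-threshold object along an axis.

    ``threshold`` is a fraction of the volume maximum; the extent is the
    distance between the first and last above-threshold positions plus one
    voxel.
    """
    data = np.asarray(volume.data, float)
    mx = data.max()
    if mx <= 0:
        raise ValueError("nothing above threshold")
    hit = np.any(data > threshold * mx,
                 axis=tuple(a for a in range(3) if a != axis))
    idx = np.where(hit)[0]
    if idx.size == 0:
        raise ValueError("nothing above threshold")
    return float((idx[-1] - idx[0] + 1) * volume.spacing[axis])


def phase_count_study(sampler: MotionSampler, w: RespiratoryWaveform,
                      phase_counts: list[int], n_slices: int | None = None,
                      tr_ms: float = 2000.0) -> pd.DataFrame:
    """Run the triggered acquisition for several phase counts on one waveform.

    Returns a table of N_phases, duty cycle, overall scan time, MIP S-I
    extent, and the percent extent difference referenced to the largest
    phase count.
    """
    if sorted(phase_counts) != list(phase_counts):
        raise ValueError("phase counts must be sorted ascending")
    rows = []
    for n in phase_counts:
        scheme = calibrate_trigger_levels(w, n)
        timeline, vols = simulate_triggered_acquisition(
            sampler, w, scheme, n_slices=n_slices, tr_ms=tr_ms)
        mip = compute_mip(vols)
        rows.append({"n_phases": n,
                     "duty_cycle": duty_cycle(timeline),
                     "overall_time_s": timeline.overall_time_s,
                     "mip_extent_mm": object_extent(mip, axis=2)})
    df = pd.DataFrame(rows)
    ref = df.mip_extent_mm.iloc[-1]
    df["extent_vs_max_pct"] = 100.0 * (df.mip_extent_mm - ref) / ref
    return df
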