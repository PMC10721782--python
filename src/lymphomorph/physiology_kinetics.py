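"""Photobiomodulation session kinetics: dosing schedule, cortical-surface
temperature traces, and tracer-drainage fluorescence time courses.

The treatment session is a sequence of irradiation and pause segments (the
standard transcranial 1267-nm protocol is 17 min irradiation, 5 min pause,
repeated three times — 61 min in total). A thermocouple trace recorded at
the brain surface is summarized as the maximum and the mean temperature rise
over a pre-session baseline; traces exceeding the +0.5 °C cortical-damage
threshold are flagged. Lymphatic drainage of an injected tracer (e.g. Evans
blue in the deep cervical lymph nodes) is quantified as a
background-subtracted mean-ROI intensity time course.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .imaging_io import BinaryMask, VesselImage


class PhysiologyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dosing schedule
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Segment:
    kind: str  # "irradiation" | "pause"
    minutes: float

    def __post_init__(self) -> None:
        if self.minutes <= 0:
            raise PhysiologyError("segment duration must be > 0")
        if self.kind not in ("irradiation", "pause"):
            raise PhysiologyError(f"unknown segment kind {self.kind!r}")


@dataclasses.dataclass
class ProtocolSchedule:
    """Ordered irradiation/pause segments plus the optical dose parameters.

    ``fluence_j_cm2`` is a free parameter (16/32/64 J/cm² in the standard
    dosing study but not enforced); ``spot_area_cm2`` is the irradiated spot.
    """

    segments: list[Segment]
    fluence_j_cm2: float | None = None
    spot_area_cm2: float = 0.2

    def __post_init__(self) -> None:
        if self.spot_area_cm2 <= 0:
            raise PhysiologyError("spot area must be > 0")


def standard_pbm_schedule(fluence_j_cm2: float | None = None) -> ProtocolSchedule:
    """The 3×(17 min irradiation) / 2×(5 min pause) session, 61 min total."""
    return ProtocolSchedule(
        segments=[
            Segment("irradiation", 17),
            Segment("pause", 5),
            Segment("irradiation", 17),
            Segment("pause", 5),
            Segment("irradiation", 17),
        ],
        fluence_j_cm2=fluence_j_cm2,
    )


def protocol_duration(schedule: ProtocolSchedule) -> float:
    """Total session duration in minutes (sum of all segment durations)."""
    return float(sum(s.minutes for s in schedule.segments))


# ---------------------------------------------------------------------------
# temperature traces
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TemperatureTrace:
    """Thermocouple samples with session-segment annotations.

    ``segments`` holds ``(kind, start_s, end_s)`` tuples covering the session
    (kinds "baseline", "irradiation", "pause"). Temperatures outside the
    physiological [20, 45] °C band are rejected as sensor faults.
    """

    t_s: np.ndarray
    temp_c: np.ndarray
    segments: list[tuple[str, float, float]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.t_s.size == 0 or self.t_s.size != self.temp_c.size:
            raise PhysiologyError("trace needs matching non-empty t and temperature")
        if np.any(np.diff(self.t_s) <= 0):
            raise PhysiologyError("timestamps must be strictly increasing")
        if self.temp_c.min() < 20 or self.temp_c.max() > 45:
            raise PhysiologyError("temperature outside [20, 45] degC sanity band")

    def first_irradiation_start(self) -> float:
        starts = [s for k, s, _ in self.segments if k == "irradiation"]
        if not starts:
            raise PhysiologyError("trace has no annotated irradiation segment")
        return min(starts)


def annotate_trace(
    trace: TemperatureTrace, schedule: ProtocolSchedule, session_start_s: float
) -> TemperatureTrace:
    """Attach schedule-derived segment boundaries to a raw trace."""
    segments: list[tuple[str, float, float]] = []
    if session_start_s > trace.t_s[0]:
        segments.append(("baseline", float(trace.t_s[0]), session_start_s))
    t = session_start_s
    for seg in schedule.segments:
        segments.append((seg.kind, t, t + seg.minutes * 60.0))
        t += seg.minutes * 60.0
    return TemperatureTrace(trace.t_s, trace.temp_c, segments)


def _baseline_mean(trace: TemperatureTrace, baseline_window_s: float) -> float:
    t0 = trace.first_irradiation_start()
    sel = (trace.t_s >= t0 - baseline_window_s) & (trace.t_s < t0)
    if sel.sum() < 3:
        raise PhysiologyError(
            "baseline window before first irradiation holds < 3 samples"
        )
    return float(trace.temp_c[sel].mean())


def _smoothed(trace: TemperatureTrace, window_s: float) -> np.ndarray:
    if window_s <= 0:
        return trace.temp_c
    dt = float(np.median(np.diff(trace.t_s)))
    n = max(int(round(window_s / dt)), 1)
    kernel = np.ones(n) / n
    pad = n // 2
    padded = np.pad(trace.temp_c, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad : pad + trace.temp_c.size]


def max_temperature_rise(
    trace: TemperatureTrace,
    baseline_window_s: float = 60.0,
    smooth_window_s: float = 0.0,
) -> float:
    """Maximum of (T − baseline) over the session; negative if it only cools.

    Baseline is the mean over the ``baseline_window_s`` seconds immediately
    preceding the first irradiation segment. ``smooth_window_s`` applies a
    moving average before taking the maximum: the raw maximum of a long noisy
    trace carries an extreme-value bias of several noise SDs, so a window
    short against the thermal time constant is recommended for noisy loggers.
    """
    baseline = _baseline_mean(trace, baseline_window_s)
    t0 = trace.first_irradiation_start()
    session = _smoothed(trace, smooth_window_s)[trace.t_s >= t0]
    if session.size == 0:
        raise PhysiologyError("no samples after session start")
    return float(session.max() - baseline)


def mean_temperature_rise(
    trace: TemperatureTrace, baseline_window_s: float = 60.0
) -> float:
    """Mean of (T − baseline) over the irradiation segments only."""
    baseline = _baseline_mean(trace, baseline_window_s)
    sel = np.zeros_like(trace.t_s, dtype=bool)
    for kind, s, e in trace.segments:
        if kind == "irradiation":
            sel |= (trace.t_s >= s) & (trace.t_s < e)
    if not sel.any():
        raise PhysiologyError("no samples inside irradiation segments")
    return float(trace.temp_c[sel].mean() - baseline)


def exceeds_safety_threshold(
    trace: TemperatureTrace,
    baseline_window_s: float = 60.0,
    threshold_c: float = 0.5,
) -> bool:
    """Flag traces whose maximum rise exceeds the cortical-damage threshold.

    A sustained +0.5 °C cortical rise is the conventional irreversible-damage
    limit; the flag is informational only and modifies no data.
    """
    return max_temperature_rise(trace, baseline_window_s) > threshold_c


# ---------------------------------------------------------------------------
# tracer drainage time courses
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class IntensitySeries:
    """Background-subtracted mean ROI intensity per timepoint."""

    t_min: np.ndarray
    intensity: np.ndarray
    background: np.ndarray
    normalization: str = "none"  # "none" | "max"

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if np.any(np.diff(self.t_min) <= 0):
            raise PhysiologyError("timepoints must be strictly increasing")
        if np.any(self.intensity < 0):
            raise PhysiologyError("intensities must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_min": self.t_min,
                "intensity": self.intensity,
                "background": self.background,
            }
        )


def roi_timecourse(
    images: list[VesselImage],
    times_min,
    roi: BinaryMask,
    background_roi: BinaryMask,
    normalize: str = "none",
) -> IntensitySeries:
    """Mean ROI minus mean background intensity per timepoint, clamped at 0.

    Background subtraction makes the series invariant to adding a constant to
    the whole image. ``normalize="max"`` rescales the series to its maximum
    for cross-animal comparison at fixed timepoints.
    """
    if not roi.grid.any() or not background_roi.grid.any():
        raise PhysiologyError("empty ROI")
    times = np.asarray(times_min, dtype=float)
    if len(images) != times.size:
        raise PhysiologyError("one timestamp per image required")
    vals, bgs = [], []
    for img in images:
        if img.shape != roi.shape or img.shape != background_roi.shape:
            raise PhysiologyError("image/ROI shape mismatch")
        bg = float(img.pixels[background_roi.grid].mean())
        vals.append(max(float(img.pixels[roi.grid].mean()) - bg, 0.0))
        bgs.append(bg)
    intensity = np.asarray(vals)
    if normalize == "max":
        peak = intensity.max()
        if peak > 0:
            intensity = intensity / peak
    elif normalize != "none":
        raise PhysiologyError(f"unknown normalization {normalize!r}")
    return IntensitySeries(times, intensity, np.asarray(bgs), normalization=normalize)
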