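"""Arteriole diameter, dF/F, dilation events, and dilation-triggered averages.

Diameter is estimated per frame as the full width at half maximum (FWHM) of
an averaged cross-vessel intensity profile: 20 lines spaced 2 um apart are
drawn perpendicular to the vessel axis, their profiles averaged, min-max
normalized, and the distance between the two half-maximum crossings (linear
interpolation between samples) taken as the diameter.

Large dilations are local maxima of the fractional diameter increase over a
rolling-median baseline; to avoid the confound of successive dilations, any
qualifying peak with another qualifying peak within the isolation window
(default 10 frames, 17.5 s) is excluded — both peaks drop.  Stall point
prevalence is then averaged across events in a window around each peak
(lag 0 = peak diameter) with the standard error taken across events.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import DegenerateBaselineError, UnbracketedFWHMError, ValidationError
from .types import DiameterTrace, DilationEvent, ImageTimeSeries, TriggeredAverage

__all__ = [
    "diameter_fwhm",
    "diameter_trace",
    "dff",
    "detect_dilations",
    "triggered_average",
]

logger = logging.getLogger(__name__)

DEFAULT_N_LINES = 20
DEFAULT_LINE_SPACING_UM = 2.0
DEFAULT_SAMPLE_STEP_UM = 0.5
DEFAULT_BASELINE_WINDOW_FRAMES = 31  # rolling-median width (odd)


def _average_profile(
    frame,
    axis_point,
    axis_direction,
    pixel_size,
    n_lines,
    spacing_um,
    profile_halfwidth_um,
    step_um,
):
    frame = np.asarray(frame, dtype=float)
    u = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValidationError("axis_direction must be a nonzero vector")
    u = u / norm
    v = np.array([-u[1], u[0]])  # perpendicular
    p0 = np.asarray(axis_point, dtype=float)

    s = np.arange(-profile_halfwidth_um, profile_halfwidth_um + step_um / 2, step_um)
    line_offsets = (np.arange(n_lines) - (n_lines - 1) / 2.0) * spacing_um
    # (n_lines, n_samples, 2) sample coordinates in pixels
    pts = (
        p0[None, None, :]
        + line_offsets[:, None, None] / pixel_size * u[None, None, :]
        + s[None, :, None] / pixel_size * v[None, None, :]
    )
    H, W = frame.shape
    if pts[..., 0].min() < 0 or pts[..., 0].max() > W - 1 or pts[..., 1].min() < 0 or pts[..., 1].max() > H - 1:
        raise ValidationError("profile lines extend outside the image")
    prof = ndimage.map_coordinates(
        frame, [pts[..., 1].ravel(), pts[..., 0].ravel()], order=1
    ).reshape(n_lines, len(s))
    return s, prof.mean(axis=0)


def _fwhm_of_profile(s, profile):
    lo, hi = profile.min(), profile.max()
    if hi <= lo:
        raise UnbracketedFWHMError("profile is flat; no half-maximum exists")
    norm = (profile - lo) / (hi - lo)
    peak = int(np.argmax(norm))

    def crossing(indices):
        """First crossing of 0.5 walking away from the peak along ``indices``."""
        prev = peak
        for i in indices:
            if norm[i] < 0.5 <= norm[prev]:
                # linear interpolation between samples prev and i
                frac = (norm[prev] - 0.5) / (norm[prev] - norm[i])
                return s[prev] + frac * (s[i] - s[prev])
            prev = i
        raise UnbracketedFWHMError("profile never crosses half-maximum on one side")

    left = crossing(range(peak - 1, -1, -1))
    right = crossing(range(peak + 1, len(norm)))
    return float(abs(right - left))


def diameter_fwhm(
    frame,
    axis_point,
    axis_direction,
    pixel_size,
    n_lines=DEFAULT_N_LINES,
    spacing_um=DEFAULT_LINE_SPACING_UM,
    profile_halfwidth_um=40.0,
    step_um=DEFAULT_SAMPLE_STEP_UM,
):
    """Vessel diameter (um) from one frame.

    ``axis_point`` (x, y, pixels) sits on the vessel axis and
    ``axis_direction`` points along it; ``n_lines`` profiles perpendicular to
    the axis, spaced ``spacing_um`` apart, are averaged before the FWHM is
    measured.  Raises :class:`UnbracketedFWHMError` when the averaged profile
    never falls below half maximum on one side.
    """
    s, profile = _average_profile(
        frame, axis_point, axis_direction, pixel_size, n_lines, spacing_um,
        profile_halfwidth_um, step_um,
    )
    return _fwhm_of_profile(s, profile)


def diameter_trace(frames: ImageTimeSeries, axis_point, axis_direction, **kwargs) -> DiameterTrace:
    """Per-frame FWHM diameter; frames with an unbracketed profile give NaN."""
    values = np.empty(frames.n_frames)
    n_bad = 0
    for t in range(frames.n_frames):
        try:
            values[t] = diameter_fwhm(
                frames.frames[t], axis_point, axis_direction, frames.pixel_size, **kwargs
            )
        except UnbracketedFWHMError:
            values[t] = np.nan
            n_bad += 1
    if n_bad:
        logger.warning("diameter undefined (unbracketed FWHM) on %d frames", n_bad)
    return DiameterTrace(values)


def dff(frames: ImageTimeSeries, roi):
    """dF/F trace of a rectangular ROI.

    ``roi`` is ``(x0, y0, x1, y1)`` with exclusive upper bounds.  F is the
    ROI-mean intensity per frame; the baseline F0 is the 10th percentile of
    the F trace, a convention robust to dilation transients.
    """
    x0, y0, x1, y1 = (int(v) for v in roi)
    H, W = frames.frames.shape[1:]
    if not (0 <= x0 < x1 <= W and 0 <= y0 < y1 <= H):
        raise ValidationError(f"roi {roi} outside the {W}x{H} image")
    f = frames.frames[:, y0:y1, x0:x1].mean(axis=(1, 2))
    f0 = np.percentile(f, 10.0)
    if f0 == 0:
        raise DegenerateBaselineError("baseline F0 is zero")
    return (f - f0) / f0


def detect_dilations(
    diameter: DiameterTrace,
    amplitude_frac_min=0.1,
    isolation_frames=10,
    baseline_window=DEFAULT_BASELINE_WINDOW_FRAMES,
):
    """Isolated large-dilation events from a diameter trace.

    A qualifying peak is a local maximum of the fractional increase over the
    rolling-median baseline reaching ``amplitude_frac_min``; qualifying peaks
    closer than ``isolation_frames`` to another qualifying peak are all
    excluded.  Returns a (possibly empty) list of :class:`DilationEvent`.
    """
    d = np.asarray(diameter.values, dtype=float)
    if len(d) <= 2 * isolation_frames:
        raise ValidationError("trace must be longer than twice the isolation window")
    filled = d.copy()
    bad = ~np.isfinite(filled)
    if bad.all():
        raise ValidationError("diameter trace has no defined values")
    if bad.any():
        filled[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), filled[~bad])
    if baseline_window % 2 == 0:
        baseline_window += 1
    baseline = ndimage.median_filter(filled, size=baseline_window, mode="nearest")
    frac = (filled - baseline) / baseline
    peaks, props = find_peaks(frac, height=amplitude_frac_min)
    if len(peaks) == 0:
        return []
    keep = []
    for i, p in enumerate(peaks):
        near = np.abs(peaks - p) <= isolation_frames
        near[i] = False
        if not near.any():
            keep.append(DilationEvent(int(p), float(props["peak_heights"][i])))
    return keep


def triggered_average(prevalence_per_frame, events, window=10) -> TriggeredAverage:
    """Average a per-frame trace in a window around each dilation peak.

    Events whose window does not fit inside the record are dropped (and
    logged); with no usable event a :class:`ValidationError` is raised.
    ``lags`` run from ``-window`` to ``+window`` with 0 at peak diameter, and
    ``sem`` is SD across events divided by sqrt(n_events).
    """
    trace = np.asarray(prevalence_per_frame, dtype=float)
    T = len(trace)
    lags = np.arange(-window, window + 1)
    rows = []
    n_dropped = 0
    for ev in events:
        p = ev.peak_frame
        if p - window < 0 or p + window >= T:
            n_dropped += 1
            continue
        rows.append(trace[p - window : p + window + 1])
    if n_dropped:
        logger.info("triggered_average: dropped %d events with clipped windows", n_dropped)
    if not rows:
        raise ValidationError("no dilation event window fits inside the record")
    rows = np.asarray(rows)
    n = len(rows)
    sem = rows.std(axis=0, ddof=0) / np.sqrt(n) if n > 1 else np.zeros(rows.shape[1])
    return TriggeredAverage(lags=lags, mean=rows.mean(axis=0), sem=sem, n_events=n)
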