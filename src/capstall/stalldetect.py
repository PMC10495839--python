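"""Correlation-based stall flagging.

While RBCs flow, each frame of a capillary's LT image is an independent
arrangement of shadows, so consecutive LT rows are uncorrelated; during a
stall the same shadows sit still and consecutive rows become nearly
identical.  Thresholding the frame-to-frame Pearson correlation therefore
flags candidate stalls.  A suprathreshold correlation ``r[t]`` is evidence
about the *pair* of frames (t, t+1), so both frames are marked stalled —
which makes the minimum detectable event exactly two frames long (one frame
interval, 1.75 s at the default 0.57 Hz rate).

The default threshold (0.4) is deliberately low: the detector trades
specificity for sensitivity, and its output is meant to be validated against
ground truth (here) or reviewed by a human (on real data, via the candidate
CSV export).
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .types import ConfusionTable, CorrelationTrace, LTImage, StallEvent, Stallogram

__all__ = [
    "frame_correlation",
    "threshold_correlation",
    "adaptive_threshold_value",
    "events_to_stallogram",
    "compare_to_truth",
]

DEFAULT_THRESHOLD = 0.4


def frame_correlation(lt: LTImage) -> CorrelationTrace:
    """Pearson correlation between each pair of consecutive LT rows.

    A pair in which either row has zero variance yields ``r = 0`` with its
    ``degenerate`` flag set: a featureless row is no evidence of a frozen
    shadow pattern.
    """
    values = lt.values
    if values.shape[0] < 2:
        raise ValidationError("frame correlation needs at least 2 LT rows")
    centered = values - values.mean(axis=1, keepdims=True)
    ss = (centered**2).sum(axis=1)
    num = (centered[:-1] * centered[1:]).sum(axis=1)
    denom = np.sqrt(ss[:-1] * ss[1:])
    degenerate = denom == 0
    r = np.zeros(values.shape[0] - 1)
    np.divide(num, denom, out=r, where=~degenerate)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationTrace(lt.capillary_id, r, degenerate, lt.frame_period)


def adaptive_threshold_value(trace: CorrelationTrace, n_sd=2.0) -> float:
    """Data-driven alternative threshold: mean + ``n_sd`` SD of the trace."""
    return float(trace.r.mean() + n_sd * trace.r.std())


def _runs(mask):
    """Maximal True runs of a boolean vector as (start, end) inclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2] - 1))


def threshold_correlation(trace: CorrelationTrace, threshold=DEFAULT_THRESHOLD):
    """Flag stalls: ``r[t] >= threshold`` marks frames t and t+1 as stalled.

    Maximal runs of stalled frames become :class:`StallEvent` objects, so one
    suprathreshold value yields a two-frame event and ``k`` consecutive
    suprathreshold values a ``(k+1)``-frame event.
    """
    supra = trace.r >= threshold
    stalled = np.zeros(len(trace.r) + 1, dtype=bool)
    stalled[:-1] |= supra
    stalled[1:] |= supra
    return [
        StallEvent(trace.capillary_id, int(s), int(e), trace.frame_period)
        for s, e in _runs(stalled)
    ]


def events_to_stallogram(events, capillary_ids, n_frames, frame_period=None) -> Stallogram:
    """Paint events into a boolean capillaries x frames matrix.

    Overlapping or adjacent events on one capillary merge into a single run.
    """
    capillary_ids = list(capillary_ids)
    row = {cid: i for i, cid in enumerate(capillary_ids)}
    matrix = np.zeros((len(capillary_ids), n_frames), dtype=bool)
    for ev in events:
        if ev.capillary_id not in row:
            raise ValidationError(f"event references unknown capillary {ev.capillary_id!r}")
        if ev.start_frame < 0 or ev.end_frame >= n_frames:
            raise ValidationError(
                f"event [{ev.start_frame}, {ev.end_frame}] outside [0, {n_frames})"
            )
        matrix[row[ev.capillary_id], ev.start_frame : ev.end_frame + 1] = True
        if frame_period is None:
            frame_period = ev.frame_period
    if frame_period is None:
        raise ValidationError("frame_period required when no events are given")
    return Stallogram(matrix, capillary_ids, frame_period)


def compare_to_truth(predicted: Stallogram, truth: Stallogram, level="capillary") -> ConfusionTable:
    """Confusion table of predicted against ground-truth stallograms.

    At the default capillary level a capillary is positive if it has at least
    one stall event anywhere in the record; ``level='frame'`` compares every
    (capillary, frame) entry instead.
    """
    if predicted.matrix.shape != truth.matrix.shape:
        raise ValidationError("predicted and truth stallograms must have equal shapes")
    if list(predicted.capillary_ids) != list(truth.capillary_ids):
        raise ValidationError("predicted and truth capillary ids must match")
    if level == "capillary":
        p = predicted.matrix.any(axis=1)
        t = truth.matrix.any(axis=1)
    elif level == "frame":
        p = predicted.matrix.ravel()
        t = truth.matrix.ravel()
    else:
        raise ValidationError("level must be 'capillary' or 'frame'")
    return ConfusionTable(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
        level=level,
    )
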