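"""Stallogram summary statistics, duration filtering, and the exponential
incidence model.

Definitions (all percentages):

* **incidence** — percent of all counted capillaries that stall at least once
  during the record;
* **point prevalence** — average over frames of the percent of capillaries
  stalled in that frame;
* **cumulative stall duration** — average, over capillaries that stall, of
  the percent of the record each spends stalled (a per-capillary time
  fraction, optionally reported in seconds instead).

Because short stalls dominate at high volume rates, statistics are also
computed after removing stalls shorter than a minimum number of frames; a
minimum of two keeps every detected stall.  The growth of incidence with
measurement time is summarized by the saturating exponential model
``I(t) = A (1 - exp(-B t)) + C`` with ``t`` in minutes: a subset of
capillaries stalls repeatedly, so the pool of observed stallers saturates
rather than growing linearly.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .types import DurationCDF, ExponentialFit, StallEvent, Stallogram, StallStatistics

__all__ = [
    "extract_events",
    "compute_statistics",
    "filter_min_duration",
    "duration_cdf",
    "incidence_vs_time",
    "fit_exponential",
    "exponential_model",
    "confusion_rates",
]


def extract_events(stallogram: Stallogram):
    """Read maximal stalled runs off the stallogram, one event per run.

    A run of a single frame violates the stall definition and raises an
    integrity error.
    """
    events = []
    for i, cid in enumerate(stallogram.capillary_ids):
        row = stallogram.matrix[i]
        idx = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
        for s, e in zip(idx[::2], idx[1::2] - 1):
            if e - s + 1 < 2:
                raise ValidationError(
                    f"capillary {cid!r} has a single-frame stalled run at frame {s}; "
                    "stallogram invariant violated"
                )
            events.append(StallEvent(cid, int(s), int(e), stallogram.frame_period))
    return events


def compute_statistics(stallogram: Stallogram, n_capillaries_total=None) -> StallStatistics:
    """Incidence, point prevalence and cumulative stall duration.

    ``n_capillaries_total`` is the denominator of incidence and prevalence —
    the number of capillaries counted in the field, which may exceed the
    number analyzed.  Defaults to the stallogram's row count.
    """
    if n_capillaries_total is None:
        n_capillaries_total = stallogram.n_capillaries
    if n_capillaries_total <= 0:
        raise ValidationError("n_capillaries_total must be positive")
    stalling_rows = stallogram.matrix.any(axis=1)
    n_stalling = int(stalling_rows.sum())
    if n_capillaries_total < n_stalling:
        raise ValidationError("n_capillaries_total is smaller than the number of stalling rows")
    T = stallogram.n_frames
    incidence = 100.0 * n_stalling / n_capillaries_total
    point_prevalence = 100.0 * stallogram.matrix.sum(axis=0).mean() / n_capillaries_total
    if n_stalling:
        frac = stallogram.matrix[stalling_rows].sum(axis=1) / T
        cumulative = 100.0 * frac.mean()
        no_stalls = False
    else:
        cumulative = 0.0
        no_stalls = True
    return StallStatistics(
        incidence=incidence,
        point_prevalence=point_prevalence,
        cumulative_stall_duration=cumulative,
        n_capillaries_total=int(n_capillaries_total),
        n_capillaries_stalling=n_stalling,
        no_stalls=no_stalls,
    )


def filter_min_duration(stallogram: Stallogram, min_frames) -> Stallogram:
    """Remove stall events shorter than ``min_frames`` frames.

    ``min_frames=2`` keeps every stall (no detected event is shorter); at the
    default frame period, ``min_frames=5`` keeps only stalls of ~8.8 s or
    longer — the regime a slower angiography modality can see.
    """
    if min_frames < 2:
        raise ValidationError("min_frames must be >= 2 (2 keeps all stalls)")
    matrix = np.zeros_like(stallogram.matrix)
    row = {cid: i for i, cid in enumerate(stallogram.capillary_ids)}
    for ev in extract_events(stallogram):
        if ev.duration_frames >= min_frames:
            matrix[row[ev.capillary_id], ev.start_frame : ev.end_frame + 1] = True
    return Stallogram(matrix, list(stallogram.capillary_ids), stallogram.frame_period)


def duration_cdf(events) -> DurationCDF:
    """Empirical CDF of event durations in seconds."""
    if len(events) == 0:
        raise ValidationError("duration_cdf needs at least one event")
    durations = np.sort([ev.duration_s for ev in events])
    unique, counts = np.unique(durations, return_counts=True)
    cdf = np.cumsum(counts) / len(durations)
    return DurationCDF(unique, cdf)


def incidence_vs_time(stallogram: Stallogram, t_grid_min) -> np.ndarray:
    """Incidence (%) using only the first ``t`` minutes of the record.

    The value at ``t`` counts capillaries with at least one stalled frame
    among frames ``[0, floor(t / frame_period))``; the curve is
    non-decreasing and reaches the overall incidence at the full record
    length.
    """
    t_grid_min = np.asarray(t_grid_min, dtype=float)
    if np.any(t_grid_min < 0):
        raise ValidationError("t grid must be non-negative")
    n_total = stallogram.n_capillaries
    if n_total == 0:
        raise ValidationError("stallogram has no capillaries")
    cum = np.cumsum(stallogram.matrix, axis=1) > 0  # stalled within first k+1 frames
    out = np.empty_like(t_grid_min)
    for j, t in enumerate(t_grid_min):
        k = int(np.floor(t * 60.0 / stallogram.frame_period))
        k = min(k, stallogram.n_frames)
        out[j] = 0.0 if k == 0 else 100.0 * cum[:, k - 1].sum() / n_total
    return out


def exponential_model(t_min, A, B, C):
    """Saturating incidence model ``A (1 - exp(-B t)) + C``, t in minutes."""
    return A * (1.0 - np.exp(-B * np.asarray(t_min, dtype=float))) + C


_FLAT_TOL = 1e-12


def fit_exponential(t_min, incidence, init=(1.0, 1.0, 0.0)) -> ExponentialFit:
    """Nonlinear least-squares fit of the saturating incidence model.

    Runs a small multi-start (the caller's ``init`` plus two data-driven
    guesses) and returns the converged solution with the lowest residual
    norm.  A constant curve is reported as ``A ~ 0, C ~ mean`` with the rate
    flagged unidentifiable.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(incidence, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("t and incidence must be 1D arrays of equal length")
    if len(t) < 4:
        raise ValidationError("fit needs at least 4 points")

    span = float(y.max() - y.min())
    t_scale = max(float(t.max()), 1e-6)
    starts = [
        tuple(init),
        (max(span, 1e-3), 2.0 / t_scale, float(y.min())),
        (max(float(y.max()), 1e-3), 5.0, 0.0),
    ]

    def residuals(p):
        return exponential_model(t, *p) - y

    results = [
        least_squares(
            residuals,
            p0,
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=10_000,
        )
        for p0 in starts
    ]
    converged = [r for r in results if r.success]
    if not converged:
        last = min(results, key=lambda r: r.cost)
        raise FitError(
            "exponential fit did not converge",
            params=tuple(last.x),
            residual_norm=float(np.linalg.norm(residuals(last.x))),
        )
    best = min(converged, key=lambda r: r.cost)

    A, B, C = best.x
    # a flat curve leaves B unidentifiable: report the degenerate convention
    b_unid = span <= max(1e-9, 1e-9 * max(abs(float(y.mean())), 1.0)) or abs(A) < 1e-9
    if b_unid and span <= 1e-9:
        A, C = 0.0, float(y.mean())
    return ExponentialFit(
        A=float(A),
        B=float(B),
        C=float(C),
        residual_norm=float(np.linalg.norm(residuals((A, B, C)))),
        converged=bool(best.success),
        b_unidentifiable=bool(b_unid),
    )


def confusion_rates(tp, fp, tn, fn):
    """Sensitivity, specificity and truth-table row percentages from counts.

    Rows with a zero denominator report ``nan`` rates and set the
    ``undefined`` flag.
    """
    for v in (tp, fp, tn, fn):
        if v < 0:
            raise ValidationError("counts must be non-negative")
    pos, neg = tp + fn, tn + fp
    out = {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "n_positive": pos,
        "n_negative": neg,
        "sensitivity_pct": 100.0 * tp / pos if pos else float("nan"),
        "false_negative_rate_pct": 100.0 * fn / pos if pos else float("nan"),
        "specificity_pct": 100.0 * tn / neg if neg else float("nan"),
        "false_positive_rate_pct": 100.0 * fp / neg if neg else float("nan"),
        "undefined": pos == 0 or neg == 0,
    }
    return out
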