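"""Shared data containers for the stall-analysis pipeline.

Conventions used throughout the package:

* images are ``(row, column)`` numpy arrays; points are ``(x, y)`` with
  ``x = column`` and ``y = row``, 0-based;
* time is the leading axis of every stack or trace;
* a *stall* spans at least two consecutive frames — the shortest event the
  frame-pair correlation can witness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "ImageTimeSeries",
    "Centerline",
    "VesselGraph",
    "GraphEdge",
    "GraphNode",
    "LTImage",
    "CorrelationTrace",
    "StallEvent",
    "Stallogram",
    "StallStatistics",
    "ConfusionTable",
    "ExponentialFit",
    "DurationCDF",
    "DiameterTrace",
    "DilationEvent",
    "TriggeredAverage",
    "GroundTruth",
]


@dataclass
class ImageTimeSeries:
    """A 2D+time grayscale stack.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of non-negative intensities.
    frame_period
        Seconds between consecutive frames.
    pixel_size
        Microns per pixel (isotropic).
    """

    frames: np.ndarray
    frame_period: float
    pixel_size: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValidationError("an image time series needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("frame intensities must be finite")
        if self.frame_period <= 0 or self.pixel_size <= 0:
            raise ValidationError("frame_period and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape


@dataclass
class Centerline:
    """Ordered path of points along one capillary."""

    capillary_id: object
    points: np.ndarray  # (N, 2) as (x, y)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("centerline points must be an (N, 2) array of (x, y)")

    @property
    def length_px(self) -> int:
        return len(self.points)


@dataclass
class GraphNode:
    id: int
    x: int
    y: int


@dataclass
class GraphEdge:
    id: int
    node_a: int
    node_b: int
    path: np.ndarray  # (N, 2) int (x, y); starts at node_a's pixel, ends at node_b's


@dataclass
class VesselGraph:
    """Skeleton graph: junction/endpoint pixels as nodes, traced paths as edges."""

    nodes: list[GraphNode] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class LTImage:
    """Length-time image: intensity along a centerline, frame by frame.

    ``values[t, i]`` is the intensity of frame ``t`` sampled at centerline
    point ``i`` (after motion correction).  ``offsets[t]`` is the (dx, dy)
    translation applied to the centerline at frame ``t``.
    """

    capillary_id: object
    values: np.ndarray  # (T, L)
    offsets: np.ndarray  # (T, 2)
    frame_period: float
    n_out_of_bounds: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("LT values must be 2D (frames x length)")
        if len(self.offsets) != len(self.values):
            raise ValidationError("one offset per frame required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("LT values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationTrace:
    """Frame-to-frame Pearson correlation of LT rows.

    ``r[t]`` correlates rows ``t`` and ``t+1``; a pair in which either row has
    zero variance contributes ``r = 0`` and sets the matching ``degenerate``
    flag, since a featureless row carries no evidence either way.
    """

    capillary_id: object
    r: np.ndarray  # (T-1,)
    degenerate: np.ndarray  # (T-1,) bool
    frame_period: float

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if self.r.ndim != 1 or self.degenerate.shape != self.r.shape:
            raise ValidationError("r and degenerate must be 1D of equal length")
        if not np.all(np.isfinite(self.r)):
            raise ValidationError("correlation values must be finite")


@dataclass(frozen=True)
class StallEvent:
    """One maximal stall interval on one capillary (frames inclusive)."""

    capillary_id: object
    start_frame: int
    end_frame: int
    frame_period: float

    def __post_init__(self):
        if self.end_frame < self.start_frame + 1:
            raise ValidationError(
                f"stall events span >= 2 frames; got [{self.start_frame}, {self.end_frame}]"
            )

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def duration_s(self) -> float:
        return self.duration_frames * self.frame_period


@dataclass
class Stallogram:
    """Boolean capillaries x frames matrix marking stalled frames."""

    matrix: np.ndarray  # (n_capillaries, T) bool
    capillary_ids: list
    frame_period: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ValidationError("stallogram matrix must be 2D")
        if len(self.capillary_ids) != self.matrix.shape[0]:
            raise ValidationError("one capillary id per stallogram row required")
        if len(set(self.capillary_ids)) != len(self.capillary_ids):
            raise ValidationError("capillary ids must be unique")

    @property
    def n_capillaries(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class StallStatistics:
    """Summary stall metrics, all on a 0-100 percent scale.

    incidence
        Percent of all counted capillaries with at least one stall.
    point_prevalence
        Time-average over frames of the percent of capillaries stalled.
    cumulative_stall_duration
        Mean over *stalling* capillaries of the percent of the record each
        spends stalled (0, flagged, when nothing stalls).
    """

    incidence: float
    point_prevalence: float
    cumulative_stall_duration: float
    n_capillaries_total: int
    n_capillaries_stalling: int
    no_stalls: bool = False
    cumulative_units: str = "percent"


@dataclass
class ConfusionTable:
    """Validation truth-table counts with derived rates (percent)."""

    tp: int
    fp: int
    tn: int
    fn: int
    level: str = "capillary"

    def __post_init__(self):
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValidationError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return float("nan") if pos == 0 else 100.0 * self.tp / pos

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return float("nan") if neg == 0 else 100.0 * self.tn / neg


@dataclass
class ExponentialFit:
    """Least-squares fit of I(t) = A(1 - exp(-B t)) + C, t in minutes."""

    A: float
    B: float
    C: float
    residual_norm: float
    converged: bool
    b_unidentifiable: bool = False

    @property
    def params(self):
        return (self.A, self.B, self.C)


@dataclass
class DurationCDF:
    """Empirical CDF of stall-event durations (seconds)."""

    durations_s: np.ndarray  # sorted unique durations
    cdf: np.ndarray  # cumulative fraction at each duration


@dataclass
class DiameterTrace:
    """Per-frame vessel diameter (um) from the FWHM estimator; NaN when the
    profile never bracketed half-maximum on one side (flagged)."""

    values: np.ndarray
    method: str = "FWHM"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] <= 0):
                raise ValidationError("diameters must be positive where defined")

    @property
    def n_undefined(self) -> int:
        return int(np.sum(~np.isfinite(self.values)))


@dataclass(frozen=True)
class DilationEvent:
    peak_frame: int
    amplitude_frac: float


@dataclass
class TriggeredAverage:
    """Event-triggered average of a per-frame trace around dilation peaks."""

    lags: np.ndarray  # frames relative to peak; 0 = peak diameter
    mean: np.ndarray
    sem: np.ndarray
    n_events: int


@dataclass
class GroundTruth:
    """Everything the simulator knows about a synthetic dataset."""

    centerlines: list  # of Centerline
    stallogram: Stallogram
    stall_events: list  # of StallEvent
    motion_offsets: np.ndarray  # (T, 2) as (dx, dy), pixels
    artery_diameter: np.ndarray | None = None  # per-frame um
    dilation_events: list | None = None  # peak frame indices
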