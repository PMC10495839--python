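"""Configuration objects for simulation and analysis.

Defaults mirror the acquisition the pipeline was designed around: 512x512
pixel frames covering 713x713 um (1.393 um/px) recorded at 0.57 Hz
(frame period 1.754 s) for 350 frames (~10 min).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: default acquisition geometry/timing
DEFAULT_PIXEL_SIZE_UM = 713.0 / 512.0
DEFAULT_FRAME_PERIOD_S = 1.0 / 0.57
DEFAULT_N_FRAMES = 350

_DURATION_FAMILIES = ("geometric", "fixed")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic angiogram generator.

    Stall behaviour is a per-capillary two-state renewal process: flowing
    intervals end after an exponential waiting time (``stall_onset_rate``
    events per minute), stalls last for a draw from ``stall_duration_dist``
    (frames, minimum 2).  Only a ``stalling_fraction`` of capillaries is
    eligible to stall at all.
    """

    height_px: int = 512
    width_px: int = 512
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM  # um / pixel
    n_frames: int = DEFAULT_N_FRAMES
    frame_period: float = DEFAULT_FRAME_PERIOD_S  # s
    n_capillaries: int = 30
    capillary_width: float = 4.0  # um, lumen FWHM
    capillary_length_px: tuple = (180, 260)  # min/max path length, pixels
    shadow_density: float = 5.0  # RBC shadows per 100 um
    shadow_speed: float = 1000.0  # um/s while flowing (>> length/frame)
    shadow_depth: float = 0.6  # fractional dip of one shadow
    stall_onset_rate: float = 0.4  # onsets per capillary per minute
    stall_duration_dist: tuple = ("geometric", {"p": 0.35})  # frames, min 2
    stalling_fraction: float = 0.5
    noise_sd: float = 0.25  # additive, in units of lumen brightness (=1)
    motion_amplitude: float = 1.0  # px, peak rigid drift
    include_artery: bool = False
    artery_diameter_baseline: float = 25.0  # um
    dilation_amplitude_frac: float = 0.2
    coupling_gain: float = 1.0  # dF/F per fractional diameter change
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.stall_duration_dist, list):
            self.stall_duration_dist = tuple(self.stall_duration_dist)
        if isinstance(self.capillary_length_px, list):
            self.capillary_length_px = tuple(self.capillary_length_px)
        for name in ("height_px", "width_px", "n_frames"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "pixel_size",
            "frame_period",
            "capillary_width",
            "artery_diameter_baseline",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "shadow_density",
            "shadow_speed",
            "shadow_depth",
            "stall_onset_rate",
            "noise_sd",
            "motion_amplitude",
            "dilation_amplitude_frac",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_capillaries < 0:
            raise ConfigurationError("n_capillaries must be >= 0")
        if not 0.0 <= self.stalling_fraction <= 1.0:
            raise ConfigurationError("stalling_fraction must lie in [0, 1]")
        if self.coupling_gain < 0:
            raise ConfigurationError("coupling_gain must be non-negative")
        family, params = self.stall_duration_dist
        if family not in _DURATION_FAMILIES:
            raise ConfigurationError(
                f"unknown stall duration family {family!r}; choose from {_DURATION_FAMILIES}"
            )
        if family == "geometric" and not 0.0 < params.get("p", 0) <= 1.0:
            raise ConfigurationError("geometric duration needs 0 < p <= 1")
        if family == "fixed" and params.get("frames", 0) < 2:
            raise ConfigurationError("fixed duration needs frames >= 2")
        lo, hi = self.capillary_length_px
        if not (0 < lo <= hi):
            raise ConfigurationError("capillary_length_px must be (min, max) with 0 < min <= max")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        return cls.from_dict(_load_mapping(path))


@dataclass
class AnalysisConfig:
    """Parameters of the analysis pipeline (centerlines through statistics)."""

    frame_period_s: float = DEFAULT_FRAME_PERIOD_S
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    correlation_threshold: float = 0.4  # intentionally low: sensitivity first
    adaptive_threshold: bool = False  # per-capillary mean + 2 SD instead
    lt_smoothing_px: float = 0.0  # along-length matched-filter sigma; 0 = off
    lt_band_halfwidth_px: float = 1.0  # transverse averaging band half-width
    lt_band_lines: int = 1  # paths averaged across the band; 1 = centerline only
    lt_detrend: bool = True  # subtract per-column temporal mean before correlating
    min_stall_frames: int = 2  # 2 keeps every detected stall
    vesselness_scales: tuple = (1.0, 2.0, 3.0, 4.0)  # px
    segmentation_threshold: float | None = None  # None -> Otsu on vesselness
    max_click_distance_px: float = 20.0
    registration_margin_px: int = 10
    registration_search_px: int = 6
    dilation_amplitude_frac_min: float = 0.1
    dilation_isolation_frames: int = 10
    triggered_window_frames: int = 10
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.vesselness_scales, list):
            self.vesselness_scales = tuple(self.vesselness_scales)
        for name in ("frame_period_s", "pixel_size_um", "max_click_distance_px"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not -1.0 < self.correlation_threshold < 1.0:
            raise ConfigurationError("correlation_threshold must lie in (-1, 1)")
        if self.min_stall_frames < 2:
            raise ConfigurationError("min_stall_frames must be >= 2 (a stall spans 2 frames)")
        if len(self.vesselness_scales) == 0 or any(s <= 0 for s in self.vesselness_scales):
            raise ConfigurationError("vesselness_scales must be non-empty and positive")
        if self.segmentation_threshold is not None and not 0.0 <= self.segmentation_threshold <= 1.0:
            raise ConfigurationError("segmentation_threshold must lie in [0, 1]")
        if self.lt_smoothing_px < 0:
            raise ConfigurationError("lt_smoothing_px must be non-negative")
        if self.lt_band_halfwidth_px < 0 or self.lt_band_lines < 1:
            raise ConfigurationError("LT band parameters must be sensible")
        if self.registration_margin_px < 0 or self.registration_search_px < 1:
            raise ConfigurationError("registration margin/search must be sensible")
        if self.dilation_isolation_frames < 0 or self.triggered_window_frames < 1:
            raise ConfigurationError("dilation windows must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        return cls.from_dict(_load_mapping(path))


def _load_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} must contain a mapping")
    return data
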