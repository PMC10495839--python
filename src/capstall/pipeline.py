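"""End-to-end orchestration: simulate -> centerlines -> LT -> detect -> stats.

These functions are the library behind the CLI's ``run-all`` and are what the
validation tests drive.  Each stage consumes and produces the package's
domain objects; file I/O lives in :mod:`capstall.io`.
"""

from __future__ import annotations

import logging

import numpy as np

from . import io as cio
from .config import AnalysisConfig, SimulationConfig
from .errors import RegistrationDegenerateError
from .kymograph import detrend_lt, extract_lt_for_centerline, smooth_lt
from .simulate import simulate_angiogram
from .stalldetect import (
    adaptive_threshold_value,
    compare_to_truth,
    events_to_stallogram,
    frame_correlation,
    threshold_correlation,
)
from .stallstats import compute_statistics, extract_events, filter_min_duration
from .vesselgraph import extract_centerlines

logger = logging.getLogger(__name__)

__all__ = ["midpoint_clicks", "detect_stalls", "analyze_stack", "run_all"]


def midpoint_clicks(centerlines):
    """One click at the midpoint of each centerline (label = capillary id)."""
    return [
        (c.capillary_id, float(c.points[len(c.points) // 2, 0]), float(c.points[len(c.points) // 2, 1]))
        for c in centerlines
    ]


def detect_stalls(series, centerlines, config: AnalysisConfig, capillary_ids=None):
    """LT extraction + correlation thresholding for a set of centerlines.

    Returns ``(stallogram, events, traces)``.  ``capillary_ids`` fixes the
    stallogram's row set (capillaries without a centerline get all-false
    rows), defaulting to the centerline ids.
    """
    if capillary_ids is None:
        capillary_ids = [c.capillary_id for c in centerlines]
    events = []
    traces = {}
    for cline in centerlines:
        try:
            lt = extract_lt_for_centerline(
                series,
                cline,
                margin_px=config.registration_margin_px,
                search_px=config.registration_search_px,
                band_halfwidth_px=config.lt_band_halfwidth_px,
                band_lines=config.lt_band_lines,
            )
        except RegistrationDegenerateError:
            logger.warning("stage=detect capillary=%s registration degenerate; skipped", cline.capillary_id)
            continue
        prepared = smooth_lt(lt, config.lt_smoothing_px)
        if config.lt_detrend:
            prepared = detrend_lt(prepared)
        trace = frame_correlation(prepared)
        traces[cline.capillary_id] = trace
        thr = (
            adaptive_threshold_value(trace)
            if config.adaptive_threshold
            else config.correlation_threshold
        )
        events.extend(threshold_correlation(trace, thr))
    stallogram = events_to_stallogram(
        events, capillary_ids, series.n_frames, frame_period=series.frame_period
    )
    if config.min_stall_frames > 2:
        stallogram = filter_min_duration(stallogram, config.min_stall_frames)
        events = extract_events(stallogram)
    logger.info(
        "stage=detect capillaries=%d events=%d", len(centerlines), len(events)
    )
    return stallogram, events, traces


def analyze_stack(series, clicks, config: AnalysisConfig):
    """Clicks to predicted stallogram and statistics on one stack."""
    mean_image = series.frames.mean(axis=0)
    centerlines, missed = extract_centerlines(
        mean_image,
        clicks,
        scales_px=config.vesselness_scales,
        segmentation_threshold=config.segmentation_threshold,
        max_click_distance=config.max_click_distance_px,
    )
    if missed:
        logger.warning("stage=centerlines missed_clicks=%d", len(missed))
    logger.info("stage=centerlines selected=%d", len(centerlines))
    all_ids = [label for label, _, _ in clicks]
    stallogram, events, traces = detect_stalls(series, centerlines, config, capillary_ids=all_ids)
    statistics = compute_statistics(stallogram, n_capillaries_total=len(all_ids))
    return {
        "centerlines": centerlines,
        "missed": missed,
        "stallogram": stallogram,
        "events": events,
        "traces": traces,
        "statistics": statistics,
    }


def run_all(sim_config: SimulationConfig, analysis_config: AnalysisConfig, out_dir, write_stack_file=True):
    """Simulate a stack, analyze it blind, and validate against ground truth.

    Writes the full file bundle into ``out_dir`` and returns a summary dict
    (stallograms, statistics, confusion table).
    """
    series, truth = simulate_angiogram(sim_config)
    logger.info(
        "stage=simulate frames=%d capillaries=%d events=%d",
        series.n_frames,
        sim_config.n_capillaries,
        len(truth.stall_events),
    )
    clicks = midpoint_clicks(truth.centerlines)
    result = analyze_stack(series, clicks, analysis_config)
    confusion = compare_to_truth(result["stallogram"], truth.stallogram)
    truth_stats = compute_statistics(truth.stallogram)
    if out_dir is not None:
        if write_stack_file:
            cio.write_stack(series, f"{out_dir}/stack.tif")
        cio.write_ground_truth(truth, out_dir)
        cio.write_clicks(clicks, f"{out_dir}/clicks.csv")
        cio.write_centerlines(result["centerlines"], f"{out_dir}/centerlines.csv")
        cio.write_results(
            result["stallogram"], result["events"], result["statistics"], confusion, out_dir
        )
        cio.write_json(
            {
                "truth_statistics": truth_stats,
                "predicted_statistics": result["statistics"],
                "sensitivity_pct": confusion.sensitivity,
                "specificity_pct": confusion.specificity,
            },
            f"{out_dir}/summary.json",
        )
    logger.info(
        "stage=validate sensitivity=%.1f%% specificity=%.1f%%",
        confusion.sensitivity,
        confusion.specificity,
    )
    return {
        "series": series,
        "truth": truth,
        "confusion": confusion,
        "truth_statistics": truth_stats,
        **result,
    }
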