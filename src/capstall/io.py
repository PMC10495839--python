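"""File formats: TIFF stacks, clicks, stallograms, events, statistics.

All CSV outputs use 0-based pixel and frame indices with ``x = column`` and
``y = row``; headers state the convention.  Numeric JSON fields are written
at full precision and with sorted keys so that re-running an analysis
produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError
from .types import Centerline, ImageTimeSeries, StallEvent, Stallogram

__all__ = [
    "read_stack",
    "write_stack",
    "read_clicks",
    "write_clicks",
    "write_centerlines",
    "read_centerlines",
    "write_stallogram",
    "read_stallogram",
    "write_events",
    "read_events",
    "write_results",
    "write_ground_truth",
]


# ---------------------------------------------------------------------------
# image stacks


def read_stack(path, frame_period=None, pixel_size=None) -> ImageTimeSeries:
    """Read a multi-page TIFF (or a directory of numbered single-page TIFFs).

    ``frame_period`` / ``pixel_size`` default to metadata embedded by
    :func:`write_stack` when present; explicit arguments win.
    """
    path = Path(path)
    meta = {}
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: p.name,
        )
        if not files:
            raise FormatError(f"no TIFF files in {path}")
        pages = []
        for f in files:
            arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise FormatError(f"{f} is not a single-page 2D TIFF")
            pages.append(arr)
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise FormatError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        frames = np.stack(pages)
        meta = _read_meta(files[0])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            raise ValidationError(f"{path} holds a single frame; a time series needs >= 2")
        if frames.ndim != 3:
            raise FormatError(f"{path} is not a 2D time series (shape {frames.shape})")
        meta = _read_meta(path)
    if frames.shape[0] < 2:
        raise ValidationError(f"{path} holds {frames.shape[0]} frame(s); need >= 2")
    frame_period = frame_period if frame_period is not None else meta.get("frame_period", 1.0)
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size", 1.0)
    return ImageTimeSeries(frames, frame_period, pixel_size)


def _read_meta(path) -> dict:
    try:
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
        data = json.loads(desc)
        return data if isinstance(data, dict) else {}
    except (Exception):
        return {}


def write_stack(series: ImageTimeSeries, path, as_uint16=False, uint16_scale=10000.0):
    """Write a stack as a multi-page TIFF, one page per frame.

    The native dtype (float32 for simulated stacks) is preserved by default so
    write/read round trips are bit-exact; ``as_uint16=True`` quantizes to
    16-bit grayscale with the given intensity scale for export to external
    viewers.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = series.frames
    if as_uint16:
        frames = np.clip(frames * uint16_scale, 0, 65535).astype(np.uint16)
    meta = json.dumps(
        {"frame_period": series.frame_period, "pixel_size": series.pixel_size},
        sort_keys=True,
    )
    tifffile.imwrite(path, frames, description=meta, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# clicks and centerlines


def write_clicks(clicks, path):
    """Clicks CSV: capillary_label, x_px, y_px (0-based; x = column)."""
    df = pd.DataFrame(clicks, columns=["capillary_label", "x_px", "y_px"])
    df.to_csv(path, index=False)
    return Path(path)


def read_clicks(path):
    df = pd.read_csv(path)
    required = {"capillary_label", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise FormatError(f"clicks file {path} must have columns {sorted(required)}")
    return [(row.capillary_label, float(row.x_px), float(row.y_px)) for row in df.itertuples()]


def write_centerlines(centerlines, path):
    """Centerlines CSV: capillary_id, point_index, x_px, y_px (0-based)."""
    records = [
        (c.capillary_id, i, x, y)
        for c in centerlines
        for i, (x, y) in enumerate(c.points)
    ]
    df = pd.DataFrame(records, columns=["capillary_id", "point_index", "x_px", "y_px"])
    df.to_csv(path, index=False)
    return Path(path)


def read_centerlines(path):
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("capillary_id", sort=True):
        grp = grp.sort_values("point_index")
        out.append(Centerline(cid, np.column_stack([grp.x_px.values, grp.y_px.values])))
    return out


# ---------------------------------------------------------------------------
# stallograms, events, statistics


def write_stallogram(stallogram: Stallogram, path):
    """Stallogram CSV: rows = capillaries, columns = frame indices, values 0/1."""
    df = pd.DataFrame(
        stallogram.matrix.astype(int),
        index=pd.Index(stallogram.capillary_ids, name="capillary_id"),
        columns=[f"frame_{t}" for t in range(stallogram.n_frames)],
    )
    df.to_csv(path)
    return Path(path)


def read_stallogram(path, frame_period) -> Stallogram:
    df = pd.read_csv(path, index_col="capillary_id")
    return Stallogram(df.values.astype(bool), list(df.index), frame_period)


def write_events(events, path):
    """Events CSV: capillary_id, start_frame, end_frame (inclusive), duration_s."""
    records = [
        (ev.capillary_id, ev.start_frame, ev.end_frame, ev.duration_s) for ev in events
    ]
    df = pd.DataFrame(
        records, columns=["capillary_id", "start_frame", "end_frame", "duration_s"]
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_events(path, frame_period):
    df = pd.read_csv(path)
    return [
        StallEvent(row.capillary_id, int(row.start_frame), int(row.end_frame), frame_period)
        for row in df.itertuples()
    ]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_json(obj, path):
    path = Path(path)
    path.write_text(json.dumps(_to_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def write_results(stallogram, events, statistics, confusion, out_dir):
    """Write the standard result bundle into ``out_dir``.

    Produces ``stallogram.csv``, ``events.csv``, ``statistics.json`` and (when
    a confusion table is given) ``confusion.json``; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stallogram": write_stallogram(stallogram, out_dir / "stallogram.csv"),
        "events": write_events(events, out_dir / "events.csv"),
        "statistics": write_json(statistics, out_dir / "statistics.json"),
    }
    if confusion is not None:
        extra = dict(_to_jsonable(confusion))
        if hasattr(confusion, "sensitivity"):
            extra["sensitivity_pct"] = confusion.sensitivity
            extra["specificity_pct"] = confusion.specificity
        paths["confusion"] = write_json(extra, out_dir / "confusion.json")
    return paths


def write_ground_truth(truth, out_dir):
    """Ground truth bundle: events/offsets JSON + stallogram and centerline CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stallogram": write_stallogram(truth.stallogram, out_dir / "truth_stallogram.csv"),
        "centerlines": write_centerlines(truth.centerlines, out_dir / "truth_centerlines.csv"),
        "events": write_events(truth.stall_events, out_dir / "truth_events.csv"),
    }
    payload = {
        "motion_offsets": truth.motion_offsets,
        "artery_diameter_um": truth.artery_diameter,
        "dilation_peak_frames": truth.dilation_events,
    }
    paths["meta"] = write_json(payload, out_dir / "truth.json")
    return paths
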