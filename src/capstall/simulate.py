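"""Synthetic angiogram generator with exact ground truth.

The simulator emulates what a Bessel-beam two-photon angiogram of cortical
capillaries looks like at low volume rate: bright curvilinear capillaries on a
dim background, dark red-blood-cell (RBC) shadows that occlude the fluorescent
plasma, rigid tissue drift, and additive detector noise.  Because RBCs move at
mm/s while frames arrive every ~1.75 s, a flowing capillary shows a completely
new shadow pattern in every frame; during a stall the very same shadows sit in
the very same place for two or more consecutive frames.  The simulator makes
that dichotomy literal: flowing frames redraw shadow positions independently,
stalled frames freeze them.

Stall timing is a per-capillary two-state renewal process — exponential
waiting time to stall onset, configurable stall-duration distribution
(minimum two frames) — applied to a configurable fraction of capillaries.

Capillary geometry is a set of quasi-parallel smooth lanes with a guaranteed
minimum separation of three capillary widths, a deliberate idealization that
keeps centerline-extraction tests free of crossing artifacts.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse
from scipy.spatial import cKDTree

from .config import SimulationConfig
from .errors import ConfigurationError, ValidationError
from .types import Centerline, GroundTruth, ImageTimeSeries, StallEvent, Stallogram

__all__ = [
    "simulate_angiogram",
    "simulate_stallogram",
    "simulate_kymograph",
    "simulate_artery",
    "sample_stall_intervals",
]

BACKGROUND_LEVEL = 0.08  # extravascular fluorescence, lumen brightness = 1
SHADOW_SIGMA_UM = 3.0  # ~RBC radius; dark dips are 1D Gaussians of this sigma
_EDGE_SOFTNESS_PX = 1.0  # erf edge width of the rendered artery band
_FIELD_MARGIN_PX = 12


# ---------------------------------------------------------------------------
# stall renewal process


def _duration_sampler(dist):
    family, params = dist
    if family == "geometric":
        p = params["p"]
        # 1 + Geom(p) >= 2 frames, mean 1 + 1/p
        return lambda rng: 1 + int(rng.geometric(p))
    if family == "fixed":
        frames = int(params["frames"])
        return lambda rng: frames
    raise ConfigurationError(f"unknown duration family {family!r}")


def sample_stall_intervals(rng, n_frames, frame_period, onset_rate_per_min, duration_sampler):
    """Draw stall intervals for one capillary from the two-state renewal process.

    Returns a list of ``(start_frame, end_frame)`` inclusive intervals, each
    spanning >= 2 frames, separated by >= 1 flowing frame so that stallogram
    runs and events remain in bijection.
    """
    events = []
    lam = onset_rate_per_min / 60.0  # onsets per second while flowing
    if lam <= 0:
        return events
    total = n_frames * frame_period
    t = 0.0
    while True:
        t += rng.exponential(1.0 / lam)
        if t >= total:
            break
        start = int(t // frame_period)
        if start > n_frames - 2:
            break
        dur = max(2, duration_sampler(rng))
        end = min(start + dur - 1, n_frames - 1)
        events.append((start, end))
        # one-frame refractory period keeps consecutive events distinct runs
        t = (end + 2) * frame_period
    return events


def simulate_stallogram(config: SimulationConfig, rng=None):
    """Sample ground-truth stall timing only (no rendering).

    Returns ``(stallogram, events, eligible)`` where ``eligible`` is the
    boolean per-capillary stall-eligibility mask.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, T = config.n_capillaries, config.n_frames
    sampler = _duration_sampler(config.stall_duration_dist)
    eligible = np.zeros(n, dtype=bool)
    n_eligible = int(round(config.stalling_fraction * n))
    if n_eligible:
        eligible[rng.choice(n, size=n_eligible, replace=False)] = True
    matrix = np.zeros((n, T), dtype=bool)
    events = []
    for cap in range(n):
        if not eligible[cap]:
            continue
        for start, end in sample_stall_intervals(
            rng, T, config.frame_period, config.stall_onset_rate, sampler
        ):
            matrix[cap, start : end + 1] = True
            events.append(StallEvent(cap, start, end, config.frame_period))
    gram = Stallogram(matrix, list(range(n)), config.frame_period)
    return gram, events, eligible


# ---------------------------------------------------------------------------
# geometry


def _make_centerlines(rng, config: SimulationConfig):
    """Quasi-parallel capillary lanes with guaranteed minimum separation."""
    n = config.n_capillaries
    if n == 0:
        return []
    H, W = config.height_px, config.width_px
    m = _FIELD_MARGIN_PX
    width_px = config.capillary_width / config.pixel_size
    min_sep = 3.0 * width_px
    lo, hi = config.capillary_length_px
    lmax = min(hi, min(H, W) - 2 * m - 4)
    lmin = min(lo, lmax)

    # a shared near-axis direction; lanes are parallel so the minimum
    # separation can be guaranteed even at high capillary counts
    max_tilt = 0.15  # rad
    base = 0.0 if rng.uniform() < 0.5 else np.pi / 2.0
    theta = base + rng.uniform(-max_tilt, max_tilt)
    u = np.array([np.cos(theta), np.sin(theta)])
    v = np.array([-np.sin(theta), np.cos(theta)])
    c0 = np.array([(W - 1) / 2.0, (H - 1) / 2.0])

    # normal-axis span available once tilt, wiggle and margin are budgeted
    max_wiggle = 2.0
    half_span = 0.5 * min(H, W) - m - 0.5 * lmax * np.sin(max_tilt) - max_wiggle - 2
    span = 2.0 * half_span
    if span <= 0 or (n > 1 and span / (n - 1) < min_sep):
        raise ConfigurationError(
            f"{n} capillaries need separation {min_sep:.1f} px but only "
            f"{max(span, 0):.0f} px of field are available"
        )
    spacing = span / max(n - 1, 1)
    wiggle_amp = (
        float(np.clip((spacing - min_sep) / 2.0 - 0.3, 0.0, max_wiggle)) if n > 1 else max_wiggle
    )

    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
    offsets = offsets + rng.uniform(-0.15, 0.15, n) * min(spacing, 1.0)
    rng.shuffle(offsets)

    centerlines = []
    for cap in range(n):
        L = rng.uniform(lmin, lmax)
        n_pts = int(round(L)) + 1
        s = np.arange(n_pts, dtype=float)
        slack = max(
            (min(H, W) - 2 * m - L) / 2.0 - half_span * np.sin(max_tilt) - max_wiggle - 2,
            0.0,
        )
        shift = rng.uniform(-slack, slack)
        wavelength = rng.uniform(80.0, 150.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        wig = wiggle_amp * np.sin(2 * np.pi * s / wavelength + phase)
        along = s - L / 2.0 + shift
        pts = c0[None, :] + along[:, None] * u[None, :] + (offsets[cap] + wig)[:, None] * v[None, :]
        pts[:, 0] = np.clip(pts[:, 0], 2.0, W - 3.0)
        pts[:, 1] = np.clip(pts[:, 1], 2.0, H - 3.0)
        centerlines.append(Centerline(cap, pts))

    if n > 1:
        trees = [cKDTree(c.points) for c in centerlines]
        for i in range(n):
            for j in range(i + 1, n):
                d = trees[i].query(centerlines[j].points, k=1)[0].min()
                if d < min_sep - 1e-6:
                    raise ConfigurationError(
                        f"capillaries {i} and {j} violate the minimum separation"
                    )
    return centerlines


# ---------------------------------------------------------------------------
# shadow profiles


def _shadow_attenuation(s_grid, positions, depth, sigma_px):
    """Summed dark dips, clipped so the lumen never goes fully black."""
    if len(positions) == 0:
        return np.zeros_like(s_grid)
    d = s_grid[:, None] - positions[None, :]
    a = depth * np.exp(-(d**2) / (2.0 * sigma_px**2))
    return np.clip(a.sum(axis=1), 0.0, 0.9)


def _draw_shadow_positions(rng, length_px, density_per_100um, pixel_size):
    lam = density_per_100um / 100.0 * pixel_size  # shadows per pixel of arc
    n = rng.poisson(lam * length_px)
    return rng.uniform(0.0, length_px, n)


class _CapillaryRenderer:
    """Precomputed splat of one capillary: pixel footprint, tube profile and a
    sparse pixel-from-arc interpolation matrix."""

    def __init__(self, centerline, shape, width_px, brightness):
        H, W = shape
        pts = centerline.points
        self.brightness = brightness
        sigma_w = width_px / 2.355  # FWHM -> sigma
        radius = max(3.0 * sigma_w, 3.0)
        x0 = max(int(pts[:, 0].min() - radius) - 1, 0)
        x1 = min(int(pts[:, 0].max() + radius) + 2, W)
        y0 = max(int(pts[:, 1].min() - radius) - 1, 0)
        y1 = min(int(pts[:, 1].max() + radius) + 2, H)
        gx, gy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        tree = cKDTree(pts)
        dist, _ = tree.query(grid, k=1)
        keep = dist <= radius
        self.flat_idx = (grid[keep, 1].astype(int) * W + grid[keep, 0].astype(int))
        self.tube = np.exp(-(dist[keep] ** 2) / (2.0 * sigma_w**2))

        # normalized Gaussian weights mapping arc samples -> footprint pixels
        sigma_map = 1.0
        pairs = tree.query_ball_point(grid[keep], r=3.0 * sigma_map)
        rows, cols, vals = [], [], []
        for i, js in enumerate(pairs):
            if not js:
                continue
            js = np.asarray(js)
            d2 = ((grid[keep][i] - pts[js]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2.0 * sigma_map**2))
            w /= w.sum()
            rows.extend([i] * len(js))
            cols.extend(js.tolist())
            vals.extend(w.tolist())
        self.weights = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(keep.sum(), len(pts))
        )
        self.n_arc = len(pts)

    def splat_static(self, canvas_flat):
        canvas_flat[self.flat_idx] += self.brightness * self.tube

    def darken(self, frame_flat, attenuation):
        frame_flat[self.flat_idx] -= self.brightness * self.tube * (self.weights @ attenuation)


def _motion_offsets(rng, n_frames, amplitude):
    """Smooth rigid drift: low-pass filtered noise scaled to peak amplitude."""
    if amplitude <= 0:
        return np.zeros((n_frames, 2))
    raw = rng.standard_normal((n_frames, 2))
    smooth = ndimage.gaussian_filter1d(raw, sigma=8.0, axis=0, mode="nearest")
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth *= amplitude / peak
    return smooth


# ---------------------------------------------------------------------------
# main entry points


def simulate_angiogram(config: SimulationConfig, return_profiles: bool = False):
    """Render a synthetic capillary angiogram time series with ground truth.

    Returns ``(ImageTimeSeries, GroundTruth)``; with ``return_profiles=True``
    a third value maps capillary id to its ``(T, L)`` noise-free lumen profile
    along the centerline (the quantity LT extraction should recover).
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.height_px, config.width_px
    T = config.n_frames

    centerlines = _make_centerlines(rng, config)
    stallogram, events, _ = simulate_stallogram(config, rng)

    width_px = config.capillary_width / config.pixel_size
    sigma_s = SHADOW_SIGMA_UM / config.pixel_size
    brightness = 1.0 + 0.1 * rng.standard_normal(max(config.n_capillaries, 1))
    brightness = np.clip(brightness, 0.7, 1.3)

    renderers = [
        _CapillaryRenderer(c, (H, W), width_px, brightness[i])
        for i, c in enumerate(centerlines)
    ]

    static = np.full(H * W, BACKGROUND_LEVEL, dtype=float)
    for r in renderers:
        r.splat_static(static)

    artery = None
    if config.include_artery:
        artery = simulate_artery(config, rng=rng, render=True)

    offsets = _motion_offsets(rng, T, config.motion_amplitude)

    frames = np.empty((T, H, W), dtype=np.float32)
    frozen = [None] * len(renderers)  # cached attenuation during a stall
    profiles = {c.capillary_id: np.empty((T, r.n_arc)) for c, r in zip(centerlines, renderers)} if return_profiles else None

    for t in range(T):
        frame = static.copy()
        for i, (cline, rend) in enumerate(zip(centerlines, renderers)):
            if stallogram.matrix[i, t]:
                if frozen[i] is None:
                    pos = _draw_shadow_positions(
                        rng, rend.n_arc, config.shadow_density, config.pixel_size
                    )
                    frozen[i] = _shadow_attenuation(
                        np.arange(rend.n_arc, dtype=float), pos, config.shadow_depth, sigma_s
                    )
                att = frozen[i]
            else:
                frozen[i] = None
                pos = _draw_shadow_positions(
                    rng, rend.n_arc, config.shadow_density, config.pixel_size
                )
                att = _shadow_attenuation(
                    np.arange(rend.n_arc, dtype=float), pos, config.shadow_depth, sigma_s
                )
            rend.darken(frame, att)
            if return_profiles:
                profiles[cline.capillary_id][t] = rend.brightness * (1.0 - att)
        frame = frame.reshape(H, W)
        if artery is not None:
            frame = frame + artery.frames[t]
        dx, dy = offsets[t]
        if config.motion_amplitude > 0:
            # content moves by (+dx, +dy): sample the scene at shifted coords
            frame = ndimage.shift(frame, (dy, dx), order=1, mode="nearest")
        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd, frame.shape)
        frames[t] = np.clip(frame, 0.0, None)

    series = ImageTimeSeries(frames, config.frame_period, config.pixel_size)
    truth = GroundTruth(
        centerlines=centerlines,
        stallogram=stallogram,
        stall_events=events,
        motion_offsets=offsets,
        artery_diameter=None if artery is None else artery.diameter_um,
        dilation_events=None if artery is None else list(artery.peak_frames),
    )
    if return_profiles:
        return series, truth, profiles
    return series, truth


def simulate_kymograph(
    length_px,
    n_frames,
    stall_intervals,
    noise_sd,
    seed,
    *,
    shadow_density=None,
    shadow_depth=None,
    pixel_size=None,
):
    """Directly synthesize a length-time image with known stall intervals.

    Rows inside a stall interval repeat one frozen shadow profile (plus fresh
    noise); rows outside are independently redrawn shadow profiles.  Returns
    ``(lt, stalled)`` with ``lt`` of shape ``(n_frames, length_px)`` and
    ``stalled`` the boolean per-frame trace.
    """
    defaults = SimulationConfig()
    shadow_density = defaults.shadow_density if shadow_density is None else shadow_density
    shadow_depth = defaults.shadow_depth if shadow_depth is None else shadow_depth
    pixel_size = defaults.pixel_size if pixel_size is None else pixel_size
    if length_px < 1 or n_frames < 2:
        raise ValidationError("need length_px >= 1 and n_frames >= 2")

    intervals = sorted(tuple(map(int, iv)) for iv in stall_intervals)
    prev_end = -2
    for start, end in intervals:
        if start < 0 or end >= n_frames:
            raise ValidationError(f"interval ({start}, {end}) outside [0, {n_frames})")
        if end - start + 1 < 2:
            raise ValidationError(
                f"interval ({start}, {end}) spans a single frame; a stall needs >= 2"
            )
        if start <= prev_end:
            raise ValidationError("stall intervals must not overlap")
        prev_end = end

    rng = np.random.default_rng(seed)
    sigma_s = SHADOW_SIGMA_UM / pixel_size
    s = np.arange(length_px, dtype=float)
    stalled = np.zeros(n_frames, dtype=bool)
    for start, end in intervals:
        stalled[start : end + 1] = True

    lt = np.empty((n_frames, length_px))
    frozen = None
    for t in range(n_frames):
        if stalled[t]:
            if frozen is None:
                pos = _draw_shadow_positions(rng, length_px, shadow_density, pixel_size)
                frozen = 1.0 - _shadow_attenuation(s, pos, shadow_depth, sigma_s)
            row = frozen
        else:
            frozen = None
            pos = _draw_shadow_positions(rng, length_px, shadow_density, pixel_size)
            row = 1.0 - _shadow_attenuation(s, pos, shadow_depth, sigma_s)
        noise = rng.normal(0.0, noise_sd, length_px) if noise_sd > 0 else 0.0
        lt[t] = row + noise
    return lt, stalled


# ---------------------------------------------------------------------------
# arteriole dynamics


class ArterySimulation:
    """Output bundle of :func:`simulate_artery`."""

    def __init__(self, diameter_um, dff, frames, peak_frames):
        self.diameter_um = diameter_um
        self.dff = dff
        self.frames = frames
        self.peak_frames = peak_frames


_DILATION_SIGMA_FRAMES = 2.0
_DILATION_MEAN_SPACING_FRAMES = 60
_ARTERY_BRIGHTNESS = 1.2
_ARTERY_CENTER_X_PX = 40.0


def simulate_artery(config: SimulationConfig, rng=None, render=True, dff_noise_sd=0.01):
    """Simulate an arteriole whose fluorescence tracks its diameter.

    The diameter trace is a baseline plus Gaussian-in-time dilation bumps of
    fractional amplitude ``config.dilation_amplitude_frac``; the dF/F trace is
    ``coupling_gain`` times the fractional diameter change plus Gaussian noise
    of SD ``dff_noise_sd``.  With ``render=True`` the artery is drawn as a
    vertical band whose erf-edged width follows the diameter (so its FWHM *is*
    the diameter) and whose brightness is modulated by (1 + dF/F).
    """
    if not config.include_artery:
        raise ConfigurationError("simulate_artery requires include_artery=True")
    if config.coupling_gain < 0:
        raise ConfigurationError("coupling_gain must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    T = config.n_frames
    base = config.artery_diameter_baseline

    # isolated dilation peaks: jittered regular spacing, away from the edges
    peaks = []
    t = 0
    while True:
        t += int(rng.integers(_DILATION_MEAN_SPACING_FRAMES - 15, _DILATION_MEAN_SPACING_FRAMES + 15))
        if t >= T - 15:
            break
        peaks.append(t)
    peaks = np.asarray(peaks, dtype=int)

    tt = np.arange(T, dtype=float)
    diameter = np.full(T, base)
    if config.dilation_amplitude_frac > 0:
        for p in peaks:
            diameter += (
                base
                * config.dilation_amplitude_frac
                * np.exp(-((tt - p) ** 2) / (2.0 * _DILATION_SIGMA_FRAMES**2))
            )
    frac_change = (diameter - base) / base
    dff = config.coupling_gain * frac_change
    if dff_noise_sd > 0:
        dff = dff + rng.normal(0.0, dff_noise_sd, T)

    frames = None
    if render:
        W = config.width_px
        x = np.arange(W, dtype=float)
        half_w = 0.5 * diameter / config.pixel_size  # px
        from scipy.special import erf

        lo = (x[None, :] - (_ARTERY_CENTER_X_PX - half_w[:, None])) / (
            _EDGE_SOFTNESS_PX * np.sqrt(2.0)
        )
        hi = (x[None, :] - (_ARTERY_CENTER_X_PX + half_w[:, None])) / (
            _EDGE_SOFTNESS_PX * np.sqrt(2.0)
        )
        band = 0.5 * (erf(lo) - erf(hi))  # (T, W), 1 inside the band
        amp = _ARTERY_BRIGHTNESS * (1.0 + dff)
        rows = (amp[:, None] * band).astype(np.float32)
        # broadcast along the image height without materializing a copy
        frames = np.broadcast_to(rows[:, None, :], (T, config.height_px, W))
    return ArterySimulation(diameter, dff, frames, peaks)
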