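"""Permeability and dilation quantification.

Implements the ROI-trace arithmetic behind the leakage read-outs: per-frame
ROI means, per-timepoint background subtraction, baseline normalization to
the mean of the pre-shift window, time-integrated leakage (which evaluates
to exactly the window length, 3600 a.u.·s by default, for a leak-free
trace), apparent leakage rates, blockade effect sizes against the
theoretical baseline, kymograph construction, Otsu-binarized vessel
diameters, and onset/area metrics for high-molecular-weight tracer.

Normalization note: the baseline denominator is the *mean* of the baseline
window. Dividing by the baseline *sum* cannot yield the documented no-leak
value of 3600 (it would give 360 for a 10-frame baseline), so the mean
reading is the one implemented throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters
from skimage.measure import profile_line

from .stack import FrameStack

__all__ = [
    "ROISpec",
    "IntensityTrace",
    "NormalizedTrace",
    "Kymograph",
    "LeakageSummary",
    "extract_trace",
    "background_correct",
    "normalize_baseline",
    "integrate_leakage",
    "leakage_rate",
    "blockade_percent",
    "build_kymograph",
    "vessel_diameter",
    "max_dilation",
    "kymo_area",
    "fov_area_um2",
    "DEFAULT_BASELINE_FRAMES",
    "THEORETICAL_BASELINE",
]

DEFAULT_BASELINE_FRAMES = 10
#: no-leakage value of the integrated normalized trace over the 0-3600 s window
THEORETICAL_BASELINE = 3600.0

# fixed ROI sizes used for manual placement on real data (px)
WOUND_ROI_SHAPE = (50, 50)
VESSEL_ROI_SHAPE = (300, 100)
DILATION_LINE_LENGTH = 50
DILATION_LINE_WIDTH = 30


@dataclass
class ROISpec:
    """Rectangle or wide-line region of interest in pixel coordinates.

    Rectangles: ``coordinates = (top, left, height, width)``.
    Lines: ``coordinates = (y0, x0, y1, x1)`` plus ``line_width`` px.
    """

    kind: str  # "rectangle" | "line"
    coordinates: tuple
    role: str = ""  # vessel | wound | background | dilation_line
    line_width: int = DILATION_LINE_WIDTH

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "line"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        n_expected = 4
        if len(self.coordinates) != n_expected:
            raise ValueError("ROI needs 4 coordinates")
        self.coordinates = tuple(float(c) for c in self.coordinates)

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.kind == "rectangle":
            top, left, rh, rw = self.coordinates
            if top < 0 or left < 0 or top + rh > h or left + rw > w or rh <= 0 or rw <= 0:
                raise ValueError(f"rectangle ROI {self.coordinates} outside image {shape}")
        else:
            y0, x0, y1, x1 = self.coordinates
            for y, x in ((y0, x0), (y1, x1)):
                if not (0 <= y <= h - 1 and 0 <= x <= w - 1):
                    raise ValueError(f"line ROI endpoint ({y}, {x}) outside image {shape}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coordinates": list(self.coordinates),
            "role": self.role,
            "line_width": self.line_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROISpec":
        return cls(
            kind=d["kind"],
            coordinates=tuple(d["coordinates"]),
            role=d.get("role", ""),
            line_width=int(d.get("line_width", DILATION_LINE_WIDTH)),
        )


@dataclass
class IntensityTrace:
    """Per-frame ROI mean intensity in arbitrary units."""

    times: np.ndarray  # s
    values: np.ndarray
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0]):
                raise ValueError("non-uniform frame spacing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class NormalizedTrace:
    """Unitless trace whose baseline-window mean is 1."""

    times: np.ndarray
    values: np.ndarray
    baseline_window: tuple[float, float]  # (t_start, t_end) s, inclusive

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        t0, t1 = self.baseline_window
        sel = (self.times >= t0) & (self.times <= t1)
        if not sel.any():
            raise ValueError("baseline window contains no samples")
        if abs(self.values[sel].mean() - 1.0) > 1e-9:
            raise ValueError("baseline-window mean of a NormalizedTrace must be 1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Kymograph:
    """Position-along-line × time intensity matrix."""

    matrix: np.ndarray  # (n_positions, n_frames)
    pixel_size: float  # µm/px along the line
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class LeakageSummary:
    iv_tot_norm: float
    ib_end: float | None = None
    max_dilation: float | None = None
    rate_peak_vessel: float | None = None  # 1/s
    rate_peak_time: float | None = None  # s
    rate_peak_wound: float | None = None  # 1/s
    onset_time: float | None = None  # s
    theoretical_baseline: float = THEORETICAL_BASELINE
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trace extraction and normalization
# ---------------------------------------------------------------------------

def extract_trace(
    stack: FrameStack, roi: ROISpec, channel: int | str = 0
) -> IntensityTrace:
    """Per-frame mean intensity inside a rectangle ROI."""
    if roi.kind != "rectangle":
        raise ValueError("extract_trace takes a rectangle ROI; use build_kymograph for lines")
    roi.check_bounds(stack.frame_shape)
    c = stack.channel_index(channel)
    top, left, h, w = (int(round(v)) for v in roi.coordinates)
    pix = stack.pixels[:, c]
    if stack.has_z:
        pix = pix.max(axis=1)
    values = pix[:, top : top + h, left : left + w].mean(axis=(1, 2))
    return IntensityTrace(times=stack.times, values=values)


def background_correct(
    trace: IntensityTrace, background_trace: IntensityTrace
) -> IntensityTrace:
    """Per-timepoint background subtraction; negatives are retained unclamped."""
    if len(trace) != len(background_trace):
        raise ValueError("trace and background length mismatch")
    return IntensityTrace(
        times=trace.times,
        values=trace.values - background_trace.values,
        background_corrected=True,
    )


def baseline_window_times(
    frame_interval: float, n_baseline_frames: int = DEFAULT_BASELINE_FRAMES
) -> tuple[float, float]:
    """Time span (inclusive) covered by the first ``n_baseline_frames`` frames."""
    return (0.0, (n_baseline_frames - 1) * frame_interval)


def normalize_baseline(
    trace: IntensityTrace,
    baseline_window: tuple[float, float] | None = None,
    n_baseline_frames: int = DEFAULT_BASELINE_FRAMES,
) -> NormalizedTrace:
    """Divide the trace by the mean of its pre-shift baseline window.

    Default window: the first 10 frames (t = 0-270 s at a 30-s interval).
    """
    if baseline_window is None:
        dt = trace.times[1] - trace.times[0] if len(trace) > 1 else 1.0
        baseline_window = (trace.times[0], trace.times[0] + (n_baseline_frames - 1) * dt)
    t0, t1 = baseline_window
    sel = (trace.times >= t0) & (trace.times <= t1)
    if not sel.any():
        raise ValueError("baseline window contains no frames")
    denom = trace.values[sel].mean()
    if denom <= 0:
        raise ValueError(f"baseline mean must be positive, got {denom!r}")
    return NormalizedTrace(
        times=trace.times, values=trace.values / denom, baseline_window=baseline_window
    )


def n_baseline_frames(trace: NormalizedTrace) -> int:
    """Number of frames inside the trace's baseline window."""
    t0, t1 = trace.baseline_window
    return int(((trace.times >= t0) & (trace.times <= t1)).sum())


def integrate_leakage(
    norm_trace: NormalizedTrace, window: tuple[float, float] = (0.0, 3600.0)
) -> float:
    """Trapezoidal integral of the normalized trace over the window (arb·s).

    A constant-1 trace over 0-3600 s integrates to exactly 3600.
    """
    t0, t1 = window
    if t0 == t1:
        return 0.0
    if t0 < norm_trace.times[0] - 1e-9 or t1 > norm_trace.times[-1] + 1e-9:
        raise ValueError(
            f"window {window} not covered by trace "
            f"[{norm_trace.times[0]}, {norm_trace.times[-1]}]"
        )
    sel = (norm_trace.times >= t0 - 1e-9) & (norm_trace.times <= t1 + 1e-9)
    return float(np.trapezoid(norm_trace.values[sel], norm_trace.times[sel]))


def leakage_rate(
    norm_trace: NormalizedTrace | IntensityTrace,
    smooth: bool = False,
    smooth_window: int = 3,
) -> tuple[np.ndarray, float, float]:
    """Temporal derivative (1/s): central differences, one-sided at the ends.

    Returns ``(rate, peak_rate, peak_time)``. Optional moving-average
    pre-smoothing (off by default — it biases the end-point estimates).
    """
    if len(norm_trace.times) < 3:
        raise ValueError("rate estimation needs at least 3 frames")
    values = norm_trace.values
    if smooth:
        if smooth_window % 2 == 0 or smooth_window < 3:
            raise ValueError("smooth_window must be an odd integer >= 3")
        pad = smooth_window // 2
        padded = np.pad(values, pad, mode="edge")
        values = np.convolve(padded, np.ones(smooth_window) / smooth_window, mode="valid")
    rate = np.gradient(values, norm_trace.times)
    k = int(np.argmax(rate))
    return rate, float(rate[k]), float(norm_trace.times[k])


def blockade_percent(
    iv_treated: float, iv_control: float, baseline: float = THEORETICAL_BASELINE
) -> float:
    """Percent block of wound-induced leakage relative to a control condition.

    ``100 * (1 - (treated - baseline) / (control - baseline))`` with excess
    measured above the theoretical no-leakage baseline. Values above 100
    indicate the treated trace dipping below baseline.
    """
    excess_control = iv_control - baseline
    if excess_control <= 0:
        raise ValueError(
            "control integrated leakage must exceed the baseline for a defined effect size"
        )
    return 100.0 * (1.0 - (iv_treated - baseline) / excess_control)


# ---------------------------------------------------------------------------
# kymograph metrics
# ---------------------------------------------------------------------------

def build_kymograph(
    stack: FrameStack, line: ROISpec, channel: int | str = 0
) -> Kymograph:
    """Line-scan kymograph: row = position along the line, column = frame.

    Each entry averages the intensity across the line's width, matching a
    multi-kymograph of a wide line selection.
    """
    if line.kind != "line":
        raise ValueError("build_kymograph takes a line ROI")
    line.check_bounds(stack.frame_shape)
    c = stack.channel_index(channel)
    y0, x0, y1, x1 = line.coordinates
    pix = stack.pixels[:, c]
    if stack.has_z:
        pix = pix.max(axis=1)
    columns = [
        profile_line(
            frame, (y0, x0), (y1, x1), linewidth=line.line_width, order=1,
            mode="reflect", reduce_func=np.mean,
        )
        for frame in pix
    ]
    return Kymograph(
        matrix=np.stack(columns, axis=1),
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
    )


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.view(np.uint8), [0]])
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return int((ends - starts).max())


def vessel_diameter(kymo: Kymograph, run_mode: str = "run") -> IntensityTrace:
    """Per-frame vessel diameter (µm) from an Otsu-binarized kymograph.

    ``run_mode="run"`` measures the longest contiguous foreground run per
    column (robust to speckle); ``"count"`` counts all foreground pixels.
    """
    if np.ptp(kymo.matrix) == 0:
        raise ValueError("flat kymograph: Otsu threshold undefined")
    threshold = filters.threshold_otsu(kymo.matrix)
    fg = kymo.matrix > threshold
    if run_mode == "run":
        widths = np.array([_longest_run(col) for col in fg.T], dtype=float)
    elif run_mode == "count":
        widths = fg.sum(axis=0).astype(float)
    else:
        raise ValueError("run_mode must be 'run' or 'count'")
    return IntensityTrace(times=kymo.times, values=widths * kymo.pixel_size)


def max_dilation(dv_norm: NormalizedTrace) -> float:
    """Maximum of the baseline-normalized diameter trace."""
    return float(np.max(dv_norm.values))


def kymo_area(
    kymo: Kymograph,
    n_baseline_frames: int = DEFAULT_BASELINE_FRAMES,
    persistence: int = 2,
) -> tuple[int, float, float | None]:
    """Foreground area of the min-max normalized, Otsu-binarized kymograph.

    Returns ``(area_px2, area_um2, onset_time)``. Onset is the first time at
    which the per-frame mean exceeds baseline mean + 3 SD for at least
    ``persistence`` consecutive frames; None if that never happens.
    """
    mat = kymo.matrix
    rng = np.ptp(mat)
    if rng == 0:
        raise ValueError("flat kymograph")
    norm = (mat - mat.min()) / rng
    threshold = filters.threshold_otsu(norm)
    mask = norm > threshold
    area_px = int(mask.sum())
    area_um2 = area_px * kymo.pixel_size**2

    trace = norm.mean(axis=0)
    base = trace[:n_baseline_frames]
    limit = base.mean() + 3 * base.std(ddof=1) if len(base) > 1 else base.mean()
    above = trace > limit
    onset = None
    for k in range(len(above) - persistence + 1):
        if above[k : k + persistence].all():
            onset = float(kymo.times[k])
            break
    return area_px, float(area_um2), onset


def fov_area_um2(shape_px: tuple[int, int] = (1024, 1024), pixel_size: float = 0.65) -> float:
    """Field-of-view area in µm² (1024² px at 0.65 µm/px ≈ 4.43e5 µm²)."""
    h, w = shape_px
    return h * pixel_size * w * pixel_size
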